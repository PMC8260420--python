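"""Nonnegative LC fitting, CRLB scaling laws, noise estimation."""

import math

import numpy as np
import pytest

from ethanolmrs.fitting import (
    CollinearBasisError,
    FitResult,
    GridMismatchError,
    crlb,
    estimate_noise,
    fit_spectrum,
    resample_to_grid,
)
from ethanolmrs.spectral_model import AcquisitionParams, BasisSet
from ethanolmrs.synthetic import AcquiredSpectrum, GroundTruth, simulate_spectrum


def spectrum_from(basis, intensity):
    return AcquiredSpectrum(basis.grid, intensity, basis.params)


class TestFitSpectrum:
    def test_exact_recovery_of_single_scaled_column(self, basis):
        spec = spectrum_from(basis, 3.0 * basis.column("Eth"))
        fit = fit_spectrum(spec, basis, noise_sd=1.0)
        assert fit.amplitudes["Eth"] == pytest.approx(3.0, abs=1e-8)
        for other in ("NAA", "Cr", "Cho"):
            assert fit.amplitudes[other] == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_mixture_recovered(self, basis):
        truth = {"NAA": 15.0, "Cr": 10.0, "Cho": 8.0, "Eth": 2.0}
        spec = simulate_spectrum(
            GroundTruth(concentrations=truth, noise_sd=0.0), basis
        )
        fit = fit_spectrum(spec, basis, noise_sd=1.0)
        for name, c in truth.items():
            assert fit.amplitudes[name] == pytest.approx(c, rel=1e-6)

    def test_negative_signal_clamped_at_zero_boundary(self, basis):
        spec = spectrum_from(basis, -basis.column("NAA"))
        fit = fit_spectrum(spec, basis, noise_sd=1.0)
        assert fit.amplitudes["NAA"] == 0.0
        assert "NAA" not in fit.active
        # oracle: unconstrained least squares wants it negative, so the
        # KKT-consistent constrained answer pins it at the boundary
        ols, *_ = np.linalg.lstsq(basis.spectra, spec.intensity, rcond=None)
        assert ols[basis.names.index("NAA")] < 0

    def test_matches_unconstrained_oracle_in_interior(self, basis, rng):
        truth = np.array([12.0, 8.0, 2.5, 9.0])
        y = basis.spectra @ truth + rng.normal(0, 5.0, basis.grid.size)
        ols, *_ = np.linalg.lstsq(basis.spectra, y, rcond=None)
        if np.all(ols >= 0):  # interior case: solutions must coincide
            fit = fit_spectrum(spectrum_from(basis, y), basis, noise_sd=5.0)
            np.testing.assert_allclose(
                [fit.amplitudes[n] for n in basis.names], ols, rtol=1e-8
            )
        else:  # pragma: no cover - noise level keeps this interior
            pytest.fail("oracle unexpectedly hit the boundary")

    def test_scale_equivariance_amplitudes_scale_crlb_fixed(self, basis):
        spec = simulate_spectrum(GroundTruth(noise_sd=0.0), basis)
        f1 = fit_spectrum(spec, basis, noise_sd=2.0)
        f2 = fit_spectrum(
            spectrum_from(basis, 10.0 * spec.intensity), basis, noise_sd=20.0
        )
        for name in basis.names:
            assert f2.amplitudes[name] == pytest.approx(
                10.0 * f1.amplitudes[name], rel=1e-9
            )
            assert f2.crlb_percent[name] == pytest.approx(
                f1.crlb_percent[name], rel=1e-9
            )

    def test_collinear_basis_rejected_with_names(self, basis):
        col = basis.column("NAA")
        bad = BasisSet(
            ("NAA", "NAA2"),
            np.column_stack([col, 2.0 * col]),
            basis.params,
            {"NAA": 3, "NAA2": 3},
        )
        spec = spectrum_from(basis, col)
        with pytest.raises(CollinearBasisError, match="NAA~NAA2"):
            fit_spectrum(spec, bad, noise_sd=1.0)

    def test_finer_grid_resampled_onto_basis_grid(self, basis):
        fine = np.linspace(-0.5, 5.5, 8192)
        fine_params = AcquisitionParams(grid=fine)
        y = np.interp(fine, basis.grid, 4.0 * basis.column("Cr"))
        spec = AcquiredSpectrum(fine, y, fine_params)
        fit = fit_spectrum(spec, basis, noise_sd=1.0)
        assert fit.amplitudes["Cr"] == pytest.approx(4.0, rel=1e-3)

    def test_extrapolation_refused(self, basis):
        short = np.linspace(1.0, 4.0, 1024)
        spec = AcquiredSpectrum(
            short, np.zeros_like(short), AcquisitionParams(grid=short)
        )
        with pytest.raises(GridMismatchError):
            resample_to_grid(spec, basis.grid)


class TestCRLB:
    def test_doubling_noise_doubles_crlb(self, basis):
        spec = simulate_spectrum(GroundTruth(noise_sd=0.0), basis)
        f = fit_spectrum(spec, basis, noise_sd=3.0)
        b1 = crlb(basis, f, noise_sd=3.0)
        b2 = crlb(basis, f, noise_sd=6.0)
        for name in basis.names:
            assert b2[name] == pytest.approx(2.0 * b1[name], rel=1e-12)

    def test_doubling_amplitude_halves_relative_crlb(self, basis):
        t1 = GroundTruth(concentrations={"Eth": 5.0}, noise_sd=0.0)
        t2 = GroundTruth(concentrations={"Eth": 10.0}, noise_sd=0.0)
        f1 = fit_spectrum(simulate_spectrum(t1, basis), basis, noise_sd=2.0)
        f2 = fit_spectrum(simulate_spectrum(t2, basis), basis, noise_sd=2.0)
        assert f2.crlb_percent["Eth"] == pytest.approx(
            0.5 * f1.crlb_percent["Eth"], rel=1e-6
        )

    def test_zero_amplitude_metabolite_flagged_nan(self, basis):
        truth = GroundTruth(concentrations={"NAA": 10.0}, noise_sd=0.0)
        f = fit_spectrum(simulate_spectrum(truth, basis), basis, noise_sd=1.0)
        assert math.isnan(f.crlb_percent["Eth"])
        assert f.crlb_percent["NAA"] > 0

    def test_monte_carlo_scatter_matches_crlb(self, basis):
        # 300 replicates at the default noise level; the linear-Gaussian
        # model attains the bound, so relative SD tracks the reported CRLB
        amps, bounds = [], []
        for seed in range(300):
            spec = simulate_spectrum(GroundTruth(seed=seed), basis)
            f = fit_spectrum(spec, basis)
            amps.append(f.amplitudes["Eth"])
            bounds.append(f.crlb_percent["Eth"])
        amps = np.asarray(amps)
        rel_sd_pct = amps.std(ddof=1) / amps.mean() * 100.0
        mean_crlb = float(np.mean(bounds))
        assert 0.8 * mean_crlb <= rel_sd_pct <= 1.25 * mean_crlb


class TestEstimateNoise:
    def test_recovers_known_sd_within_ten_percent(self, params, rng):
        y = rng.normal(0.0, 0.5, params.grid.size)
        spec = AcquiredSpectrum(params.grid, y, params)
        assert estimate_noise(spec) == pytest.approx(0.5, rel=0.10)

    def test_noiseless_spectrum_estimates_near_zero(self, basis):
        spec = simulate_spectrum(GroundTruth(noise_sd=0.0), basis)
        assert estimate_noise(spec) < 1e-3 * spec.intensity.max()

    def test_constant_offset_and_linear_trend_removed(self, params, rng):
        y = rng.normal(0.0, 0.5, params.grid.size)
        spec0 = AcquiredSpectrum(params.grid, y, params)
        spec1 = AcquiredSpectrum(params.grid, y + 7.0 + 0.3 * params.grid, params)
        assert estimate_noise(spec1) == pytest.approx(estimate_noise(spec0), rel=1e-9)

    def test_missing_window_rejected(self):
        grid = np.linspace(0.0, 3.0, 1024)
        spec = AcquiredSpectrum(
            grid, np.zeros_like(grid), AcquisitionParams(grid=grid)
        )
        with pytest.raises(ValueError, match="window"):
            estimate_noise(spec)


def test_fit_result_json_roundtrip(basis, tmp_path):
    spec = simulate_spectrum(GroundTruth(seed=3), basis)
    fit = fit_spectrum(spec, basis)
    path = tmp_path / "fit.json"
    fit.to_json(path)
    loaded = FitResult.from_json(path)
    assert loaded.amplitudes == fit.amplitudes
    assert loaded.residual_rms == fit.residual_rms
    assert loaded.active == fit.active
    for name in basis.names:
        a, b = loaded.crlb_percent[name], fit.crlb_percent[name]
        assert (math.isnan(a) and math.isnan(b)) or a == b
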