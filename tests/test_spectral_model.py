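"""Forward model: Lorentzian rendering, default basis, serialization."""

import numpy as np
import pytest

from ethanolmrs.spectral_model import (
    AcquisitionParams,
    GridCoverageError,
    Resonance,
    build_basis,
    default_basis,
    load_basis,
    render_resonance,
    save_basis,
    standard_resonances,
    triplet,
)


class TestResonanceInvariants:
    def test_multiplet_intensities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            Resonance(2.0, 3, ((0.0, 0.6), (7.0, 0.6)))

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            Resonance(2.0, 3, ((0.0, 1.5), (7.0, -0.5)))

    @pytest.mark.parametrize(
        "kwargs", [{"n_protons": 0}, {"linewidth_hz": 0.0}, {"linewidth_hz": -1.0}]
    )
    def test_bad_scalars_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Resonance(2.0, **{"n_protons": 1, **kwargs})


class TestRenderResonance:
    def test_singlet_peaks_at_grid_point_nearest_center(self, params):
        res = Resonance(2.01, 1)
        y = render_resonance(res, params)
        nearest = np.argmin(np.abs(params.grid - 2.01))
        assert np.argmax(y) == nearest

    def test_proton_count_scales_pointwise(self, params):
        y1 = render_resonance(Resonance(2.01, 1), params)
        y3 = render_resonance(Resonance(2.01, 3), params)
        np.testing.assert_allclose(y3, 3.0 * y1, rtol=0, atol=1e-12)

    def test_triplet_symmetric_about_center(self):
        # symmetric grid centred on the multiplet centre
        grid = np.linspace(1.18 - 1.0, 1.18 + 1.0, 2001)
        params = AcquisitionParams(grid=grid)
        y = render_resonance(Resonance(1.18, 3, triplet(7.1)), params)
        np.testing.assert_allclose(y, y[::-1], rtol=0, atol=1e-9)

    def test_linearity_of_multicomponent_render(self, params):
        parts = [Resonance(1.18, 3, triplet(7.1)), Resonance(3.65, 2)]
        total = sum(render_resonance(r, params) for r in parts)
        basis = build_basis({"Eth": tuple(parts)}, params)
        np.testing.assert_allclose(basis.column("Eth"), total, rtol=0, atol=1e-9)

    @pytest.mark.parametrize("fwhm_hz", [1.0, 2.0, 4.0, 8.0])
    def test_area_invariant_under_linewidth(self, fwhm_hz):
        # grid covering +/- 30 linewidths in each case
        fwhm_ppm = fwhm_hz / 123.25
        grid = np.linspace(2.5 - 30 * fwhm_ppm, 2.5 + 30 * fwhm_ppm, 4001)
        params = AcquisitionParams(grid=grid)
        y = render_resonance(Resonance(2.5, 2, linewidth_hz=fwhm_hz), params)
        area = np.trapezoid(y, grid)
        # truncated Lorentzian at +/-30 FWHM captures (2/pi) atan(60) of the mass
        expected = 2 * (2 / np.pi) * np.arctan(60.0)
        assert area == pytest.approx(expected, rel=1e-3)

    def test_ppm_shift_moves_argmax_consistently_in_hz(self, params):
        delta_ppm = 0.5
        y0 = render_resonance(Resonance(2.0, 1), params)
        y1 = render_resonance(Resonance(2.0 + delta_ppm, 1), params)
        shift_ppm = params.grid[np.argmax(y1)] - params.grid[np.argmax(y0)]
        dppm = params.grid[1] - params.grid[0]
        assert abs(shift_ppm - delta_ppm) <= dppm
        assert shift_ppm * params.field_mhz == pytest.approx(
            delta_ppm * params.field_mhz, abs=dppm * params.field_mhz
        )

    def test_refuses_grid_not_covering_resonance(self):
        params = AcquisitionParams(grid=np.linspace(2.0, 4.0, 512))
        with pytest.raises(GridCoverageError):
            render_resonance(Resonance(1.18, 3, triplet(7.1)), params)


class TestDefaultBasis:
    def test_contains_the_four_study_metabolites(self, basis):
        assert set(basis.names) >= {"Eth", "NAA", "Cr", "Cho"}

    def test_ethanol_peak_near_1p18_ppm(self, basis):
        eth = basis.column("Eth")
        assert abs(basis.grid[np.argmax(eth)] - 1.18) <= 0.05

    def test_design_matrix_full_rank(self, basis):
        B = basis.spectra / np.linalg.norm(basis.spectra, axis=0)
        gram = B.T @ B
        assert np.linalg.matrix_rank(gram) == len(basis.names)
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) < 0.999)

    def test_narrow_grid_refused(self):
        with pytest.raises(GridCoverageError):
            default_basis(AcquisitionParams(grid=np.linspace(1.0, 3.0, 512)))

    def test_optional_ethanol_ch2_quartet(self, params):
        b = default_basis(params, include_ethanol_ch2=True)
        eth = b.column("Eth")
        window = (params.grid > 3.5) & (params.grid < 3.8)
        assert eth[window].max() > 0.1 * eth.max()
        assert b.n_protons["Eth"] == 5


class TestSerialization:
    def test_basis_roundtrip_lossless(self, basis, tmp_path):
        save_basis(basis, tmp_path / "basis")
        loaded = load_basis(tmp_path / "basis")
        assert loaded.names == basis.names
        np.testing.assert_allclose(loaded.spectra, basis.spectra, rtol=0, atol=1e-12)
        np.testing.assert_allclose(loaded.grid, basis.grid, rtol=0, atol=1e-12)
        assert loaded.n_protons == basis.n_protons

    def test_standard_resonance_table_proton_counts(self):
        table = standard_resonances()
        counts = {m: sum(r.n_protons for r in group) for m, group in table.items()}
        assert counts == {"Eth": 3, "NAA": 3, "Cr": 3, "Cho": 9}
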