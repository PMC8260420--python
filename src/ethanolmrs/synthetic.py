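"""Synthetic stand-ins for the scanner and the serum assay.

Everything the study measured can be generated here with known ground truth:
noisy single-voxel spectra, unsuppressed water reference scans, region-typical
voxel compositions, and serum ethanol time courses (linear absorption ramp to
a peak, then zero-order elimination). Noise is iid Gaussian per grid point in
absorption-mode intensity — the simplest model consistent with the
Cramér-Rao machinery in the fitting module. All randomness flows through
explicit integer seeds; there is no hidden global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as k
from .quantify import VoxelComposition
from .serum_pk import PKParams, SerumSeries, serum_from_blood
from .spectral_model import (
    AcquisitionParams,
    BasisSet,
    render_resonance,
    water_resonance,
)

DEFAULT_NOISE_SD = 75.0
"""Per-point noise SD in basis-amplitude signal units.

Derived analytically from the default design matrix: with the default truth
(13 mmol/L ethanol per litre voxel water in a ~72%-water voxel) the predicted
ethanol CRLB is ~6%, the middle of the single-digit precision typical of
dedicated long-TE in vivo acquisitions; see docs/methods.md.
"""

DEFAULT_TRUTH_MMOL = {"Eth": 13.0, "NAA": 12.0, "Cr": 8.0, "Cho": 2.0}
"""Default true concentrations, mmol per L of voxel water.

13 mmol/L ethanol is ~0.6 g/L, the centre of the concentrations the study
design targets; NAA/Cr/Cho are typical healthy-brain values.
"""

# (gm, wm, csf) uniform sampling ranges per region, calibrated to the
# segmented study voxels; renormalized to sum exactly to 1.
REGION_FRACTION_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    "occipital_cortex": ((0.40, 0.54), (0.42, 0.58), (0.03, 0.05)),
    "cerebellum": ((0.77, 0.89), (0.11, 0.23), (0.00, 0.04)),
    "frontal_cortex": ((0.11, 0.16), (0.62, 0.81), (0.08, 0.23)),
    "putamen": ((0.77, 0.91), (0.09, 0.23), (0.00, 0.02)),
}

VOXEL_ML = {
    "occipital_cortex": 15.6,
    "cerebellum": 8.0,
    "frontal_cortex": 8.0,
    "putamen": 7.5,
}


@dataclass(frozen=True)
class GroundTruth:
    """Simulation truth for one voxel measurement.

    ``concentrations`` are in basis-amplitude units (mmol/L-equivalent);
    ``water_signal_scale`` is the integrated area of the water reference
    line in the same arbitrary signal units as the spectrum.
    """

    concentrations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_MMOL)
    )
    water_signal_scale: float = 1.0
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class AcquiredSpectrum:
    """One voxel spectrum (or water reference scan) plus metadata."""

    grid: np.ndarray
    intensity: np.ndarray
    params: AcquisitionParams
    voxel_id: str = ""
    is_water_reference: bool = False

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if intensity.shape != grid.shape:
            raise ValueError("intensity and grid lengths differ")
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensity contains non-finite values")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "intensity", intensity)


class UnknownMetaboliteError(KeyError):
    """A ground-truth label has no column in the basis set."""


def simulate_spectrum(
    truth: GroundTruth, basis: BasisSet, voxel_id: str = ""
) -> AcquiredSpectrum:
    """Water-suppressed voxel spectrum: basis x concentrations + noise."""
    unknown = set(truth.concentrations) - set(basis.names)
    if unknown:
        raise UnknownMetaboliteError(
            f"metabolites {sorted(unknown)} not in basis {list(basis.names)}"
        )
    conc = np.array(
        [truth.concentrations.get(name, 0.0) for name in basis.names]
    )
    intensity = basis.spectra @ conc
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        intensity = intensity + rng.normal(0.0, truth.noise_sd, size=intensity.shape)
    return AcquiredSpectrum(basis.grid, intensity, basis.params, voxel_id)


def simulate_water_reference(
    truth: GroundTruth,
    params: AcquisitionParams,
    voxel_id: str = "",
    linewidth_hz: float = k.DEFAULT_LINEWIDTH_HZ,
) -> AcquiredSpectrum:
    """Unsuppressed water reference scan.

    A single Lorentzian line at ``params.reference_ppm`` whose integrated
    area equals ``truth.water_signal_scale`` (up to grid tail truncation).
    """
    if truth.water_signal_scale <= 0:
        raise ValueError("water_signal_scale must be > 0")
    res = water_resonance(linewidth_hz)
    if params.reference_ppm != res.center_ppm:
        from dataclasses import replace

        res = replace(res, center_ppm=params.reference_ppm)
    # unit-area line: render has area n_protons, divide it out
    intensity = truth.water_signal_scale * render_resonance(res, params) / res.n_protons
    if truth.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
        intensity = intensity + rng.normal(0.0, truth.noise_sd, size=intensity.shape)
    return AcquiredSpectrum(
        params.grid, intensity, params, voxel_id, is_water_reference=True
    )


def sample_voxel_composition(region: str, seed: int) -> VoxelComposition:
    """Draw a region-typical GM/WM/CSF composition, summing exactly to 1."""
    if region not in REGION_FRACTION_RANGES:
        raise ValueError(
            f"unknown region {region!r}; expected one of {sorted(REGION_FRACTION_RANGES)}"
        )
    rng = np.random.default_rng(seed)
    draws = np.array(
        [rng.uniform(lo, hi) for lo, hi in REGION_FRACTION_RANGES[region]]
    )
    draws /= draws.sum()
    f_gm, f_wm = float(draws[0]), float(draws[1])
    f_csf = 1.0 - f_gm - f_wm  # exact complement so the sum is exactly 1
    return VoxelComposition(f_gm, f_wm, max(f_csf, 0.0), VOXEL_ML[region], region)


def simulate_serum_series(
    pk: PKParams,
    times_min: np.ndarray,
    subject: str = "SIM",
    peak_gL: float | None = None,
    timepoint_labels: tuple[str, ...] = (),
) -> SerumSeries:
    """Piecewise-linear serum ethanol curve.

    Zero at t = 0 (pre-drinking sample), linear rise to ``peak_gL`` at
    ``pk.absorption_min``, then zero-order decline at ``pk.beta_gL_per_h``,
    clamped at zero. The default peak is the design target,
    ``serum_from_blood(pk.target_bac_gkg)``.
    """
    times = np.asarray(times_min, dtype=float)
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be >= 0 and strictly increasing")
    if peak_gL is None:
        peak_gL = serum_from_blood(pk.target_bac_gkg, pk.serum_blood_factor)
    conc = np.where(
        times <= pk.absorption_min,
        peak_gL * times / pk.absorption_min,
        peak_gL - pk.beta_gL_per_h * (times - pk.absorption_min) / 60.0,
    )
    conc = np.clip(conc, 0.0, None)
    return SerumSeries(
        subject,
        tuple(zip(times.tolist(), conc.tolist())),
        timepoint_labels,
    )
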