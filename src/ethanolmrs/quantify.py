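"""Absolute quantification: water content, internal water reference, normalization.

The voxel's water content follows from its gray-matter / white-matter / CSF
volume fractions and compartmental water constants (42.9 mol/L = 78 vol% for
GM, 35.8 mol/L = 65 vol% for WM, 53.4 mol/L = 97 vol% for CSF). Two variants
are kept explicit: the volume-fraction percentage (the normalization
denominator) and the mol/L molarity (the internal-water-reference scale).

No relaxation (T1/T2) correction is applied anywhere; ``relaxation_factor``
hooks exist but default to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from . import constants as k

FRACTION_SUM_TOL = 0.015
"""Tolerance on f_gm+f_wm+f_csf-1; admits integer-percent rounding (3 x 0.5%)."""


@dataclass(frozen=True)
class WaterConstants:
    """Per-compartment water molarity (mol/L) and volume fraction (%)."""

    c_gm: float = k.WATER_MOLARITY_GM
    c_wm: float = k.WATER_MOLARITY_WM
    c_csf: float = k.WATER_MOLARITY_CSF
    w_gm: float = k.WATER_PERCENT_GM
    w_wm: float = k.WATER_PERCENT_WM
    w_csf: float = k.WATER_PERCENT_CSF


@dataclass(frozen=True)
class VoxelComposition:
    """GM/WM/CSF volume fractions of one measurement voxel.

    Fractions must sum to 1 within ``FRACTION_SUM_TOL``; compositions read
    from integer-percent tables may be off by up to 1% and are deliberately
    NOT renormalized, so that printed water contents are reproduced exactly.
    """

    f_gm: float
    f_wm: float
    f_csf: float
    voxel_ml: float = 8.0
    region: str = ""

    def __post_init__(self) -> None:
        for name, f in (("f_gm", self.f_gm), ("f_wm", self.f_wm), ("f_csf", self.f_csf)):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}={f} outside [0, 1]")
        total = self.f_gm + self.f_wm + self.f_csf
        if abs(total - 1.0) > FRACTION_SUM_TOL:
            raise ValueError(f"tissue fractions sum to {total}, not 1")
        if self.voxel_ml <= 0:
            raise ValueError("voxel_ml must be > 0")


@dataclass(frozen=True)
class QuantResult:
    """One metabolite's quantification chain for one voxel."""

    metabolite: str
    raw_conc_mmol: float  # mmol per L of voxel
    norm_conc_gL: float  # g per L of voxel water
    wc_percent: float
    crlb_percent: float


def water_content(
    comp: VoxelComposition, consts: WaterConstants = WaterConstants()
) -> tuple[float, float]:
    """Voxel water content as ``(wc_percent, wc_mol_per_L)``.

    Both are fraction-weighted means over the compartments; the percent
    variant is the normalization denominator, the mol/L variant scales the
    internal water reference.
    """
    wc_pct = (
        comp.f_gm * consts.w_gm + comp.f_wm * consts.w_wm + comp.f_csf * consts.w_csf
    )
    wc_mol = (
        comp.f_gm * consts.c_gm + comp.f_wm * consts.c_wm + comp.f_csf * consts.c_csf
    )
    return wc_pct, wc_mol


def water_content_from_percents(
    gm_pct: int,
    wm_pct: int,
    csf_pct: int,
    consts: WaterConstants = WaterConstants(),
) -> float:
    """Table-mirroring water content (%) from integer tissue percentages.

    Computed in decimal arithmetic and rounded half away from zero to one
    decimal, matching the printed presentation (e.g. gm 85 / wm 15 gives
    76.05 exactly, printed as 76.1 — plain float arithmetic misrounds it).
    """
    wc = (
        Decimal(gm_pct) * Decimal(repr(consts.w_gm))
        + Decimal(wm_pct) * Decimal(repr(consts.w_wm))
        + Decimal(csf_pct) * Decimal(repr(consts.w_csf))
    ) / Decimal(100)
    return float(wc.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def water_referenced_mmol(
    area_ratio: float,
    n_protons_met: int,
    c_water_voxel_mol: float,
    n_protons_water: int = k.N_PROTONS_WATER,
    relaxation_factor: float = 1.0,
) -> float:
    """Metabolite concentration (mmol per L voxel) from a signal-area ratio.

    ``area_ratio`` is metabolite signal area over water signal area from the
    same voxel. Proton-count correction converts areas to per-molecule
    signal; the voxel water molarity sets the absolute scale::

        c_met = ratio * (n_water / n_met) * C_water[mol/L] * 1000
    """
    if area_ratio < 0:
        raise ValueError("area ratio must be >= 0")
    return (
        area_ratio
        * (n_protons_water / n_protons_met)
        * c_water_voxel_mol
        * 1000.0
        * relaxation_factor
    )


def water_reference_conc(
    amplitude: float,
    water_fit_area: float,
    comp: VoxelComposition,
    n_protons_met: int,
    consts: WaterConstants = WaterConstants(),
    relaxation_factor: float = 1.0,
) -> float:
    """Internal-water-reference scaling of one fitted amplitude.

    ``amplitude`` is in basis units (unit amplitude = area n_protons), so the
    metabolite signal area is ``amplitude * n_protons_met``;
    ``water_fit_area`` is the fitted area of the unsuppressed water line.
    Returns mmol per litre of voxel. No relaxation correction by default.
    """
    if water_fit_area <= 0:
        raise ValueError("water reference area must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    _, c_water_mol = water_content(comp, consts)
    return water_referenced_mmol(
        amplitude * n_protons_met / water_fit_area,
        n_protons_met,
        c_water_mol,
        relaxation_factor=relaxation_factor,
    )


def normalize_to_water(raw_gL: float, wc_percent: float) -> float:
    """Concentration per litre of voxel water from per litre of voxel."""
    if wc_percent <= 0 or wc_percent > 100:
        raise ValueError(f"wc_percent={wc_percent} outside (0, 100]")
    return raw_gL / (wc_percent / 100.0)


def denormalize(norm_conc_gL: float, wc_percent: float) -> float:
    """Exact inverse of :func:`normalize_to_water`."""
    if wc_percent <= 0 or wc_percent > 100:
        raise ValueError(f"wc_percent={wc_percent} outside (0, 100]")
    return norm_conc_gL * (wc_percent / 100.0)


def mmol_to_gL(
    c_mmol: float, molar_mass: float = k.ETHANOL_MOLAR_MASS_G_PER_MOL
) -> float:
    if c_mmol < 0:
        raise ValueError("concentration must be >= 0")
    return c_mmol * molar_mass / 1000.0


def gL_to_mmol(
    c_gL: float, molar_mass: float = k.ETHANOL_MOLAR_MASS_G_PER_MOL
) -> float:
    if c_gL < 0:
        raise ValueError("concentration must be >= 0")
    return c_gL * 1000.0 / molar_mass


def round_half_up(value: float, ndigits: int) -> float:
    """Round half away from zero (table presentation rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
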