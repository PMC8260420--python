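"""Metabolite resonance models and basis-spectrum rendering.

This is the shared forward model: the same Lorentzian line renders used to
simulate voxel spectra also populate the design matrix of the
linear-combination fit. Each basis column is the unit-amplitude render of one
metabolite, where *unit amplitude* means 1 mmol/L-equivalent and the rendered
area on the ppm axis equals the metabolite's proton count (so signal area =
amplitude x n_protons).

Lineshape is Lorentzian absorption mode. J-coupled multiplets are sums of
Lorentzian components at Hz offsets from the centre; TE-dependent
J-modulation of the ethanol triplet is deliberately not modelled (the basis
is treated as already matched to the echo time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as k


class GridCoverageError(ValueError):
    """The ppm grid does not cover a resonance (plus safety margin)."""


@dataclass(frozen=True)
class Resonance:
    """One metabolite resonance: a (possibly J-split) group of Lorentzian lines.

    Parameters
    ----------
    center_ppm:
        Chemical shift of the multiplet centre, ppm.
    n_protons:
        Number of protons contributing to the signal; scales the area.
    multiplet:
        ``(offset_hz, relative_intensity)`` components; intensities must be
        positive and sum to 1. A singlet is ``((0.0, 1.0),)``.
    linewidth_hz:
        Lorentzian FWHM of every component, Hz.
    """

    center_ppm: float
    n_protons: int
    multiplet: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    linewidth_hz: float = k.DEFAULT_LINEWIDTH_HZ

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ValueError(f"n_protons must be >= 1, got {self.n_protons}")
        if self.linewidth_hz <= 0:
            raise ValueError(f"linewidth_hz must be > 0, got {self.linewidth_hz}")
        rel = np.array([w for _, w in self.multiplet], dtype=float)
        if rel.size == 0 or np.any(rel <= 0):
            raise ValueError("multiplet relative intensities must be positive")
        if abs(rel.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"multiplet relative intensities must sum to 1, got {rel.sum()!r}"
            )


def triplet(j_hz: float) -> tuple[tuple[float, float], ...]:
    """1:2:1 triplet at offsets (-J, 0, +J)."""
    return ((-j_hz, 0.25), (0.0, 0.5), (j_hz, 0.25))


def quartet(j_hz: float) -> tuple[tuple[float, float], ...]:
    """1:3:3:1 quartet at offsets (-1.5J, -0.5J, +0.5J, +1.5J)."""
    return (
        (-1.5 * j_hz, 0.125),
        (-0.5 * j_hz, 0.375),
        (0.5 * j_hz, 0.375),
        (1.5 * j_hz, 0.125),
    )


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition context shared by simulation and fitting."""

    field_mhz: float = k.DEFAULT_FIELD_MHZ
    te_ms: float = k.DEFAULT_TE_MS
    grid: np.ndarray = field(
        default_factory=lambda: default_grid(), repr=False
    )
    reference_ppm: float = k.WATER_PPM

    def __post_init__(self) -> None:
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be > 0")
        if self.te_ms <= 0:
            raise ValueError("te_ms must be > 0")
        grid = np.asarray(self.grid, dtype=float)
        d = np.diff(grid)
        if grid.ndim != 1 or grid.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("grid must be a strictly monotone 1-D array")
        object.__setattr__(self, "grid", grid)


def default_grid(
    ppm_min: float = 0.0, ppm_max: float = 5.0, n_points: int = 2048
) -> np.ndarray:
    """Uniform ppm axis, 0-5 ppm with 2048 points by default."""
    return np.linspace(ppm_min, ppm_max, n_points)


def render_resonance(res: Resonance, params: AcquisitionParams) -> np.ndarray:
    """Render one resonance as real absorption-mode intensities on the grid.

    Each multiplet component is an area-normalized Lorentzian centred at
    ``center_ppm + offset_hz / field_mhz``, scaled by
    ``n_protons * relative_intensity``; the total area on the ppm axis is
    therefore ``n_protons`` (up to tail truncation by the finite grid).

    Raises
    ------
    GridCoverageError
        If the grid does not cover every component +/- 3 linewidths.
    """
    grid = params.grid
    fwhm_ppm = res.linewidth_hz / params.field_mhz
    lo, hi = float(grid.min()), float(grid.max())
    out = np.zeros_like(grid)
    for offset_hz, rel in res.multiplet:
        center = res.center_ppm + offset_hz / params.field_mhz
        if center - 3 * fwhm_ppm < lo or center + 3 * fwhm_ppm > hi:
            raise GridCoverageError(
                f"grid [{lo}, {hi}] ppm does not cover line at {center:.3f} ppm "
                f"+/- 3 linewidths ({3 * fwhm_ppm:.3f} ppm)"
            )
        hwhm = fwhm_ppm / 2.0
        out += (
            res.n_protons
            * rel
            * (hwhm / np.pi)
            / ((grid - center) ** 2 + hwhm**2)
        )
    return out


def standard_resonances(
    linewidth_hz: float = k.DEFAULT_LINEWIDTH_HZ,
    include_ethanol_ch2: bool = False,
) -> dict[str, tuple[Resonance, ...]]:
    """Literature resonance table for the default basis.

    Ethanol is represented by its CH3 triplet (1.18 ppm, J = 7.1 Hz); the
    CH2 quartet at 3.65 ppm is optional and off by default. NAA, Cr and Cho
    are modelled as their dominant methyl singlets.
    """
    eth: list[Resonance] = [
        Resonance(k.ETHANOL_CH3_PPM, 3, triplet(k.ETHANOL_J_HZ), linewidth_hz)
    ]
    if include_ethanol_ch2:
        eth.append(
            Resonance(k.ETHANOL_CH2_PPM, 2, quartet(k.ETHANOL_J_HZ), linewidth_hz)
        )
    return {
        "Eth": tuple(eth),
        "NAA": (Resonance(k.NAA_PPM, 3, linewidth_hz=linewidth_hz),),
        "Cr": (Resonance(k.CR_PPM, 3, linewidth_hz=linewidth_hz),),
        "Cho": (Resonance(k.CHO_PPM, 9, linewidth_hz=linewidth_hz),),
    }


def water_resonance(linewidth_hz: float = k.DEFAULT_LINEWIDTH_HZ) -> Resonance:
    return Resonance(k.WATER_PPM, k.N_PROTONS_WATER, linewidth_hz=linewidth_hz)


@dataclass(frozen=True)
class BasisSet:
    """Named metabolite model spectra on a shared ppm grid.

    ``spectra`` has one row per grid point and one column per metabolite;
    it is the design matrix of the linear-combination fit. Column units:
    unit amplitude = 1 mmol/L-equivalent, i.e. a column integrates to that
    metabolite's proton count on the ppm axis.
    """

    names: tuple[str, ...]
    spectra: np.ndarray
    params: AcquisitionParams
    n_protons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spectra = np.asarray(self.spectra, dtype=float)
        if spectra.ndim != 2 or spectra.shape[1] != len(self.names):
            raise ValueError("spectra must have one column per name")
        if spectra.shape[0] != self.params.grid.size:
            raise ValueError("spectra rows must match the grid length")
        if not np.all(spectra.max(axis=0) > 0):
            raise ValueError("every basis column needs a strictly positive value")
        object.__setattr__(self, "spectra", spectra)

    @property
    def grid(self) -> np.ndarray:
        return self.params.grid

    def column(self, name: str) -> np.ndarray:
        return self.spectra[:, self.names.index(name)]


def build_basis(
    resonances: dict[str, tuple[Resonance, ...]], params: AcquisitionParams
) -> BasisSet:
    """Render a named resonance table into a BasisSet on params.grid."""
    cols = []
    n_protons = {}
    for name, group in resonances.items():
        col = np.zeros_like(params.grid)
        for res in group:
            col += render_resonance(res, params)
        cols.append(col)
        n_protons[name] = sum(res.n_protons for res in group)
    return BasisSet(tuple(resonances), np.column_stack(cols), params, n_protons)


def default_basis(
    params: AcquisitionParams | None = None,
    linewidth_hz: float = k.DEFAULT_LINEWIDTH_HZ,
    include_ethanol_ch2: bool = False,
) -> BasisSet:
    """Default Eth/NAA/Cr/Cho basis at 3 T.

    Raises
    ------
    GridCoverageError
        If the grid does not span at least 0.5-4.2 ppm.
    """
    if params is None:
        params = AcquisitionParams()
    lo, hi = float(params.grid.min()), float(params.grid.max())
    if lo > 0.5 or hi < 4.2:
        raise GridCoverageError(
            f"grid [{lo}, {hi}] ppm too narrow for the default basis (need 0.5-4.2)"
        )
    return build_basis(
        standard_resonances(linewidth_hz, include_ethanol_ch2), params
    )


def save_basis(basis: BasisSet, stem: str | Path) -> tuple[Path, Path]:
    """Write a basis set as <stem>.json (header) + <stem>.csv (matrix).

    The CSV holds the ppm axis in its first column and one column per
    metabolite; the JSON header records labels, proton counts and the
    acquisition parameters. Round-trips losslessly (float repr is exact).
    """
    stem = Path(stem)
    header = {
        "names": list(basis.names),
        "n_protons": basis.n_protons,
        "field_mhz": basis.params.field_mhz,
        "te_ms": basis.params.te_ms,
        "reference_ppm": basis.params.reference_ppm,
    }
    json_path = stem.with_suffix(".json")
    csv_path = stem.with_suffix(".csv")
    json_path.write_text(json.dumps(header, indent=2))
    df = pd.DataFrame(basis.spectra, columns=list(basis.names))
    df.insert(0, "ppm", basis.grid)
    df.to_csv(csv_path, index=False, float_format="%.17g")
    return json_path, csv_path


def load_basis(stem: str | Path) -> BasisSet:
    """Read a basis set written by :func:`save_basis`."""
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".csv"), float_precision="round_trip")
    params = AcquisitionParams(
        field_mhz=header["field_mhz"],
        te_ms=header["te_ms"],
        grid=df["ppm"].to_numpy(),
        reference_ppm=header["reference_ppm"],
    )
    names = tuple(header["names"])
    return BasisSet(
        names,
        df[list(names)].to_numpy(),
        params,
        {n: int(v) for n, v in header["n_protons"].items()},
    )
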