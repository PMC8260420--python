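"""Widmark dose arithmetic, serum/blood conversion and brain-serum comparison.

The study-design side of the pipeline: the ingested ethanol mass needed to
reach a target blood alcohol concentration follows Widmark's relation
A = c * r * m (dose = target BAC x body mass x distribution factor),
optionally inflated for a resorption deficit. Serum concentrations (g/L)
convert to whole-blood (g/kg) by a fixed divisor, defaulting to
0.99 / 0.8 = 1.2375 so the designed serum/blood pair maps exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as k

DEFAULT_PAIRING_TOL_MIN = 20.0
"""Nearest-time pairing tolerance (min) for brain vs serum comparison."""


@dataclass(frozen=True)
class PKParams:
    """Dose-calculation and elimination parameters for one subject."""

    body_mass_kg: float = 70.0
    r_factor: float = 0.7  # Widmark distribution factor for men
    target_bac_gkg: float = 0.8
    beta_gL_per_h: float = 0.15  # zero-order serum elimination slope
    serum_blood_factor: float = k.SERUM_BLOOD_FACTOR
    abv: float = 0.40  # vodka
    ethanol_density: float = 0.789  # g/mL at 20 C
    resorption_deficit: float = 0.0
    absorption_min: float = 60.0  # time from first drink to peak

    def __post_init__(self) -> None:
        for name in (
            "body_mass_kg",
            "r_factor",
            "target_bac_gkg",
            "beta_gL_per_h",
            "serum_blood_factor",
            "ethanol_density",
            "absorption_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.abv <= 1:
            raise ValueError("abv must be in (0, 1]")
        if not 0 <= self.resorption_deficit < 1:
            raise ValueError("resorption_deficit must be in [0, 1)")


@dataclass(frozen=True)
class SerumSeries:
    """Timed serum ethanol concentrations for one subject."""

    subject: str
    samples: tuple[tuple[float, float], ...]  # (time_min, conc_gL)
    timepoint_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        if any(c < 0 for _, c in self.samples):
            raise ValueError("concentrations must be >= 0")
        if self.timepoint_labels and len(self.timepoint_labels) != len(self.samples):
            raise ValueError("one label per sample required")

    @property
    def times_min(self) -> np.ndarray:
        return np.array([t for t, _ in self.samples])

    @property
    def conc_gL(self) -> np.ndarray:
        return np.array([c for _, c in self.samples])


def blood_from_serum(
    serum_gL: float, factor: float = k.SERUM_BLOOD_FACTOR
) -> float:
    """Whole-blood alcohol (g/kg) from serum concentration (g/L)."""
    if serum_gL < 0:
        raise ValueError("serum concentration must be >= 0")
    return serum_gL / factor


def serum_from_blood(
    blood_gkg: float, factor: float = k.SERUM_BLOOD_FACTOR
) -> float:
    """Inverse of :func:`blood_from_serum`."""
    if blood_gkg < 0:
        raise ValueError("blood concentration must be >= 0")
    return blood_gkg * factor


def widmark_dose_grams(p: PKParams) -> float:
    """Grams of ethanol to ingest to reach the target BAC.

    ``grams = target_bac * body_mass * r / (1 - resorption_deficit)``.
    """
    return (
        p.target_bac_gkg * p.body_mass_kg * p.r_factor / (1.0 - p.resorption_deficit)
    )


def dose_to_beverage_ml(
    grams: float, abv: float, ethanol_density: float = 0.789
) -> float:
    """Beverage volume (mL) supplying ``grams`` of ethanol."""
    if abv <= 0 or ethanol_density <= 0:
        raise ValueError("abv and ethanol_density must be > 0")
    return grams / (ethanol_density * abv)


def _summary(values: np.ndarray) -> dict[str, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    if sd <= 1e-12 * abs(mean):  # constant series up to fp residue
        sd = 0.0
    return {
        "max": float(np.max(values)),
        "min": float(np.min(values)),
        "range": float(np.max(values) - np.min(values)),
        "cv": sd / mean if mean != 0 else 0.0,
    }


def compare_matrices(
    brain: pd.DataFrame,
    serum: dict[str, SerumSeries] | list[SerumSeries],
    pairing_tol_min: float = DEFAULT_PAIRING_TOL_MIN,
) -> dict:
    """Descriptive brain-vs-serum comparison (no significance testing).

    ``brain`` needs columns ``subject, time_min, conc_gL``. Per subject the
    report holds max/min/range/CV for each matrix, brain/serum ratios at
    nearest-time pairings (within ``pairing_tol_min``), and a flatness ratio
    CV_brain / CV_serum (defined as 1 when both curves are constant).
    """
    if isinstance(serum, list):
        serum = {s.subject: s for s in serum}
    report: dict = {"subjects": {}, "overall": {}}
    for subject, grp in brain.groupby("subject"):
        if subject not in serum:
            continue
        ss = serum[subject]
        if len(grp) < 2 or len(ss.samples) < 2:
            raise ValueError(f"need >= 2 timepoints per matrix for {subject}")
        b_t = grp["time_min"].to_numpy(dtype=float)
        b_c = grp["conc_gL"].to_numpy(dtype=float)
        if b_t.max() < ss.times_min.min() or b_t.min() > ss.times_min.max():
            raise ValueError(f"brain and serum series do not overlap for {subject}")
        pairs = []
        for (t, c), label in zip(
            ss.samples, ss.timepoint_labels or [""] * len(ss.samples)
        ):
            i = int(np.argmin(np.abs(b_t - t)))
            if abs(b_t[i] - t) <= pairing_tol_min:
                pairs.append(
                    {
                        "timepoint": label,
                        "serum_time_min": t,
                        "brain_time_min": float(b_t[i]),
                        "serum_gL": c,
                        "brain_gL": float(b_c[i]),
                        "brain_over_serum": float(b_c[i] / c) if c > 0 else np.nan,
                    }
                )
        bsum, ssum = _summary(b_c), _summary(ss.conc_gL)
        if bsum["cv"] == 0 and ssum["cv"] == 0:
            flatness = 1.0
        elif ssum["cv"] == 0:
            flatness = np.inf
        else:
            flatness = bsum["cv"] / ssum["cv"]
        report["subjects"][subject] = {
            "brain": bsum,
            "serum": ssum,
            "pairs": pairs,
            "flatness_cv_ratio": flatness,
        }
    subs = report["subjects"]
    if subs:
        report["overall"] = {
            "brain_max_gL": max(s["brain"]["max"] for s in subs.values()),
            "brain_min_gL": min(s["brain"]["min"] for s in subs.values()),
            "serum_max_gL": max(s["serum"]["max"] for s in subs.values()),
        }
    return report
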