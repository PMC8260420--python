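"""Plain-text I/O: spectra, tissue fractions, serum series, study tables.

All on-disk formats are human-readable (CSV + JSON sidecars). The two study
tables — per-voxel ethanol concentrations with serum draws interleaved, and
the segmented voxel compositions with their water contents — ship with the
package and load as DataFrames.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import VoxelComposition
from .serum_pk import SerumSeries
from .spectral_model import AcquisitionParams
from .synthetic import AcquiredSpectrum


def load_table1() -> pd.DataFrame:
    """Interleaved brain and serum ethanol concentrations (g/L).

    Long format: matrix (brain|serum), region, cycle, timepoint (T1-T5 for
    serum), approximate clock time in minutes after end of drinking,
    subject, concentration. Brain values are normalized to the voxel's
    water volume fraction.
    """
    with resources.files("ethanolmrs.data").joinpath(
        "table1_ethanol_concentrations.csv"
    ).open() as fh:
        df = pd.read_csv(fh, dtype={"region": "string", "timepoint": "string"})
    return df


def load_table2() -> pd.DataFrame:
    """Segmented GM/WM/CSF percentages and printed water contents."""
    with resources.files("ethanolmrs.data").joinpath(
        "table2_voxel_composition.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def serum_series_from_table1(df: pd.DataFrame | None = None) -> dict[str, SerumSeries]:
    if df is None:
        df = load_table1()
    serum = df[df["matrix"] == "serum"]
    out = {}
    for subject, grp in serum.groupby("subject"):
        grp = grp.sort_values("time_min")
        out[subject] = SerumSeries(
            subject,
            tuple(zip(grp["time_min"].astype(float), grp["conc_gL"].astype(float))),
            tuple(grp["timepoint"]),
        )
    return out


def brain_table_from_table1(df: pd.DataFrame | None = None) -> pd.DataFrame:
    if df is None:
        df = load_table1()
    return df[df["matrix"] == "brain"].reset_index(drop=True)


def compositions_from_table2(
    df: pd.DataFrame | None = None,
) -> dict[tuple[str, int, str], VoxelComposition]:
    """VoxelComposition per (subject, cycle, region), fractions as printed."""
    if df is None:
        df = load_table2()
    from .synthetic import VOXEL_ML

    out = {}
    for row in df.itertuples():
        out[(row.subject, int(row.cycle), row.region)] = VoxelComposition(
            row.gm_pct / 100.0,
            row.wm_pct / 100.0,
            row.csf_pct / 100.0,
            VOXEL_ML.get(row.region, 8.0),
            row.region,
        )
    return out


def save_spectrum(spec: AcquiredSpectrum, stem: str | Path) -> tuple[Path, Path]:
    """Write <stem>.csv (ppm,intensity) + <stem>.json metadata sidecar."""
    stem = Path(stem)
    csv_path, json_path = stem.with_suffix(".csv"), stem.with_suffix(".json")
    pd.DataFrame({"ppm": spec.grid, "intensity": spec.intensity}).to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    json_path.write_text(
        json.dumps(
            {
                "voxel_id": spec.voxel_id,
                "is_water_reference": spec.is_water_reference,
                "field_mhz": spec.params.field_mhz,
                "te_ms": spec.params.te_ms,
                "reference_ppm": spec.params.reference_ppm,
            },
            indent=2,
        )
    )
    return csv_path, json_path


def load_spectrum(stem: str | Path) -> AcquiredSpectrum:
    stem = Path(stem)
    df = pd.read_csv(stem.with_suffix(".csv"), float_precision="round_trip")
    meta = json.loads(stem.with_suffix(".json").read_text())
    grid = df["ppm"].to_numpy()
    params = AcquisitionParams(
        field_mhz=meta["field_mhz"],
        te_ms=meta["te_ms"],
        grid=grid,
        reference_ppm=meta["reference_ppm"],
    )
    return AcquiredSpectrum(
        grid,
        df["intensity"].to_numpy(),
        params,
        meta["voxel_id"],
        meta["is_water_reference"],
    )


def save_serum_series(series: dict[str, SerumSeries], path: str | Path) -> Path:
    rows = []
    for s in series.values():
        labels = s.timepoint_labels or [""] * len(s.samples)
        for (t, c), label in zip(s.samples, labels):
            rows.append(
                {
                    "subject": s.subject,
                    "timepoint": label,
                    "time_min": t,
                    "serum_g_per_L": c,
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_serum_series(path: str | Path) -> dict[str, SerumSeries]:
    df = pd.read_csv(path, dtype={"timepoint": "string"})
    out = {}
    for subject, grp in df.groupby("subject"):
        grp = grp.sort_values("time_min")
        labels = tuple(
            "" if pd.isna(v) else str(v) for v in grp["timepoint"]
        )
        out[subject] = SerumSeries(
            str(subject),
            tuple(
                zip(grp["time_min"].astype(float), grp["serum_g_per_L"].astype(float))
            ),
            labels if any(labels) else (),
        )
    return out


def load_tissue_fractions(path: str | Path) -> pd.DataFrame:
    """Tissue-fraction CSV: subject,cycle,region,gm_pct,wm_pct,csf_pct."""
    df = pd.read_csv(path)
    required = {"subject", "cycle", "region", "gm_pct", "wm_pct", "csf_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tissue fraction file lacks columns {sorted(missing)}")
    return df
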