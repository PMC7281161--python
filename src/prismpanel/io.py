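"""Readers and writers for the pipeline's tabular interchange formats.

All tables are plain CSV/TSV (delimiter chosen by file extension).  Readers
validate the schema up front and report offending columns and row numbers;
writers emit deterministic, sorted TSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from prismpanel.srm_quant import ResponseCurve

TRANSITION_COLUMNS = (
    "peptide_id", "protein_id", "sample_id",
    "light_area", "heavy_area", "apex_intensity", "background_noise",
    "heavy_spike_amol_per_ug",
)
CALIBRATION_COLUMNS = (
    "peptide_id", "protein_id", "spike_level_amol_per_ug", "replicate",
    "hl_ratio", "apex_intensity", "background_noise",
)

COHORT_CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "race": ("AA", "CA_other"),
    "psa_dx": ("<10", "10-20", ">20"),
    "clinical_t": ("T1-T2a", "T2b-T2c", "T3a-T4"),
    "biopsy_grade": ("<=6", "7", "8-10"),
    "nccn": ("low", "intermediate", "high"),
    "path_t": ("pT2", "pT3-4"),
    "grade_group": ("1", "2", "3", "4", "5"),
    "margin": ("neg", "pos"),
    "outcome": ("nonevent", "BCR", "DM"),
}

#: Nonevent status requires at least 10 years of post-surgery follow-up.
MIN_NONEVENT_FOLLOWUP_MONTHS = 120.0


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _check_numeric(df: pd.DataFrame, columns: Iterable[str], path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} "
                f"in column {col!r} at line {row}"
            )
        df[col] = coerced
    return df


def read_transition_report(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-measurement transition report."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = set(TRANSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    numeric = ("light_area", "heavy_area", "apex_intensity",
               "background_noise", "heavy_spike_amol_per_ug")
    df = _check_numeric(df, numeric, path)
    dup = df.duplicated(subset=["peptide_id", "sample_id"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 2
        raise ValueError(f"{path}: duplicate peptide x sample row at line {row}")
    return df


def read_calibration_table(
    path: str | Path, levels: Iterable[float] | None = None
) -> pd.DataFrame:
    """Read and validate a calibration-series table.

    When ``levels`` is given, every spike level must belong to the declared
    level set.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = set(CALIBRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    numeric = ("spike_level_amol_per_ug", "replicate", "hl_ratio",
               "apex_intensity", "background_noise")
    df = _check_numeric(df, numeric, path)
    dup = df.duplicated(subset=["peptide_id", "spike_level_amol_per_ug", "replicate"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 2
        raise ValueError(
            f"{path}: duplicate peptide x level x replicate row at line {row}"
        )
    if levels is not None:
        declared = np.asarray(sorted(levels), dtype=float)
        found = df["spike_level_amol_per_ug"].unique()
        stray = [lv for lv in found
                 if not np.isclose(declared, lv).any()]
        if stray:
            raise ValueError(f"{path}: spike level(s) {stray} outside declared set")
    return df


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a patient cohort table.

    Categorical fields are checked against their allowed levels (missing
    values pass).  A nonevent with under 120 months of follow-up violates
    the outcome definition and triggers a warning, not an error.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if "patient_id" not in df.columns or "outcome" not in df.columns:
        raise ValueError(f"{path}: cohort table needs patient_id and outcome columns")
    for col, allowed in COHORT_CATEGORICAL_LEVELS.items():
        if col not in df.columns:
            continue
        values = df[col].dropna().astype(str)
        bad = ~values.isin(allowed)
        if bad.any():
            raise ValueError(
                f"{path}: unknown level {values[bad].iloc[0]!r} in column "
                f"{col!r} (allowed: {allowed})"
            )
    if {"followup"}.issubset(df.columns):
        short = (df["outcome"] == "nonevent") & (
            df["followup"] < MIN_NONEVENT_FOLLOWUP_MONTHS
        )
        if short.any():
            warnings.warn(
                f"{int(short.sum())} nonevent patient(s) with follow-up under "
                f"{MIN_NONEVENT_FOLLOWUP_MONTHS:.0f} months"
            )
    return df


def write_curves(curves: Mapping[str, ResponseCurve], path: str | Path) -> None:
    """Write fitted response curves as a sorted TSV."""
    rows = []
    for pep in sorted(curves):
        c = curves[pep]
        rows.append(
            {
                "peptide_id": pep,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "lod": c.lod if c.lod is not None else "NA",
                "loq": c.loq if c.loq is not None else "NA",
                "c_light_matrix": c.c_light_matrix
                if c.c_light_matrix is not None else "NA",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_curves(path: str | Path) -> dict[str, ResponseCurve]:
    """Read response curves written by :func:`write_curves`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    curves = {}
    for row in df.itertuples(index=False):
        curves[row.peptide_id] = ResponseCurve(
            peptide_id=row.peptide_id,
            slope=float(row.slope),
            intercept=float(row.intercept),
            r_squared=float(row.r_squared),
            lod=None if pd.isna(row.lod) else float(row.lod),
            loq=None if pd.isna(row.loq) else float(row.loq),
            c_light_matrix=None if pd.isna(row.c_light_matrix)
            else float(row.c_light_matrix),
        )
    return curves


def write_matrix(
    conc: pd.DataFrame, flags: pd.DataFrame | None, path: str | Path
) -> None:
    """Write a protein x sample concentration matrix (long TSV with QC flags)."""
    long = conc.stack().rename("c_endogenous_amol_per_ug").reset_index()
    long.columns = ["protein_id", "sample_id", "c_endogenous_amol_per_ug"]
    if flags is not None:
        fl = flags.stack().rename("qc_flag").reset_index()
        fl.columns = ["protein_id", "sample_id", "qc_flag"]
        long = long.merge(fl, on=["protein_id", "sample_id"], how="left")
    long.sort_values(["protein_id", "sample_id"]).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a concentration matrix written by :func:`write_matrix`."""
    long = pd.read_csv(path, sep="\t")
    conc = long.pivot(index="protein_id", columns="sample_id",
                      values="c_endogenous_amol_per_ug")
    flags = None
    if "qc_flag" in long.columns:
        flags = long.pivot(index="protein_id", columns="sample_id",
                           values="qc_flag")
    return conc.sort_index().sort_index(axis=1), flags
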