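"""Isotope-dilution SRM quantification via calibration (response) curves.

Quantification follows the standard heavy-spike design: a stable-isotope
labelled ("heavy") peptide standard is spiked into a pooled tissue matrix at a
series of known concentrations and the heavy-over-light (H/L) total peak-area
ratio is regressed on the spike concentration,

    H/L = slope * C_heavy + intercept.

Because the pooled matrix contributes a fixed endogenous light concentration,
the fitted curve also encodes that concentration: at the intermediate spike
levels the light concentration is estimated as
``C_light = C_heavy / (H/L - intercept)`` and averaged.  For a study sample
with heavy spike ``C_heavy`` and measured light-over-heavy ratio L/H, the
endogenous concentration is back-calculated by inverting the curve:

    C_endo = ((L/H * C_heavy / C_light) - intercept) / slope     [amol/ug]

Limits of detection and quantification are per-assay calibration levels: the
LOD is the lowest spike level whose signal-to-noise ratio (peak apex over the
highest background in a +/-15 s retention-time window) reaches 3, the LOQ the
lowest level reaching S/N 10 with a replicate CV of the H/L ratio below 20%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

#: Heavy-spike concentrations (amol/ug) of the 12-point calibration series.
CALIBRATION_LEVELS: tuple[float, ...] = (
    0.0, 0.6, 3.0, 12.0, 60.0, 300.0, 1500.0, 3000.0,
    6000.0, 12000.0, 24000.0, 48000.0,
)

#: Spike levels used to estimate the endogenous light concentration of the
#: pooled calibration matrix.
MATRIX_ESTIMATION_LEVELS: tuple[float, ...] = (300.0, 1500.0, 3000.0)

#: Sentinel for an S/N ratio with zero background but non-zero signal.
INFINITE_SNR = math.inf

QC_OK = "ok"
QC_BELOW_LOD = "below_lod"
QC_BELOW_LOQ = "below_loq"
QC_NEGATIVE_CLAMPED = "negative_clamped"
QC_MISSING = "missing"


@dataclass(frozen=True)
class CalibrationPoint:
    """One replicate injection of one heavy-spike level for one peptide."""

    peptide_id: str
    spike_conc: float      # heavy concentration, amol/ug
    replicate: int
    hl_ratio: float        # heavy-over-light peak-area ratio
    apex_intensity: float = np.nan
    background_noise: float = np.nan

    def __post_init__(self) -> None:
        if self.spike_conc < 0:
            raise ValueError(f"negative spike concentration: {self.spike_conc}")
        if np.isfinite(self.hl_ratio) and self.hl_ratio < 0:
            raise ValueError(f"negative H/L ratio: {self.hl_ratio}")


@dataclass
class ResponseCurve:
    """Fitted calibration curve for one peptide assay.

    ``lod``/``loq`` are calibration levels in amol/ug, or ``None`` when no
    level met the signal-to-noise (and CV) requirements.  ``c_light_matrix``
    is the endogenous light-peptide concentration of the pooled matrix the
    curve was acquired in.
    """

    peptide_id: str
    slope: float           # per (amol/ug)
    intercept: float       # dimensionless (H/L at zero spike)
    r_squared: float
    lod: float | None = None
    loq: float | None = None
    c_light_matrix: float | None = None

    def __post_init__(self) -> None:
        if self.lod is not None and self.loq is not None and self.lod > self.loq:
            raise ValueError(
                f"{self.peptide_id}: LOD {self.lod} exceeds LOQ {self.loq}"
            )


@dataclass(frozen=True)
class RatioMeasurement:
    """One sample x peptide light-over-heavy observation."""

    peptide_id: str
    sample_id: str
    lh_ratio: float        # light-over-heavy peak-area ratio
    c_heavy_spiked: float  # heavy spike concentration in the sample, amol/ug


@dataclass(frozen=True)
class ConcentrationResult:
    """Back-calculated endogenous concentration with its QC flag."""

    peptide_id: str
    sample_id: str
    c_endogenous: float    # amol/ug
    qc_flag: str


def compute_snr(apex_intensity: float, background_noise: float) -> float:
    """Signal-to-noise ratio: peak apex over the highest nearby background.

    Returns ``math.inf`` when the background is zero but signal is present;
    zero apex with zero background gives an S/N of 0 (no detectable signal).

    >>> compute_snr(300, 100)
    3.0
    """
    if apex_intensity < 0 or background_noise < 0:
        raise ValueError("apex intensity and background noise must be >= 0")
    if background_noise == 0:
        return INFINITE_SNR if apex_intensity > 0 else 0.0
    return apex_intensity / background_noise


def _points_frame(points: Iterable[CalibrationPoint] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        return points
    return pd.DataFrame(
        {
            "peptide_id": [p.peptide_id for p in points],
            "spike_conc": [p.spike_conc for p in points],
            "replicate": [p.replicate for p in points],
            "hl_ratio": [p.hl_ratio for p in points],
            "apex_intensity": [p.apex_intensity for p in points],
            "background_noise": [p.background_noise for p in points],
        }
    )
    # callers pass either dataclass records or an equivalent DataFrame


def fit_response_curve(
    points: Iterable[CalibrationPoint] | pd.DataFrame,
    weighting: str | None = None,
) -> ResponseCurve:
    """Least-squares fit of H/L ratio on heavy spike concentration.

    All replicate points with finite ratios enter the fit (the full
    3-replicate design, not level means — identical in the noiseless case).
    Requires at least 3 distinct spike levels.

    ``weighting=None`` is ordinary least squares.  ``"1/x"`` and ``"1/x2"``
    apply the weighted fits standard for isotope-dilution calibration over a
    wide dynamic range: ratio noise is roughly proportional to signal, so
    equal weights let the highest spike levels dominate and leave the
    intercept poorly determined, whereas 1/x^2 weighting equalizes relative
    residuals.  Weighted fits exclude the zero-concentration blank (its
    weight is undefined).
    """
    df = _points_frame(points)
    df = df[np.isfinite(df["hl_ratio"])]
    if weighting not in (None, "1/x", "1/x2"):
        raise ValueError("weighting must be None, '1/x' or '1/x2'")
    if weighting is not None:
        df = df[df["spike_conc"] > 0]
    if df["spike_conc"].nunique() < 3:
        raise ValueError("need >= 3 distinct spike levels with finite ratios")
    if np.isclose(df["spike_conc"].std(), 0):
        raise ValueError("all spike levels identical: singular fit")
    x = df["spike_conc"].to_numpy(dtype=float)
    y = df["hl_ratio"].to_numpy(dtype=float)
    if weighting is None:
        w = np.ones_like(x)
    else:
        w = 1.0 / x if weighting == "1/x" else 1.0 / x**2
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - np.sum(w * resid**2) / ss_tot if ss_tot > 0 else 1.0
    peptide = str(df["peptide_id"].iloc[0]) if "peptide_id" in df else ""
    return ResponseCurve(
        peptide_id=peptide,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
    )


def fit_calibration_curves(
    calibration: pd.DataFrame,
    weighting: str | None = "1/x2",
    levels: Iterable[float] = MATRIX_ESTIMATION_LEVELS,
) -> dict[str, "ResponseCurve"]:
    """Fit per-peptide response curves with LOD/LOQ and matrix light estimate.

    ``calibration`` is a long table with a ``peptide_id`` column and either a
    ``spike_conc`` or ``spike_level_amol_per_ug`` level column.  The default
    1/x^2 weighting is the practitioner standard for wide-range
    isotope-dilution calibration (see :func:`fit_response_curve`).
    """
    df = calibration.rename(
        columns={"spike_level_amol_per_ug": "spike_conc"}
    )
    curves: dict[str, ResponseCurve] = {}
    for pep, grp in df.groupby("peptide_id"):
        curve = fit_response_curve(grp, weighting=weighting)
        curve.peptide_id = str(pep)
        curve.lod, curve.loq = determine_lod_loq(grp)
        curve.c_light_matrix = estimate_matrix_light_conc(curve, grp, levels)
        curves[str(pep)] = curve
    return curves


def determine_lod_loq(
    points: Iterable[CalibrationPoint] | pd.DataFrame,
    *,
    snr_lod: float = 3.0,
    snr_loq: float = 10.0,
    max_cv: float = 0.20,
) -> tuple[float | None, float | None]:
    """Lowest calibration levels meeting the S/N (and replicate-CV) rules.

    Per level, replicate S/N values are summarised by their median and the CV
    is the sample standard deviation over the mean of the replicate H/L
    ratios.  The LOD is the lowest non-zero level with median S/N >= 3; the
    LOQ additionally requires median S/N >= 10 and CV < 20%.  Levels that
    never qualify give a ``None`` sentinel (an assay whose limits cannot be
    determined, e.g. under heavy-channel interference).
    """
    df = _points_frame(points)
    if df.empty:
        raise ValueError("no calibration levels provided")
    lod: float | None = None
    loq: float | None = None
    for level, grp in df[df["spike_conc"] > 0].groupby("spike_conc", sort=True):
        snr = np.median(
            [compute_snr(a, b) for a, b in zip(grp["apex_intensity"], grp["background_noise"])]
        )
        ratios = grp["hl_ratio"].to_numpy(dtype=float)
        mean = ratios.mean()
        cv = ratios.std(ddof=1) / mean if len(ratios) > 1 and mean > 0 else 0.0
        if lod is None and snr >= snr_lod:
            lod = float(level)
        if loq is None and snr >= snr_loq and cv < max_cv:
            loq = float(level)
    if lod is not None and loq is not None and loq < lod:
        # an S/N>=10 level below the first S/N>=3 level cannot occur with
        # monotone response; guard against pathological inputs anyway
        lod = loq
    return lod, loq


def estimate_matrix_light_conc(
    curve: ResponseCurve,
    points: Iterable[CalibrationPoint] | pd.DataFrame,
    levels: Iterable[float] = MATRIX_ESTIMATION_LEVELS,
) -> float:
    """Endogenous light concentration of the pooled calibration matrix.

    At each requested spike level the measured mean H/L ratio, corrected for
    the fitted intercept, gives ``C_light = C_heavy / (H/L - intercept)``;
    the arithmetic mean of the per-level estimates is returned.  Levels with
    a non-positive corrected ratio (or no data) are excluded; an error is
    raised only if every level is unusable.
    """
    df = _points_frame(points)
    estimates = []
    for level in levels:
        grp = df[np.isclose(df["spike_conc"], level)]
        if grp.empty:
            continue
        corrected = grp["hl_ratio"].mean() - curve.intercept
        if corrected <= 0:
            continue
        estimates.append(level / corrected)
    if not estimates:
        raise ValueError(
            f"no usable spike levels among {tuple(levels)} to estimate "
            "the matrix light concentration"
        )
    return float(np.mean(estimates))


def endogenous_concentration(
    m: RatioMeasurement, curve: ResponseCurve
) -> ConcentrationResult:
    """Back-calculate the endogenous concentration of one measurement.

    Inverts the response curve:
    ``C_endo = ((L/H * C_heavy / C_light) - intercept) / slope``.
    Negative back-calculations are clamped to 0 and flagged; concentrations
    below the assay LOD/LOQ keep their value but carry the corresponding
    flag.
    """
    if curve.slope is None or not np.isfinite(curve.slope) or curve.slope <= 0:
        raise ValueError(f"{curve.peptide_id}: unusable curve slope {curve.slope}")
    if curve.c_light_matrix is None or curve.c_light_matrix <= 0:
        raise ValueError(
            f"{curve.peptide_id}: matrix light concentration undefined"
        )
    if m.c_heavy_spiked is None or not np.isfinite(m.c_heavy_spiked) or m.c_heavy_spiked <= 0:
        raise ValueError(f"{m.sample_id}/{m.peptide_id}: missing heavy spike concentration")
    if not np.isfinite(m.lh_ratio):
        return ConcentrationResult(m.peptide_id, m.sample_id, np.nan, QC_MISSING)

    c = ((m.lh_ratio * m.c_heavy_spiked / curve.c_light_matrix) - curve.intercept) / curve.slope
    flag = QC_OK
    if c < 0:
        c, flag = 0.0, QC_NEGATIVE_CLAMPED
    elif curve.lod is not None and c < curve.lod:
        flag = QC_BELOW_LOD
    elif curve.loq is not None and c < curve.loq:
        flag = QC_BELOW_LOQ
    return ConcentrationResult(m.peptide_id, m.sample_id, float(c), flag)


def quantify_samples(
    report: pd.DataFrame,
    curves: Mapping[str, ResponseCurve],
    *,
    multi_peptide: str = "error",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn a transition report into a protein x sample concentration matrix.

    ``report`` must carry columns ``peptide_id, protein_id, sample_id,
    light_area, heavy_area, heavy_spike_amol_per_ug``.  The light-over-heavy
    ratio is the total-peak-area ratio ``light_area / heavy_area``.  Each
    protein is quantified through its designated surrogate peptide; with
    ``multi_peptide="mean"`` several peptides per protein are averaged
    instead of rejected.

    Returns ``(concentrations, qc_flags)`` as protein x sample DataFrames in
    sorted order.  A below-LOD/LOQ or clamped flag wins over ``ok`` when
    peptides are averaged.
    """
    required = {
        "peptide_id", "protein_id", "sample_id",
        "light_area", "heavy_area", "heavy_spike_amol_per_ug",
    }
    missing = required - set(report.columns)
    if missing:
        raise ValueError(f"transition report missing columns: {sorted(missing)}")
    if report.empty:
        empty = pd.DataFrame(dtype=float)
        return empty, empty.astype(object)

    dup = report.duplicated(subset=["peptide_id", "sample_id"])
    if dup.any():
        rows = report.loc[dup, ["peptide_id", "sample_id"]].iloc[0]
        raise ValueError(
            f"duplicate measurement for peptide {rows['peptide_id']!r} "
            f"in sample {rows['sample_id']!r}"
        )
    unknown = sorted(set(report["peptide_id"]) - set(curves))
    if unknown:
        raise KeyError(f"no response curve for peptide(s): {unknown}")
    if multi_peptide not in ("error", "mean"):
        raise ValueError("multi_peptide must be 'error' or 'mean'")
    per_protein = report.groupby("protein_id")["peptide_id"].nunique()
    if multi_peptide == "error" and (per_protein > 1).any():
        bad = per_protein[per_protein > 1].index.tolist()
        raise ValueError(
            f"multiple surrogate peptides for protein(s) {bad}; "
            "pass multi_peptide='mean' to roll them up"
        )

    records = []
    for row in report.itertuples(index=False):
        heavy = float(row.heavy_area)
        lh = float(row.light_area) / heavy if heavy > 0 else np.nan
        meas = RatioMeasurement(
            peptide_id=row.peptide_id,
            sample_id=row.sample_id,
            lh_ratio=lh,
            c_heavy_spiked=float(row.heavy_spike_amol_per_ug),
        )
        res = endogenous_concentration(meas, curves[row.peptide_id])
        records.append(
            (row.protein_id, row.sample_id, res.c_endogenous, res.qc_flag)
        )
    long = pd.DataFrame(records, columns=["protein_id", "sample_id", "c", "flag"])

    conc = long.pivot_table(
        index="protein_id", columns="sample_id", values="c", aggfunc="mean"
    ).sort_index().sort_index(axis=1)

    flag_rank = {QC_OK: 0, QC_BELOW_LOQ: 1, QC_BELOW_LOD: 2,
                 QC_NEGATIVE_CLAMPED: 3, QC_MISSING: 4}
    rank_flag = {v: k for k, v in flag_rank.items()}
    flags = (
        long.assign(rank=long["flag"].map(flag_rank))
        .pivot_table(index="protein_id", columns="sample_id", values="rank", aggfunc="max")
        .sort_index().sort_index(axis=1)
        .map(lambda r: rank_flag[int(r)] if np.isfinite(r) else QC_MISSING)
    )
    conc.index.name = flags.index.name = "protein_id"
    return conc, flags
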