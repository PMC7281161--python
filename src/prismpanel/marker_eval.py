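"""Per-marker evaluation: cohort descriptives, AUC, constrained cut-points,
PCA screening, and univariable survival analysis.

The constrained cut-point search is the central primitive here: for a marker
oriented so that higher values indicate the event, it scans every candidate
threshold (midpoints between consecutive sorted unique values, plus the two
infinite sentinels) and, among the thresholds whose negative predictive value
and specificity meet the configured floors, returns the one with the highest
sensitivity.  Ties are broken towards higher specificity, then towards the
larger threshold.  Confidence intervals for the selected cut-point come from
a nonparametric percentile bootstrap in which the full search is repeated on
each resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


@dataclass
class AUCResult:
    """Mann-Whitney AUC of one marker for one binary endpoint."""

    marker_id: str
    endpoint: str
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pos: int
    n_neg: int


@dataclass
class CutpointResult:
    """Constraint-satisfying optimal threshold for one oriented marker.

    ``direction`` records which side of the threshold is called positive:
    ``"high_risk"`` flags values >= cutpoint, ``"low_risk"`` flags values
    <= cutpoint.  ``feasible`` is False when no threshold met the NPV and
    specificity floors, in which case the metrics are NaN.
    """

    marker_id: str
    cutpoint: float
    direction: str
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    ci_low: float
    ci_high: float
    feasible: bool


# ---------------------------------------------------------------------------
# cohort descriptives


def summarize_cohort(
    cohort: pd.DataFrame,
    group_col: str = "outcome",
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-variable between-group tests mirroring a cohort 'Table 1'.

    Continuous variables are tested with one-way ANOVA and Kruskal-Wallis
    (both reported); categorical variables with the chi-square test without
    continuity correction, replaced by Fisher's exact test when any expected
    cell count is below 5 (2x2 tables only; larger sparse tables keep the
    chi-square with a note).  Rows with a missing value are dropped per
    variable (complete-case), and the exclusion count is reported.
    """
    groups = cohort[group_col].dropna().unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 outcome groups")
    rows = []
    for var in continuous:
        sub = cohort[[var, group_col]].dropna()
        samples = [g[var].to_numpy(dtype=float) for _, g in sub.groupby(group_col)]
        n_excluded = len(cohort) - len(sub)
        if any(len(np.unique(np.concatenate(samples))) < 2 for _ in [0]):
            rows.append((var, "anova", np.nan, np.nan, n_excluded,
                         "single distinct value; test skipped"))
            continue
        f, p_a = stats.f_oneway(*samples)
        h, p_k = stats.kruskal(*samples)
        rows.append((var, "anova", float(f), float(p_a), n_excluded, ""))
        rows.append((var, "kruskal_wallis", float(h), float(p_k), n_excluded, ""))
    for var in categorical:
        sub = cohort[[var, group_col]].dropna()
        table = pd.crosstab(sub[var], sub[group_col])
        n_excluded = len(cohort) - len(sub)
        if table.shape[0] < 2:
            rows.append((var, "chi_square", np.nan, np.nan, n_excluded,
                         "single distinct value; test skipped"))
            continue
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        note = ""
        test = "chi_square"
        if (expected < 5).any():
            if table.shape == (2, 2):
                _, p = stats.fisher_exact(table)
                chi2 = np.nan
                test = "fisher_exact"
            else:
                note = "expected cell < 5; chi-square retained (non-2x2 table)"
        rows.append((var, test, float(chi2), float(p), n_excluded, note))
    return pd.DataFrame(
        rows, columns=["variable", "test", "statistic", "p_value",
                       "n_excluded", "note"]
    )


# ---------------------------------------------------------------------------
# AUC


def _auc_from_ranks(values: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC via midranks."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(values)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def marker_auc(
    values: Sequence[float],
    labels: Sequence[int],
    *,
    marker_id: str = "",
    endpoint: str = "",
    B: int = 1000,
    seed: int | None = None,
) -> AUCResult:
    """AUC with percentile-bootstrap CI and Mann-Whitney p-value.

    The AUC is the tie-corrected Mann-Whitney statistic divided by
    ``n_pos * n_neg`` (probability that a random event subject scores above
    a random non-event, ties counting one half).  The 95% CI is a
    nonparametric percentile bootstrap over ``B`` resamples of the
    (value, label) pairs; degenerate single-class resamples are discarded.
    The p-value is the two-sided normal-approximation Mann-Whitney test of
    AUC = 0.5.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc = _auc_from_ranks(v, y)
    res = stats.mannwhitneyu(v[y == 1], v[y == 0], alternative="two-sided",
                             method="asymptotic")
    rng = np.random.default_rng(seed)
    n = len(v)
    boot = np.empty(B)
    boot[:] = np.nan
    for b in range(B):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        boot[b] = _auc_from_ranks(v[idx], yb)
    boot = boot[np.isfinite(boot)]
    lo, hi = (np.percentile(boot, [2.5, 97.5]) if len(boot) else (np.nan, np.nan))
    return AUCResult(
        marker_id=marker_id,
        endpoint=endpoint,
        auc=float(auc),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(res.pvalue),
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise type-I error threshold ``alpha / m`` for m markers."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# constrained cut-point search


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.empty(0)
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _metrics_at_thresholds(
    values: np.ndarray, labels: np.ndarray, thresholds: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised 2x2 metrics with the rule value >= threshold => positive."""
    order = np.argsort(values, kind="mergesort")
    sv = values[order]
    sy = labels[order]
    n_pos = sy.sum()
    n_neg = len(sy) - n_pos
    # subjects with value >= t: suffix counts starting at searchsorted(left)
    pos_cum = np.concatenate(([0], np.cumsum(sy)))          # positives with value < v[i]
    idx = np.searchsorted(sv, thresholds, side="left")
    tp = n_pos - pos_cum[idx]
    predicted_pos = len(sv) - idx
    fp = predicted_pos - tp
    fn = n_pos - tp
    tn = n_neg - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = tp / n_pos
        spec = tn / n_neg
        ppv = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        npv = np.where(tn + fn > 0, tn / np.maximum(tn + fn, 1), np.nan)
    return {"sens": sens, "spec": spec, "ppv": ppv, "npv": npv}


def _search_cutpoint(
    values: np.ndarray,
    labels: np.ndarray,
    min_npv: float,
    min_spec: float,
    strict: bool,
) -> tuple[float, dict[str, float]] | None:
    """Best feasible threshold, or None.  Assumes higher value => event."""
    thr = _candidate_thresholds(values)
    m = _metrics_at_thresholds(values, labels, thr)
    if strict:
        feasible = (m["npv"] > min_npv) & (m["spec"] > min_spec)
    else:
        feasible = (m["npv"] >= min_npv) & (m["spec"] >= min_spec)
    feasible &= np.isfinite(m["npv"])
    if not feasible.any():
        return None
    # lexicographic: max sensitivity, then max specificity, then largest cut
    keys = np.stack([m["sens"], m["spec"], thr])
    cand = np.flatnonzero(feasible)
    best = cand[np.lexsort((keys[2, cand], keys[1, cand], keys[0, cand]))[-1]]
    return float(thr[best]), {k: float(v[best]) for k, v in m.items()}


def constrained_cutpoint(
    values: Sequence[float],
    labels: Sequence[int],
    min_npv: float,
    min_spec: float,
    *,
    direction: str = "high_risk",
    strict: bool = False,
    marker_id: str = "",
    B: int = 1000,
    seed: int | None = None,
) -> CutpointResult:
    """Sensitivity-maximising threshold subject to NPV and specificity floors.

    Scans every midpoint between consecutive sorted unique marker values
    (plus +/-inf sentinels).  With ``direction="low_risk"`` the marker is
    internally negated so that low values flag the event, and the threshold
    is mapped back to the original scale.  Constraints are evaluated as
    "at least" (>=) by default; ``strict=True`` switches to strict
    inequalities.  The bootstrap CI re-runs the full search on each of ``B``
    resamples and takes the 2.5/97.5 percentiles of the feasible replicate
    thresholds.
    """
    if not (0 <= min_npv <= 1 and 0 <= min_spec <= 1):
        raise ValueError("constraints must lie in [0, 1]")
    if direction not in ("high_risk", "low_risk"):
        raise ValueError("direction must be 'high_risk' or 'low_risk'")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    sign = 1.0 if direction == "high_risk" else -1.0
    hit = _search_cutpoint(sign * v, y, min_npv, min_spec, strict)
    if hit is None:
        return CutpointResult(marker_id, np.nan, direction, np.nan, np.nan,
                              np.nan, np.nan, np.nan, np.nan, feasible=False)
    cut, m = hit

    rng = np.random.default_rng(seed)
    n = len(v)
    boot = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        h = _search_cutpoint(sign * v[idx], yb, min_npv, min_spec, strict)
        if h is not None and np.isfinite(h[0]):
            boot.append(h[0])
    lo, hi = (np.percentile(boot, [2.5, 97.5]) if boot else (np.nan, np.nan))
    if direction == "low_risk":
        cut = -cut
        lo, hi = -hi, -lo
    return CutpointResult(
        marker_id=marker_id,
        cutpoint=cut,
        direction=direction,
        sensitivity=m["sens"],
        specificity=m["spec"],
        ppv=m["ppv"],
        npv=m["npv"],
        ci_low=float(lo),
        ci_high=float(hi),
        feasible=True,
    )


# ---------------------------------------------------------------------------
# PCA screening


@dataclass
class PCAPanelResult:
    eigenvalues: np.ndarray          # descending
    n_retained: int                  # eigenvalue > 1 (Kaiser rule)
    loadings: pd.DataFrame           # markers x retained components
    marker_ids: list[str] = field(default_factory=list)


def pca_panel_screen(marker_matrix: pd.DataFrame) -> PCAPanelResult:
    """Eigendecomposition of the marker correlation matrix (Kaiser screen).

    Components with eigenvalue > 1 are retained; loadings are eigenvectors
    scaled by the square root of their eigenvalue (correlation of each marker
    with the component).  Constant marker columns are rejected by name.
    """
    if marker_matrix.shape[1] < 2 or marker_matrix.shape[0] < 3:
        raise ValueError("need >= 2 markers and >= 3 samples")
    stds = marker_matrix.std(ddof=1)
    constant = stds[stds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant marker column(s): {constant}")
    corr = np.corrcoef(marker_matrix.to_numpy(dtype=float), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    retained = int((evals > 1.0).sum())
    loadings = pd.DataFrame(
        evecs[:, :retained] * np.sqrt(np.maximum(evals[:retained], 0)),
        index=marker_matrix.columns,
        columns=[f"PC{i + 1}" for i in range(retained)],
    )
    return PCAPanelResult(
        eigenvalues=evals,
        n_retained=retained,
        loadings=loadings,
        marker_ids=list(marker_matrix.columns),
    )


# ---------------------------------------------------------------------------
# survival


def km_estimate(times: Sequence[float], event_flags: Sequence[int]) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival estimate.

    Returns a DataFrame ``(time, survival, at_risk)`` with one row per
    distinct observed time; censored subjects leave the risk set without an
    event step.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=int)
    if (t < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "survival": surv.to_numpy(),
         "at_risk": at_risk.to_numpy()}
    )


def logrank_test(
    times: Sequence[float],
    event_flags: Sequence[int],
    group_labels: Sequence,
) -> tuple[float, float]:
    """Log-rank chi-square test of equal survival across groups (df = k-1)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=int)
    g = np.asarray(group_labels)
    if len(np.unique(g)) < 2:
        raise ValueError("need >= 2 groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)
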