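"""Multi-protein panel classifier: training, 0-100 scoring, bootstrapped
decision threshold, and added value over standard-of-care covariates.

The classifier is a multivariable logistic regression on the selected marker
panel; the reported score is the predicted event probability scaled to 0-100.
Its decision threshold is chosen by the same constrained search used for
single markers (maximise sensitivity subject to NPV and specificity floors),
with a percentile bootstrap CI in which the logistic model is re-fitted on
each resample before re-thresholding.  Added prognostic value over the
"biopsy" (age, race, NCCN risk) and "pathology" (pathological T, grade group,
surgical margin) standard-of-care covariate sets is assessed with likelihood
ratio tests of nested logistic models and with Cox proportional-hazards
models of the survival endpoints.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from prismpanel.marker_eval import (
    CutpointResult,
    _auc_from_ranks,
    _search_cutpoint,
    constrained_cutpoint,
)

#: Standard-of-care covariate sets the panel classifier augments.
SOC_BIOPSY = ("age_at_dx", "race", "nccn")
SOC_PATHOLOGY = ("path_t", "grade_group", "margin")


@dataclass
class SplitSpec:
    """Train/test partition rule: simple random split, floor(train_fraction*n)."""

    train_fraction: float = 0.7
    seed: int | None = None


@dataclass
class ThresholdResult:
    """Decision threshold (score units, 0-100) with its operating metrics."""

    threshold: float
    sensitivity: float
    specificity: float
    npv: float
    ppv: float
    ci_low: float
    ci_high: float
    feasible: bool


@dataclass
class ClassifierModel:
    """Fitted logistic panel classifier with its 0-100 scaling and threshold."""

    marker_ids: list[str]
    intercept: float
    coefficients: dict[str, float]
    scaling: str = "probability_x100"
    threshold: float | None = None
    threshold_ci: tuple[float, float] | None = None
    penalized: bool = False
    seed: int | None = None
    B: int | None = None
    selection_criteria: str | None = None

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        if d.get("threshold_ci") is not None:
            d["threshold_ci"] = tuple(d["threshold_ci"])
        return cls(**d)


def split_cohort(
    cohort: pd.DataFrame,
    spec: SplitSpec | None = None,
    *,
    outcome_col: str = "outcome",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple (non-stratified) random train/test split.

    Train size is ``floor(train_fraction * n)``; the two parts are disjoint
    and exhaustive and the partition is reproducible from the seed.  A
    single-class train or test set triggers a warning but not an error.
    """
    spec = spec or SplitSpec()
    n = len(cohort)
    if n < 10:
        raise ValueError("cohort too small to split")
    n_train = int(np.floor(spec.train_fraction * n))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train = cohort.iloc[np.sort(perm[:n_train])]
    test = cohort.iloc[np.sort(perm[n_train:])]
    if outcome_col in cohort.columns:
        for name, part in (("train", train), ("test", test)):
            if part[outcome_col].nunique() < 2:
                warnings.warn(f"{name} split contains a single outcome class")
    return train, test


def _logit_fit(X: np.ndarray, y: np.ndarray):
    """Statsmodels MLE logistic fit; returns None when it fails to converge."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                disp=0, maxiter=200
            )
        except Exception:
            return None
    if not res.mle_retvals.get("converged", False):
        return None
    # runaway coefficients signal (quasi-)separation even when the optimizer
    # reports convergence
    if np.abs(res.params).max() > 1e3:
        return None
    return res


def univariable_select(
    train: pd.DataFrame,
    candidate_markers: Sequence[str],
    *,
    outcome_col: str = "event",
    p_max: float = 0.05,
    auc_min: float = 0.65,
) -> list[str]:
    """Markers passing the univariable logistic screen (p < p_max, AUC > auc_min).

    The p-value is the Wald test of the marker coefficient; the AUC is
    orientation-free (``max(a, 1 - a)`` of the raw Mann-Whitney AUC, which
    for a single monotone predictor equals the AUC of the fitted univariable
    model).  Both inequalities are strict.  Markers whose fit does not
    converge are excluded with a warning.
    """
    y = train[outcome_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcome has a single class")
    selected = []
    for marker in candidate_markers:
        x = train[marker].to_numpy(dtype=float)
        res = _logit_fit(x[:, None], y)
        if res is None:
            warnings.warn(f"univariable fit failed to converge for {marker}; excluded")
            continue
        p = float(res.pvalues[1])
        a = _auc_from_ranks(x, y)
        a = max(a, 1 - a)
        if p < p_max and a > auc_min:
            selected.append(marker)
    return selected


def fit_panel_classifier(
    train: pd.DataFrame,
    markers: Sequence[str],
    *,
    outcome_col: str = "event",
    ridge_alpha: float = 1.0,
) -> ClassifierModel:
    """Maximum-likelihood multivariable logistic fit of the marker panel.

    On perfect (or quasi-) separation and other convergence failures the fit
    falls back to an L2-penalised logistic regression (penalty strength
    ``ridge_alpha``) and the model is flagged ``penalized=True``.
    """
    if len(markers) < 1:
        raise ValueError("need at least one marker")
    X = train[list(markers)].to_numpy(dtype=float)
    y = train[outcome_col].to_numpy(dtype=int)
    const = [m for m, s in zip(markers, X.std(axis=0)) if s == 0]
    if const:
        raise ValueError(f"constant marker column(s): {const}")
    penalized = False
    res = _logit_fit(X, y)
    if res is not None:
        params = np.asarray(res.params, dtype=float)
    else:
        penalized = True
        clf = LogisticRegression(C=1.0 / ridge_alpha, solver="lbfgs",
                                 max_iter=1000)
        clf.fit(X, y)
        params = np.concatenate(([clf.intercept_[0]], clf.coef_[0]))
    return ClassifierModel(
        marker_ids=list(markers),
        intercept=float(params[0]),
        coefficients={m: float(b) for m, b in zip(markers, params[1:])},
        penalized=penalized,
    )


def score_patients(model: ClassifierModel, data: pd.DataFrame) -> pd.Series:
    """Classifier score: predicted event probability scaled to 0-100.

    Patients with a missing marker value receive a NaN score.
    """
    X = data[model.marker_ids].to_numpy(dtype=float)
    beta = np.array([model.coefficients[m] for m in model.marker_ids])
    eta = model.intercept + X @ beta
    scores = 100.0 * expit(eta)
    scores[~np.isfinite(X).all(axis=1)] = np.nan
    return pd.Series(scores, index=data.index, name="score")


def evaluate_at_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
) -> dict[str, float]:
    """2x2 operating characteristics with the rule score >= threshold => positive."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(s) == 0:
        raise ValueError("empty input")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = s >= threshold
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())

    def _ratio(a: int, b: int) -> float:
        return a / b if b > 0 else np.nan

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def bootstrap_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    *,
    min_npv: float = 0.90,
    min_spec: float = 0.35,
    B: int = 1000,
    seed: int | None = None,
    train: pd.DataFrame | None = None,
    model: ClassifierModel | None = None,
    outcome_col: str = "event",
) -> ThresholdResult:
    """Constraint-satisfying decision threshold with a bootstrap CI.

    The point estimate applies the constrained cut-point search (maximise
    sensitivity subject to NPV >= ``min_npv`` and specificity >=
    ``min_spec``) to the full-data scores.  The CI is the 2.5/97.5
    percentile of per-replicate optimal thresholds over ``B`` bootstrap
    resamples.  When ``train`` and ``model`` are supplied the logistic
    model is re-fitted on every resample before re-scoring and
    re-thresholding ("bootstrapped multivariable logistic regression");
    otherwise fixed scores are resampled and only the threshold search is
    repeated.
    """
    if not (0 <= min_npv <= 1 and 0 <= min_spec <= 1):
        raise ValueError("constraints must lie in [0, 1]")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    point = _search_cutpoint(s, y, min_npv, min_spec, strict=False)
    if point is None:
        return ThresholdResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                               np.nan, np.nan, feasible=False)
    cut, m = point

    rng = np.random.default_rng(seed)
    refit = train is not None and model is not None
    n = len(y)
    boot = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        if refit:
            sub = train.iloc[idx]
            try:
                mb = fit_panel_classifier(sub, model.marker_ids,
                                          outcome_col=outcome_col)
            except ValueError:
                continue
            sb = score_patients(mb, sub).to_numpy()
        else:
            sb = s[idx]
        h = _search_cutpoint(sb, yb, min_npv, min_spec, strict=False)
        if h is not None and np.isfinite(h[0]):
            boot.append(h[0])
    lo, hi = (np.percentile(boot, [2.5, 97.5]) if boot else (np.nan, np.nan))
    return ThresholdResult(
        threshold=float(cut),
        sensitivity=m["sens"],
        specificity=m["spec"],
        npv=m["npv"],
        ppv=m["ppv"],
        ci_low=float(lo),
        ci_high=float(hi),
        feasible=True,
    )


def compare_models_lrt(base_fit, augmented_fit) -> tuple[float, int, float]:
    """Likelihood ratio test of nested (base vs augmented) model fits.

    Accepts fitted statsmodels results (anything exposing ``llf``,
    ``df_model`` and ``nobs``).  Returns ``(chi2, df, p)`` with
    ``chi2 = 2 * (ll_full - ll_base)`` and df the parameter difference.
    """
    if int(base_fit.nobs) != int(augmented_fit.nobs):
        raise ValueError("models fitted on different numbers of observations")
    df = int(augmented_fit.df_model - base_fit.df_model)
    if df < 0:
        raise ValueError("augmented model has fewer parameters than base")
    chi2 = 2.0 * (augmented_fit.llf - base_fit.llf)
    if chi2 < -1e-6:
        raise ValueError("augmented model has lower likelihood; models not nested")
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p


def _build_cox_design(
    cohort: pd.DataFrame,
    soc_set: str,
    classifier_col: str,
    classifier_form: str,
    threshold: float | None,
) -> pd.DataFrame:
    cols = {}
    if soc_set == "biopsy":
        cols["age_at_dx"] = cohort["age_at_dx"].astype(float)
        cols["race_aa"] = (cohort["race"] == "AA").astype(float)
        cols["nccn_intermediate"] = (cohort["nccn"] == "intermediate").astype(float)
        cols["nccn_high"] = (cohort["nccn"] == "high").astype(float)
    elif soc_set == "pathology":
        cols["path_t3_4"] = (cohort["path_t"] == "pT3-4").astype(float)
        cols["gg5"] = (cohort["grade_group"].astype(int) == 5).astype(float)
        cols["margin_pos"] = (cohort["margin"] == "pos").astype(float)
    else:
        raise ValueError("soc_set must be 'biopsy' or 'pathology'")
    if classifier_form == "dichotomous":
        if threshold is None:
            raise ValueError("dichotomous form requires a threshold")
        cols["classifier_high"] = (cohort[classifier_col] >= threshold).astype(float)
    elif classifier_form == "continuous":
        cols["classifier"] = cohort[classifier_col].astype(float)
    else:
        raise ValueError("classifier_form must be 'dichotomous' or 'continuous'")
    return pd.DataFrame(cols, index=cohort.index)


def cox_classifier(
    cohort: pd.DataFrame,
    *,
    duration_col: str,
    event_col: str,
    soc_set: str = "biopsy",
    classifier_col: str = "score",
    classifier_form: str = "dichotomous",
    threshold: float | None = None,
    ph_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cox PH model of a survival endpoint on SOC covariates plus the classifier.

    ``soc_set="biopsy"`` adjusts for age, race (AA vs CA/other) and NCCN risk
    stratum (intermediate/high vs low); ``"pathology"`` for pathological T
    (pT3-4 vs pT2), grade group (GG5 vs GG1-4) and surgical margin.  The
    classifier enters dichotomised at ``threshold`` or as a continuous score.
    Covariates without variation are dropped with a warning.  Returns the
    hazard-ratio table (HR, CI, p) and the scaled-Schoenfeld-residual
    proportional-hazards diagnostics (reported, not enforced).
    """
    design = _build_cox_design(cohort, soc_set, classifier_col,
                               classifier_form, threshold)
    keep = design.columns[design.std() > 0]
    dropped = sorted(set(design.columns) - set(keep))
    if dropped:
        warnings.warn(f"dropping covariate(s) without variation: {dropped}")
    df = design[keep].copy()
    df["_time"] = cohort[duration_col].astype(float)
    df["_event"] = cohort[event_col].astype(int)
    df = df.dropna()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception:
        # sparse event counts can defeat the unpenalized partial-likelihood
        # fit; retry with a small ridge penalty and flag it
        warnings.warn("Cox fit did not converge; retrying with ridge penalty 0.1")
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(df, duration_col="_time", event_col="_event")
    summary = cph.summary[
        ["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]
    ].rename(
        columns={
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "ci_low",
            "exp(coef) upper 95%": "ci_high",
            "p": "p_value",
        }
    )
    ph = proportional_hazard_test(cph, df, time_transform="rank").summary
    ph = ph.rename(columns={"test_statistic": "statistic", "p": "p_value"})
    ph["violates_ph"] = ph["p_value"] < ph_alpha
    return summary, ph
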