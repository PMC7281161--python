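"""End-to-end orchestration: quantification -> marker evaluation -> classifier.

``run_pipeline`` reproduces the study's analysis order on any cohort table
with marker columns: cohort descriptives, per-marker AUCs with a Bonferroni
significance threshold, constrained cut-points with Kaplan-Meier/log-rank
follow-up, PCA panel screening, and the train/test construction of the
0-100-scaled logistic panel classifier with its bootstrapped decision
threshold, likelihood-ratio added-value tests and Cox models.

Two entry modes exist upstream of the cohort: "raw" (transition report ->
response curves -> concentration matrix, via :mod:`prismpanel.srm_quant`)
and "matrix" (precomputed concentrations).  Marker abundances are analyzed
on a standardized log10 scale by default (see :func:`log10_zscore`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from prismpanel import classifier as clf
from prismpanel import marker_eval as me

ENDPOINTS = ("DM_vs_nonevent", "BCR_vs_nonevent", "highGG_vs_lowGG")


@dataclass
class PipelineConfig:
    """Stated analysis constants and switches, one place.

    Constraint pairs are (min NPV, min specificity): the classifier decision
    threshold uses (0.90, 0.35); single-marker cut-points use (0.80, 0.40)
    for the metastasis endpoint and (0.70, 0.30) for biochemical recurrence.
    ``auc_retain`` gates which markers proceed to cut-point analysis.
    """

    transform: str = "log10_zscore"      # or "none"
    classifier_constraints: tuple[float, float] = (0.90, 0.35)
    dm_marker_constraints: tuple[float, float] = (0.80, 0.40)
    bcr_marker_constraints: tuple[float, float] = (0.70, 0.30)
    auc_retain: float = 0.60
    gg_grouping: str = "3-5_vs_1-2"      # alternative: "4-5_vs_1-3"
    B: int = 1000
    alpha: float = 0.05
    n_markers_tested: int = 16
    train_fraction: float = 0.7
    selection_p_max: float = 0.05
    selection_auc_min: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        for pair in (self.classifier_constraints, self.dm_marker_constraints,
                     self.bcr_marker_constraints):
            if not all(0 <= v <= 1 for v in pair):
                raise ValueError("constraints must lie in [0, 1]")
        if self.B < 1:
            raise ValueError("B must be >= 1")


def log10_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-marker standardized log10 abundance (columns = markers).

    Zeros (e.g. clamped below-detection values) are replaced by half the
    smallest positive value of that marker before taking logs, a standard
    detection-floor imputation that keeps them lowest-ranked.
    """
    out = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float).copy()
        pos = x[x > 0]
        if len(pos) == 0:
            raise ValueError(f"marker {col!r} has no positive values")
        x[x <= 0] = pos.min() / 2.0
        lg = np.log10(x)
        sd = lg.std(ddof=1)
        if sd == 0:
            raise ValueError(f"marker {col!r} is constant after transform")
        out[col] = (lg - lg.mean()) / sd
    return pd.DataFrame(out, index=matrix.index)


def survival_endpoint(cohort: pd.DataFrame, endpoint: str) -> tuple[pd.Series, pd.Series]:
    """(duration, event) columns for distant-metastasis- or BCR-free survival."""
    if endpoint == "dm":
        event = (cohort["outcome"] == "DM").astype(int)
        time = np.where(event == 1, cohort["time_to_dm"], cohort["followup"])
    elif endpoint == "bcr":
        event = cohort["outcome"].isin(["BCR", "DM"]).astype(int)
        time = np.where(event == 1, cohort["time_to_bcr"], cohort["followup"])
    else:
        raise ValueError("endpoint must be 'dm' or 'bcr'")
    return pd.Series(time, index=cohort.index, name="time"), event


def endpoint_labels(
    cohort: pd.DataFrame, endpoint: str, gg_grouping: str = "3-5_vs_1-2"
) -> tuple[pd.DataFrame, pd.Series]:
    """Subset and binary labels for one of the three comparison endpoints."""
    if endpoint == "DM_vs_nonevent":
        sub = cohort[cohort["outcome"].isin(["DM", "nonevent"])]
        y = (sub["outcome"] == "DM").astype(int)
    elif endpoint == "BCR_vs_nonevent":
        sub = cohort[cohort["outcome"].isin(["BCR", "nonevent"])]
        y = (sub["outcome"] == "BCR").astype(int)
    elif endpoint == "highGG_vs_lowGG":
        gg = pd.to_numeric(cohort["grade_group"], errors="coerce")
        sub = cohort[gg.notna()]
        gg = gg[gg.notna()]
        high = (gg >= 3) if gg_grouping == "3-5_vs_1-2" else (gg >= 4)
        y = high.astype(int)
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return sub, y


def _soc_design(cohort: pd.DataFrame, soc_set: str) -> pd.DataFrame:
    """Dummy-encoded standard-of-care covariates for logistic base models."""
    cols = {}
    if soc_set == "biopsy":
        cols["age_at_dx"] = cohort["age_at_dx"].astype(float)
        cols["race_aa"] = (cohort["race"] == "AA").astype(float)
        cols["nccn_intermediate"] = (cohort["nccn"] == "intermediate").astype(float)
        cols["nccn_high"] = (cohort["nccn"] == "high").astype(float)
    elif soc_set == "pathology":
        cols["path_t3_4"] = (cohort["path_t"] == "pT3-4").astype(float)
        cols["gg5"] = (pd.to_numeric(cohort["grade_group"]) == 5).astype(float)
        cols["margin_pos"] = (cohort["margin"] == "pos").astype(float)
    else:
        raise ValueError("soc_set must be 'biopsy' or 'pathology'")
    return pd.DataFrame(cols, index=cohort.index)


def added_value_lrt(
    cohort: pd.DataFrame,
    labels: Sequence[int],
    score: Sequence[float],
    soc_set: str,
) -> dict:
    """Likelihood-ratio test of SOC base model vs base model + classifier score."""
    X_base = _soc_design(cohort, soc_set)
    y = np.asarray(labels, dtype=int)
    keep = X_base.columns[X_base.std() > 0]
    Xb = sm.add_constant(X_base[keep].to_numpy(), has_constant="add")
    Xa = sm.add_constant(
        np.column_stack([X_base[keep].to_numpy(), np.asarray(score, float)]),
        has_constant="add",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = sm.Logit(y, Xb).fit(disp=0, maxiter=200)
        aug = sm.Logit(y, Xa).fit(disp=0, maxiter=200)
    chi2, df, p = clf.compare_models_lrt(base, aug)
    auc_base = me._auc_from_ranks(np.asarray(base.predict(Xb)), y)
    auc_aug = me._auc_from_ranks(np.asarray(aug.predict(Xa)), y)
    return {
        "soc_set": soc_set, "chi2": chi2, "df": df, "p_value": p,
        "auc_base": float(auc_base), "auc_augmented": float(auc_aug),
    }


def run_pipeline(
    cohort: pd.DataFrame,
    markers: Sequence[str],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full marker-evaluation and classifier protocol on a cohort.

    ``cohort`` must contain the clinical columns plus one numeric column per
    marker (already transformed if desired).  Returns a report bundle dict;
    with ``outdir`` the tables are additionally written as TSV/JSON plus a
    structured log.  All randomness derives from ``config.seed``.
    """
    config = config or PipelineConfig()
    markers = list(markers)
    log: list[str] = []
    bundle: dict = {"config": config}

    # --- cohort descriptives -------------------------------------------------
    categorical = [c for c in ("race", "psa_dx", "clinical_t", "biopsy_grade",
                               "nccn", "path_t", "grade_group", "margin")
                   if c in cohort.columns]
    continuous = [c for c in ("age_at_dx", "followup") if c in cohort.columns]
    bundle["cohort_summary"] = me.summarize_cohort(
        cohort, "outcome", continuous=continuous, categorical=categorical
    )

    # --- per-marker AUCs (Table 2 analog) ------------------------------------
    bonf = me.bonferroni_threshold(config.alpha, config.n_markers_tested)
    bundle["bonferroni_threshold"] = bonf
    auc_rows = []
    for endpoint in ENDPOINTS:
        sub, y = endpoint_labels(cohort, endpoint, config.gg_grouping)
        for i, m in enumerate(markers):
            res = me.marker_auc(
                sub[m].to_numpy(), y.to_numpy(), marker_id=m, endpoint=endpoint,
                B=config.B, seed=config.seed + 1000 + i,
            )
            auc_rows.append(
                {"marker_id": m, "endpoint": endpoint, "auc": res.auc,
                 "ci_low": res.ci_low, "ci_high": res.ci_high,
                 "p_value": res.p_value, "significant": res.p_value < bonf,
                 "n_pos": res.n_pos, "n_neg": res.n_neg}
            )
    marker_table = pd.DataFrame(auc_rows)
    bundle["marker_auc"] = marker_table

    # --- constrained cut-points + survival (Tables 3-4 analog) ---------------
    cut_tables = {}
    km_tables = {}
    for endpoint, constraints, surv in (
        ("DM_vs_nonevent", config.dm_marker_constraints, "dm"),
        ("BCR_vs_nonevent", config.bcr_marker_constraints, "bcr"),
    ):
        sub, y = endpoint_labels(cohort, endpoint, config.gg_grouping)
        ep_auc = marker_table[marker_table["endpoint"] == endpoint]
        retained = ep_auc[
            np.maximum(ep_auc["auc"], 1 - ep_auc["auc"]) >= config.auc_retain
        ]["marker_id"].tolist()
        log.append(f"{endpoint}: {len(retained)} marker(s) with AUC >= "
                   f"{config.auc_retain} retained for cut-point analysis")
        rows = []
        for i, m in enumerate(retained):
            auc_m = float(ep_auc.set_index("marker_id").loc[m, "auc"])
            direction = "high_risk" if auc_m >= 0.5 else "low_risk"
            cp = me.constrained_cutpoint(
                sub[m].to_numpy(), y.to_numpy(), *constraints,
                direction=direction, marker_id=m, B=config.B,
                seed=config.seed + 2000 + i,
            )
            rows.append(
                {"marker_id": m, "cutpoint": cp.cutpoint,
                 "direction": cp.direction, "sensitivity": cp.sensitivity,
                 "specificity": cp.specificity, "ppv": cp.ppv, "npv": cp.npv,
                 "ci_low": cp.ci_low, "ci_high": cp.ci_high,
                 "feasible": cp.feasible}
            )
            if not cp.feasible:
                log.append(f"{endpoint}/{m}: no feasible cut-point under "
                           f"NPV>={constraints[0]}, spec>={constraints[1]}")
                continue
            time, event = survival_endpoint(cohort, surv)
            high = (cohort[m] >= cp.cutpoint if direction == "high_risk"
                    else cohort[m] <= cp.cutpoint)
            chi2, p = me.logrank_test(time, event, np.where(high, "high", "low"))
            km_tables[(endpoint, m)] = {
                "logrank_chi2": chi2, "logrank_p": p,
                "km_high": me.km_estimate(time[high], event[high]),
                "km_low": me.km_estimate(time[~high], event[~high]),
            }
        cut_tables[endpoint] = pd.DataFrame(rows)
    bundle["cutpoints"] = cut_tables
    bundle["survival"] = km_tables

    # --- PCA panel screen -----------------------------------------------------
    try:
        bundle["pca"] = me.pca_panel_screen(cohort[markers])
    except ValueError as err:
        log.append(f"PCA screen skipped: {err}")

    # --- classifier (train/test protocol) ------------------------------------
    dm_sub, dm_y = endpoint_labels(cohort, "DM_vs_nonevent", config.gg_grouping)
    dm = dm_sub.assign(event=dm_y)
    train, test = clf.split_cohort(
        dm, clf.SplitSpec(config.train_fraction, config.seed)
    )
    selected = clf.univariable_select(
        train, markers, outcome_col="event",
        p_max=config.selection_p_max, auc_min=config.selection_auc_min,
    )
    log.append(f"univariable screen selected {len(selected)} marker(s): {selected}")
    bundle["selected_markers"] = selected
    if not selected:
        log.append("no markers selected; classifier stage skipped")
        bundle["log"] = log
        _write_bundle(bundle, outdir)
        return bundle

    model = clf.fit_panel_classifier(train, selected, outcome_col="event")
    train_scores = clf.score_patients(model, train)
    thr = clf.bootstrap_threshold(
        train_scores.to_numpy(), train["event"].to_numpy(),
        min_npv=config.classifier_constraints[0],
        min_spec=config.classifier_constraints[1],
        B=config.B, seed=config.seed + 3000,
        train=train, model=model, outcome_col="event",
    )
    model.threshold = thr.threshold if thr.feasible else None
    model.threshold_ci = (thr.ci_low, thr.ci_high) if thr.feasible else None
    model.seed = config.seed
    model.B = config.B
    model.selection_criteria = (
        f"p<{config.selection_p_max}, AUC>{config.selection_auc_min}"
    )
    bundle["model"] = model
    bundle["threshold"] = thr
    if not thr.feasible:
        log.append("no feasible classifier threshold on training data")

    test_scores = clf.score_patients(model, test)
    train_auc = me.marker_auc(
        train_scores.to_numpy(), train["event"].to_numpy(),
        marker_id="classifier", endpoint="DM_vs_nonevent",
        B=config.B, seed=config.seed + 3100,
    )
    test_auc = me.marker_auc(
        test_scores.to_numpy(), test["event"].to_numpy(),
        marker_id="classifier", endpoint="DM_vs_nonevent",
        B=config.B, seed=config.seed + 3200,
    )
    evaluation = {
        "n_train": len(train), "n_test": len(test),
        "n_train_events": int(train["event"].sum()),
        "n_test_events": int(test["event"].sum()),
        "train_auc": train_auc.auc, "test_auc": test_auc.auc,
        "test_auc_ci": (test_auc.ci_low, test_auc.ci_high),
    }
    if thr.feasible:
        evaluation["train_metrics"] = clf.evaluate_at_threshold(
            train_scores.to_numpy(), train["event"].to_numpy(), thr.threshold
        )
        evaluation["test_metrics"] = clf.evaluate_at_threshold(
            test_scores.to_numpy(), test["event"].to_numpy(), thr.threshold
        )
    bundle["evaluation"] = evaluation

    # --- added value over SOC (LRT) and Cox models on the test cohort --------
    test_scored = test.assign(score=test_scores)
    lrt = {}
    cox = {}
    for soc in ("biopsy", "pathology"):
        needed = clf.SOC_BIOPSY if soc == "biopsy" else clf.SOC_PATHOLOGY
        if not set(needed).issubset(cohort.columns):
            log.append(f"SOC set {soc!r} incomplete; skipped")
            continue
        try:
            lrt[soc] = added_value_lrt(
                test_scored, test_scored["event"], test_scored["score"], soc
            )
        except Exception as err:  # small test sets can defeat the MLE
            log.append(f"LRT for SOC set {soc!r} failed: {err}")
        time, event = survival_endpoint(test_scored, "dm")
        surv_df = test_scored.assign(_t=time, _e=event)
        for form in ("dichotomous", "continuous"):
            if form == "dichotomous" and not thr.feasible:
                continue
            try:
                hr, ph = clf.cox_classifier(
                    surv_df, duration_col="_t", event_col="_e",
                    soc_set=soc, classifier_col="score",
                    classifier_form=form, threshold=model.threshold,
                )
                cox[(soc, form)] = {"hazard_ratios": hr, "ph_test": ph}
            except Exception as err:
                log.append(f"Cox model ({soc}, {form}) failed: {err}")
    bundle["lrt"] = lrt
    bundle["cox"] = cox
    bundle["log"] = log
    _write_bundle(bundle, outdir)
    return bundle


def _write_bundle(bundle: dict, outdir: str | Path | None) -> None:
    if outdir is None:
        return
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["cohort_summary"].to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
    bundle["marker_auc"].to_csv(out / "marker_auc.tsv", sep="\t", index=False)
    for endpoint, table in bundle.get("cutpoints", {}).items():
        table.to_csv(out / f"cutpoints_{endpoint}.tsv", sep="\t", index=False)
    for (endpoint, m), entry in bundle.get("survival", {}).items():
        entry["km_high"].to_csv(
            out / f"km_{endpoint}_{m}_high.tsv", sep="\t", index=False
        )
        entry["km_low"].to_csv(
            out / f"km_{endpoint}_{m}_low.tsv", sep="\t", index=False
        )
    if "model" in bundle:
        (out / "model.json").write_text(bundle["model"].to_json())

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        return str(o)

    report = {
        "selected_markers": bundle.get("selected_markers"),
        "evaluation": bundle.get("evaluation"),
        "lrt": bundle.get("lrt"),
        "bonferroni_threshold": bundle.get("bonferroni_threshold"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_default))
    (out / "log.txt").write_text("\n".join(bundle.get("log", [])) + "\n")
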