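"""Panel classifier: split, selection, fitting, scoring, thresholding, Cox."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.special import expit

from conftest import brute_force_cutpoint
from prismpanel import classifier as clf
from prismpanel.marker_eval import constrained_cutpoint


def _binary_cohort(rng, n, prevalence=0.25, d=1.5, n_markers=1):
    y = (rng.uniform(size=n) < prevalence).astype(int)
    data = {"event": y}
    for j in range(n_markers):
        data[f"m{j}"] = rng.normal(0, 1, n) + d * y
    return pd.DataFrame(data)


class TestSplitCohort:
    def test_published_cohort_sizes(self):
        cohort = pd.DataFrame({"outcome": ["DM"] * 53 + ["nonevent"] * 161})
        train, test = clf.split_cohort(cohort, clf.SplitSpec(0.7, seed=1))
        assert len(train) == 149
        assert len(test) == 65

    def test_seed_determinism(self):
        cohort = pd.DataFrame({"outcome": ["a", "b"] * 50, "x": range(100)})
        t1, s1 = clf.split_cohort(cohort, clf.SplitSpec(0.7, seed=9))
        t2, s2 = clf.split_cohort(cohort, clf.SplitSpec(0.7, seed=9))
        assert t1.equals(t2) and s1.equals(s2)

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_property(self, seed):
        cohort = pd.DataFrame({"outcome": ["a", "b"] * 30, "x": range(60)})
        train, test = clf.split_cohort(cohort, clf.SplitSpec(0.7, seed=seed))
        union = pd.concat([train, test]).sort_index()
        assert union.equals(cohort)
        assert set(train.index).isdisjoint(test.index)

    def test_single_class_split_warns(self):
        cohort = pd.DataFrame({"outcome": ["a"] * 11 + ["b"]})
        with pytest.warns(UserWarning, match="single outcome class"):
            clf.split_cohort(cohort, clf.SplitSpec(0.7, seed=0))


class TestUnivariableSelect:
    def test_noise_marker_excluded(self):
        rng = np.random.default_rng(0)
        train = _binary_cohort(rng, 500, d=0.0)
        assert clf.univariable_select(train, ["m0"]) == []

    def test_boundary_auc_is_strict(self):
        # a fabricated marker whose AUC is exactly the 0.65 floor
        y = np.repeat([0, 1], [20, 20])
        x = np.zeros(40)
        x[y == 1] = np.arange(20)
        x[y == 0] = np.arange(20) - 6.0  # overlap tuned below
        df = pd.DataFrame({"event": y, "m0": x})
        from prismpanel.marker_eval import _auc_from_ranks

        auc = max(_auc_from_ranks(x, y), 1 - _auc_from_ranks(x, y))
        selected = clf.univariable_select(df, ["m0"], auc_min=auc)
        assert selected == []  # strict >

    def test_planted_strong_marker_selected(self):
        # d = 1.19 corresponds to a theoretical AUC of 0.80
        hits = 0
        n_sims = 40
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            train = _binary_cohort(rng, 500, d=1.19)
            if "m0" in clf.univariable_select(train, ["m0"]):
                hits += 1
        assert hits >= 0.95 * n_sims


class TestFitPanelClassifier:
    def test_symmetric_design_zero_intercept(self):
        rng = np.random.default_rng(1)
        n = 4000
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(0, 1, n) + np.where(y == 1, 0.8, -0.8)
        train = pd.DataFrame({"event": y, "m0": x})
        model = clf.fit_panel_classifier(train, ["m0"])
        assert abs(model.intercept) < 0.15
        assert not model.penalized

    def test_planted_coefficients_recovered(self):
        rng = np.random.default_rng(2)
        n = 5000
        x = rng.normal(size=n)
        p = expit(-2.0 + 1.0 * x)
        y = (rng.uniform(size=n) < p).astype(int)
        train = pd.DataFrame({"event": y, "m0": x})
        model = clf.fit_panel_classifier(train, ["m0"])
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        lo, hi = fit.conf_int()[0]
        assert lo <= -2.0 <= hi
        lo, hi = fit.conf_int()[1]
        assert lo <= 1.0 <= hi
        assert model.coefficients["m0"] == pytest.approx(fit.params[1], rel=1e-5)

    def test_perfect_separation_falls_back_to_ridge(self):
        train = pd.DataFrame(
            {"event": [0, 0, 0, 1, 1, 1], "m0": [1.0, 2, 3, 10, 11, 12]}
        )
        model = clf.fit_panel_classifier(train, ["m0"])
        assert model.penalized

    def test_duplicated_marker_column_penalized(self):
        rng = np.random.default_rng(3)
        df = _binary_cohort(rng, 200, d=1.0)
        df["m1"] = df["m0"]
        model = clf.fit_panel_classifier(df, ["m0", "m1"])
        assert model.penalized

    def test_constant_marker_rejected(self):
        df = pd.DataFrame({"event": [0, 1, 0, 1], "m0": [1.0, 1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            clf.fit_panel_classifier(df, ["m0"])


class TestScorePatients:
    @staticmethod
    def _model(intercept=0.0, beta=1.0):
        return clf.ClassifierModel(
            marker_ids=["m0"], intercept=intercept, coefficients={"m0": beta}
        )

    def test_logistic_midpoint_is_50(self):
        scores = clf.score_patients(self._model(), pd.DataFrame({"m0": [0.0]}))
        assert scores.iloc[0] == pytest.approx(50.0)

    def test_range_limits(self):
        scores = clf.score_patients(
            self._model(), pd.DataFrame({"m0": [-1e6, 1e6]})
        )
        assert scores.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert scores.iloc[1] == pytest.approx(100.0, abs=1e-9)

    def test_monotone_in_marker(self):
        x = np.linspace(-3, 3, 50)
        scores = clf.score_patients(self._model(beta=0.7), pd.DataFrame({"m0": x}))
        assert (np.diff(scores) > 0).all()

    def test_missing_marker_scored_nan(self):
        scores = clf.score_patients(
            self._model(), pd.DataFrame({"m0": [0.0, np.nan]})
        )
        assert np.isnan(scores.iloc[1])

    def test_affine_reencoding_invariance(self):
        """Rescaling a marker and its coefficient leaves scores unchanged."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        a, b = 3.5, -2.0
        m1 = clf.ClassifierModel(["m0"], intercept=0.4, coefficients={"m0": 0.9})
        m2 = clf.ClassifierModel(
            ["m0"], intercept=0.4 - 0.9 * b / a, coefficients={"m0": 0.9 / a}
        )
        s1 = clf.score_patients(m1, pd.DataFrame({"m0": x}))
        s2 = clf.score_patients(m2, pd.DataFrame({"m0": a * x + b}))
        np.testing.assert_allclose(s1, s2, rtol=1e-10)


class TestEvaluateAtThreshold:
    def test_derived_2x2_counting(self):
        # 10 positives / 90 negatives; threshold catches 9 TP and 42 FP
        scores = np.concatenate(
            [np.full(9, 0.9), [0.1], np.full(42, 0.8), np.full(48, 0.2)]
        )
        labels = np.concatenate([np.ones(10), np.zeros(90)]).astype(int)
        m = clf.evaluate_at_threshold(scores, labels, 0.5)
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(48 / 90)
        assert m["npv"] == pytest.approx(48 / 49)

    def test_threshold_above_all_scores(self):
        scores = [10, 20, 30, 40]
        labels = [0, 0, 1, 1]
        m = clf.evaluate_at_threshold(scores, labels, 99)
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["npv"] == pytest.approx(1 - 0.5)

    def test_threshold_below_all_scores(self):
        scores = [10, 20, 30, 40]
        labels = [0, 0, 0, 1]
        m = clf.evaluate_at_threshold(scores, labels, 0)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["ppv"] == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            clf.evaluate_at_threshold([], [], 0.5)


class TestBootstrapThreshold:
    def test_perfect_separation_midpoint(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = [0, 0, 0, 1, 1, 1]
        res = clf.bootstrap_threshold(scores, labels, B=50, seed=0)
        assert res.feasible
        assert res.threshold == pytest.approx(6.5)
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        oracle = brute_force_cutpoint(scores, labels, 0.9, 0.35)
        assert res.threshold == pytest.approx(oracle[0])

    def test_unattainable_npv(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        res = clf.bootstrap_threshold(scores, labels, min_npv=1.0, B=20, seed=0)
        assert not res.feasible

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(2, 1, 20)])
        labels = np.repeat([0, 1], [60, 20])
        a = clf.bootstrap_threshold(scores, labels, B=100, seed=7)
        b = clf.bootstrap_threshold(scores, labels, B=100, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_point_estimate_shares_cutpoint_engine(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(1.4, 1, 25)])
        labels = np.repeat([0, 1], [60, 25])
        res = clf.bootstrap_threshold(scores, labels, min_npv=0.8,
                                      min_spec=0.3, B=5, seed=0)
        cp = constrained_cutpoint(scores, labels, 0.8, 0.3, B=5, seed=0)
        assert res.threshold == pytest.approx(cp.cutpoint)
        assert res.sensitivity == pytest.approx(cp.sensitivity)

    def test_refit_mode_runs_and_is_deterministic(self):
        rng = np.random.default_rng(8)
        train = _binary_cohort(rng, 120, d=1.5, n_markers=2)
        model = clf.fit_panel_classifier(train, ["m0", "m1"])
        scores = clf.score_patients(model, train).to_numpy()
        y = train["event"].to_numpy()
        a = clf.bootstrap_threshold(scores, y, B=30, seed=3, train=train,
                                    model=model)
        b = clf.bootstrap_threshold(scores, y, B=30, seed=3, train=train,
                                    model=model)
        assert a.feasible
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestCompareModelsLrt:
    @staticmethod
    def _fits(rng, n=500, beta=0.0):
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        p = expit(-1.0 + 0.5 * x1 + beta * x2)
        y = (rng.uniform(size=n) < p).astype(int)
        base = sm.Logit(y, sm.add_constant(x1)).fit(disp=0)
        aug = sm.Logit(y, sm.add_constant(np.column_stack([x1, x2]))).fit(disp=0)
        return base, aug

    def test_identical_models_null(self):
        base, _ = self._fits(np.random.default_rng(0))
        chi2, df, p = clf.compare_models_lrt(base, base)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_df_equals_added_parameters(self):
        base, aug = self._fits(np.random.default_rng(1))
        _, df, _ = clf.compare_models_lrt(base, aug)
        assert df == 1

    def test_planted_covariate_detected(self):
        detections = 0
        n_sims = 30
        for seed in range(n_sims):
            base, aug = self._fits(np.random.default_rng(seed), n=2000, beta=1.0)
            _, _, p = clf.compare_models_lrt(base, aug)
            detections += p < 0.001
        assert detections >= 0.95 * n_sims

    def test_different_n_rejected(self):
        rng = np.random.default_rng(2)
        base, _ = self._fits(rng, n=300)
        _, aug = self._fits(rng, n=400)
        with pytest.raises(ValueError):
            clf.compare_models_lrt(base, aug)


def _survival_cohort(rng, n, log_hr=0.0):
    """Exponential survival with a binary covariate and admin censoring."""
    x = rng.integers(0, 2, n)
    lam = 0.02 * np.exp(log_hr * x)
    t = rng.exponential(1 / lam)
    c = rng.uniform(20, 120, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    df = pd.DataFrame(
        {
            "age_at_dx": rng.normal(60, 8, n),
            "race": rng.choice(["AA", "CA_other"], n),
            "nccn": rng.choice(["low", "intermediate", "high"], n),
            "score": x.astype(float),
            "_t": time,
            "_e": event,
        }
    )
    return df


class TestCoxClassifier:
    def test_null_covariate_ci_coverage(self):
        covered = 0
        n_sims = 60
        for seed in range(n_sims):
            rng = np.random.default_rng(100 + seed)
            df = _survival_cohort(rng, 300, log_hr=0.0)
            hr, _ = clf.cox_classifier(
                df, duration_col="_t", event_col="_e", soc_set="biopsy",
                classifier_col="score", classifier_form="continuous",
            )
            row = hr.loc["classifier"]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 0.88 * n_sims

    def test_planted_hazard_ratio_recovered(self):
        hrs = []
        for seed in range(25):
            rng = np.random.default_rng(200 + seed)
            df = _survival_cohort(rng, 2000, log_hr=np.log(2.0))
            fit = CoxPHFitter().fit(
                df[["score", "_t", "_e"]], duration_col="_t", event_col="_e"
            )
            hrs.append(np.exp(fit.params_["score"]))
        assert 1.8 <= np.mean(hrs) <= 2.2

    def test_time_scale_invariance(self):
        rng = np.random.default_rng(9)
        df = _survival_cohort(rng, 400, log_hr=0.5)
        hr1, _ = clf.cox_classifier(
            df, duration_col="_t", event_col="_e", soc_set="biopsy",
            classifier_col="score", classifier_form="continuous",
        )
        df2 = df.assign(_t=2.0 * df["_t"])
        hr2, _ = clf.cox_classifier(
            df2, duration_col="_t", event_col="_e", soc_set="biopsy",
            classifier_col="score", classifier_form="continuous",
        )
        np.testing.assert_allclose(hr1["hr"], hr2["hr"], rtol=1e-6)

    def test_no_variation_covariate_dropped(self):
        rng = np.random.default_rng(10)
        df = _survival_cohort(rng, 200, log_hr=0.5)
        df["race"] = "AA"
        with pytest.warns(UserWarning, match="without variation"):
            hr, _ = clf.cox_classifier(
                df, duration_col="_t", event_col="_e", soc_set="biopsy",
                classifier_col="score", classifier_form="continuous",
            )
        assert "race_aa" not in hr.index


class TestModelSerialization:
    def test_json_round_trip(self):
        model = clf.ClassifierModel(
            marker_ids=["a", "b"], intercept=-1.5,
            coefficients={"a": 0.4, "b": -0.2}, threshold=8.3,
            threshold_ci=(6.0, 11.0), seed=5, B=1000,
        )
        restored = clf.ClassifierModel.from_json(model.to_json())
        assert restored == model
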