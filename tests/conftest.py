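"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from prismpanel.synthetic_data import SimulationConfig, simulate_cohort

# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)


def brute_force_cutpoint(values, labels, min_npv, min_spec):
    """Exhaustive threshold scan with direct 2x2 counting.

    Returns (threshold, sens, spec) of the feasible candidate maximising
    sensitivity (ties: higher specificity, then larger threshold), or None.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(values)
    cands = [-np.inf, *((uniq[:-1] + uniq[1:]) / 2.0), np.inf]
    best = None
    for t in cands:
        pred = values >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = int((~pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        if tn + fn == 0:
            continue
        npv = tn / (tn + fn)
        if npv < min_npv or spec < min_spec:
            continue
        key = (sens, spec, t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return None if best is None else (best[1], best[2], best[3])


def pair_count_auc(values, labels):
    """AUC by exhaustive pairwise concordance counting (half credit for ties)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = values[labels == 1]
    neg = values[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def closed_form_ols(x, y):
    """Two-parameter OLS by the textbook closed form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
    return slope, ybar - slope * xbar


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=20260924)


@pytest.fixture(scope="session")
def cohort_338(default_config):
    """One cohort at the study's size and prevalences."""
    cohort, truth = simulate_cohort(default_config, seed=20260924)
    return cohort, truth


@pytest.fixture(scope="session")
def cohort_5000():
    """A large cohort for checking planted-AUC convergence."""
    config = SimulationConfig(n_patients=5000, seed=57)
    cohort, truth = simulate_cohort(config, seed=57)
    return cohort, truth
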