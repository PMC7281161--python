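"""Synthetic calibration series, patient cohorts, and SRM measurement tables.

The generators emulate the statistical structure the analysis pipeline
assumes, with retrievable ground truth, so every stage is testable without
access to restricted patient data:

* **Cohort model.**  Patients fall into three outcome groups (nonevent,
  biochemical recurrence, distant metastasis) at configurable prevalences.
  Marker abundances on the standardized log scale are binormal with equal
  variance: nonevents are N(0, 1) and each event group is shifted by a
  per-marker effect size ``d``, so the theoretical event-vs-nonevent AUC is
  ``Phi(|d| / sqrt(2))`` — the one quantitative handle the study design
  offers.  Default shifts are back-calculated from the published per-marker
  AUC scale; tissue PSA is planted with a negative shift (lower abundance in
  metastatic disease).  Clinical covariates are drawn from per-group marginal
  frequency tables; event times are exponential with configurable medians and
  nonevents are censored at a follow-up of at least 120 months.

* **SRM forward model.**  Calibration heavy-over-light ratios follow
  ``H/L = slope * spike + intercept`` with multiplicative log-normal noise;
  peak apex and background are constructed so the planted LOD/LOQ levels are
  recoverable by the signal-to-noise rules.  Sample light-over-heavy ratios
  invert the endogenous-concentration equation, so quantification round-trips
  to the planted truth exactly in the noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from prismpanel.srm_quant import CALIBRATION_LEVELS

OUTCOMES = ("nonevent", "BCR", "DM")

#: Published per-marker discrimination scale (event-vs-nonevent AUC) used to
#: back-calculate default effect sizes; tissue PSA is oriented negative
#: (lower abundance in progressing disease).
_MARKER_AUCS: dict[str, tuple[float, float]] = {
    # marker: (AUC DM vs nonevent, AUC BCR vs nonevent)
    "ANXA2": (0.535, 0.538),
    "CAMKK2": (0.591, 0.604),
    "CCND1": (0.532, 0.624),
    "EGFR": (0.628, 0.578),
    "ERG": (0.543, 0.546),
    "FOLH1": (0.653, 0.627),
    "MMP9": (0.562, 0.511),
    "MUC1": (0.570, 0.474),
    "NCOA2": (0.637, 0.613),
    "PSA": (0.730, 0.529),
    "SMAD4": (0.511, 0.526),
    "SPINK1": (0.486, 0.548),
    "SPARC": (0.800, 0.695),
    "TFF3": (0.541, 0.472),
    "TGFB1": (0.788, 0.649),
    "VEGFA": (0.528, 0.601),
}

_NEGATIVE_ORIENTATION = {"PSA"}


def effect_size_from_auc(auc: float) -> float:
    """Standardized binormal shift d with event-vs-nonevent AUC = Phi(d/sqrt(2))."""
    return float(np.sqrt(2.0) * norm.ppf(auc))


def _default_marker_shifts() -> dict[str, tuple[float, float]]:
    shifts = {}
    for marker, (auc_dm, auc_bcr) in _MARKER_AUCS.items():
        sign = -1.0 if marker in _NEGATIVE_ORIENTATION else 1.0
        shifts[marker] = (
            sign * effect_size_from_auc(auc_dm),
            sign * effect_size_from_auc(auc_bcr),
        )
    return shifts


#: Per-group marginal frequencies of the clinical covariates
#: (nonevent, BCR, DM), taken from the cohort's descriptive table.
_COVARIATE_TABLES: dict[str, dict[str, tuple[float, float, float]]] = {
    "race": {
        "AA": (55, 48, 17),
        "CA_other": (106, 75, 36),
    },
    "psa_dx": {
        "<10": (133, 90, 39),
        "10-20": (25, 25, 9),
        ">20": (1, 9, 5),
    },
    "clinical_t": {
        "T1-T2a": (134, 107, 33),
        "T2b-T2c": (22, 15, 15),
        "T3a-T4": (1, 2, 5),
    },
    "biopsy_grade": {
        "<=6": (100, 68, 14),
        "7": (35, 41, 19),
        "8-10": (6, 10, 19),
    },
    "nccn": {
        "low": (69, 46, 10),
        "intermediate": (59, 55, 20),
        "high": (8, 19, 22),
    },
    "path_t": {
        "pT2": (119, 46, 9),
        "pT3-4": (41, 77, 39),
    },
    "grade_group": {
        "1": (18, 13, 0),
        "2": (77, 27, 1),
        "3": (2, 4, 0),
        "4": (54, 49, 21),
        "5": (9, 30, 27),
    },
    "margin": {
        "neg": (126, 62, 21),
        "pos": (33, 59, 27),
    },
}

#: Age at diagnosis, mean (SD) years per outcome group.
_AGE_PARAMS = {"nonevent": (59.0, 8.1), "BCR": (59.2, 7.7), "DM": (61.7, 5.9)}


@dataclass
class SimulationConfig:
    """Study-condition parameters for all three generators.

    Cohort parameters default to the published cohort structure: n = 338 at
    outcome prevalences (0.476, 0.367, 0.157), median time from surgery to
    biochemical recurrence 20.4 months (1.7 years) and to distant metastasis
    80.4 months (6.7 years), nonevent follow-up uniform on [120, 253]
    months.  The SRM forward model defaults to a 10% measurement CV, a
    pooled-matrix light concentration of 500 amol/ug (slope = 1/500), a
    heavy spike of 300 amol/ug in study samples, and a signal-to-noise
    gradient that places the LOD at the 3 amol/ug level and the LOQ at
    12 amol/ug.
    """

    n_patients: int = 338
    prevalences: tuple[float, float, float] = (0.476, 0.367, 0.157)
    marker_shifts: dict[str, tuple[float, float]] = field(
        default_factory=_default_marker_shifts
    )
    median_bcr_months: float = 20.4
    median_dm_months: float = 80.4
    followup_range_months: tuple[float, float] = (120.0, 253.0)

    # SRM forward model
    calibration_levels: tuple[float, ...] = CALIBRATION_LEVELS
    n_replicates: int = 3
    noise_cv: float = 0.10
    c_light_matrix: float = 500.0
    curve_intercept: float = 0.0
    spike_amol_per_ug: float = 300.0
    snr_per_amol: float = 1.0       # S/N = snr_per_amol * spike level
    background_noise: float = 100.0
    c_scale_amol_per_ug: float = 500.0
    log10_sd: float = 0.35
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.prevalences) - 1.0) > 1e-6:
            raise ValueError("outcome prevalences must sum to 1")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        levels = np.asarray(self.calibration_levels)
        if not (np.diff(levels) > 0).all():
            raise ValueError("calibration levels must be strictly increasing")
        if self.c_light_matrix <= 0 or self.c_scale_amol_per_ug <= 0:
            raise ValueError("concentration scales must be positive")

    @property
    def curve_slope(self) -> float:
        """Slope of the planted response curve (1 / matrix light concentration)."""
        return 1.0 / self.c_light_matrix


@dataclass
class GroundTruth:
    """Planted truth retrievable by tests, never consumed by pipeline stages."""

    outcome: pd.Series | None = None
    marker_shifts: pd.DataFrame | None = None
    true_z: pd.DataFrame | None = None
    true_concentrations: pd.DataFrame | None = None
    curve_params: pd.DataFrame | None = None
    planted_lod: float | None = None
    planted_loq: float | None = None


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative noise with unit mean and the requested CV."""
    if cv == 0:
        return np.ones(size if size is not None else ())
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, size))


# ---------------------------------------------------------------------------
# calibration series


def simulate_calibration(
    config: SimulationConfig,
    peptides: Mapping[str, str] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Calibration-point table for each peptide with planted curve truth.

    ``peptides`` maps peptide_id -> protein_id; by default one surrogate
    peptide per configured marker, named ``PEP_<marker>``.  H/L ratios follow
    the planted line with multiplicative log-normal noise; apex intensity is
    ``background * snr_per_amol * level``, so the replicate-median S/N rules
    recover the planted LOD and LOQ deterministically.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if peptides is None:
        peptides = {f"PEP_{m}": m for m in config.marker_shifts}
    levels = np.asarray(config.calibration_levels, dtype=float)
    rows = []
    for pep in peptides:
        for level in levels:
            for rep in range(1, config.n_replicates + 1):
                y = config.curve_slope * level + config.curve_intercept
                y *= _lognormal_factor(rng, config.noise_cv, None)
                rows.append(
                    {
                        "peptide_id": pep,
                        "protein_id": peptides[pep],
                        "spike_level_amol_per_ug": level,
                        "replicate": rep,
                        "hl_ratio": float(y),
                        "apex_intensity": config.background_noise
                        * config.snr_per_amol * level,
                        "background_noise": config.background_noise,
                    }
                )
    table = pd.DataFrame(rows)
    nonzero = levels[levels > 0]
    snr = config.snr_per_amol * nonzero
    lod_levels = nonzero[snr >= 3.0]
    loq_levels = nonzero[snr >= 10.0]
    truth = GroundTruth(
        curve_params=pd.DataFrame(
            {
                "peptide_id": list(peptides),
                "slope": config.curve_slope,
                "intercept": config.curve_intercept,
                "c_light_matrix": config.c_light_matrix,
            }
        ).set_index("peptide_id"),
        planted_lod=float(lod_levels[0]) if len(lod_levels) else None,
        planted_loq=float(loq_levels[0]) if len(loq_levels) else None,
    )
    return table, truth


# ---------------------------------------------------------------------------
# patient cohort


def _sample_categorical(
    rng: np.random.Generator, table: dict[str, tuple[float, float, float]],
    group_idx: np.ndarray,
) -> np.ndarray:
    levels = list(table)
    probs = np.asarray([table[lv] for lv in levels], dtype=float)  # levels x 3
    probs = probs / probs.sum(axis=0, keepdims=True)
    out = np.empty(len(group_idx), dtype=object)
    for g in range(3):
        mask = group_idx == g
        out[mask] = rng.choice(levels, size=int(mask.sum()), p=probs[:, g])
    return out


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Patient table with planted marker effects and survival structure.

    Marker columns hold standardized log-abundances: N(0, 1) for nonevents,
    shifted by the configured per-marker, per-endpoint effect size for BCR
    and DM patients.  Event times are exponential with the configured
    medians (the DM time is the BCR time plus an exponential increment);
    nonevents are censored at a uniform [120, 253]-month follow-up.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    group_idx = rng.choice(3, size=n, p=np.asarray(config.prevalences))
    outcome = np.asarray(OUTCOMES, dtype=object)[group_idx]

    cohort = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    cohort["outcome"] = outcome

    age_mean = np.asarray([_AGE_PARAMS[o][0] for o in outcome])
    age_sd = np.asarray([_AGE_PARAMS[o][1] for o in outcome])
    cohort["age_at_dx"] = rng.normal(age_mean, age_sd)
    for var, table in _COVARIATE_TABLES.items():
        cohort[var] = _sample_categorical(rng, table, group_idx)

    # survival: exponential times parameterized by median (scale = median/ln 2)
    scale_bcr = config.median_bcr_months / np.log(2.0)
    scale_dm_extra = max(
        config.median_dm_months - config.median_bcr_months, 1e-6
    ) / np.log(2.0)
    t_bcr = rng.exponential(scale_bcr, n)
    t_dm = t_bcr + rng.exponential(scale_dm_extra, n)
    fu_lo, fu_hi = config.followup_range_months
    fu_nonevent = rng.uniform(fu_lo, fu_hi, n)
    fu_event_extra = rng.exponential(48.0 / np.log(2.0), n)

    is_ne = outcome == "nonevent"
    is_bcr = outcome == "BCR"
    is_dm = outcome == "DM"
    cohort["time_to_bcr"] = np.where(is_ne, np.nan, t_bcr)
    cohort["time_to_dm"] = np.where(is_dm, t_dm, np.nan)
    cohort["followup"] = np.where(
        is_ne, fu_nonevent,
        np.where(is_bcr, t_bcr + fu_event_extra, t_dm + fu_event_extra),
    )

    markers = list(config.marker_shifts)
    shifts = np.zeros((n, len(markers)))
    for j, m in enumerate(markers):
        d_dm, d_bcr = config.marker_shifts[m]
        shifts[is_dm, j] = d_dm
        shifts[is_bcr, j] = d_bcr
    z = rng.standard_normal((n, len(markers))) + shifts
    for j, m in enumerate(markers):
        cohort[m] = z[:, j]

    true_conc = config.c_scale_amol_per_ug * np.power(10.0, config.log10_sd * z)
    truth = GroundTruth(
        outcome=pd.Series(outcome, index=cohort.index, name="outcome"),
        marker_shifts=pd.DataFrame(
            config.marker_shifts, index=["d_dm", "d_bcr"]
        ).T,
        true_z=pd.DataFrame(z, columns=markers, index=cohort.index),
        true_concentrations=pd.DataFrame(
            true_conc, columns=markers, index=cohort["patient_id"]
        ),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# SRM measurements from a cohort


def simulate_srm_from_cohort(
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Transition report whose quantification round-trips to the cohort truth.

    For each sample x marker the light-over-heavy ratio inverts the
    endogenous-concentration equation at the planted curve:
    ``L/H = C_light * (slope * c_true + intercept) / C_heavy`` times
    multiplicative noise.  Peak areas are reported with a fixed heavy area.
    """
    if truth.true_concentrations is None:
        raise ValueError("cohort ground truth with true concentrations required")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    conc = truth.true_concentrations
    heavy_area = 1.0e5
    rows = []
    for marker in conc.columns:
        pep = f"PEP_{marker}"
        c = conc[marker].to_numpy()
        lh = (
            config.c_light_matrix
            * (config.curve_slope * c + config.curve_intercept)
            / config.spike_amol_per_ug
        )
        lh = lh * _lognormal_factor(rng, config.noise_cv, len(lh))
        for sample, ratio in zip(conc.index, lh):
            rows.append(
                {
                    "peptide_id": pep,
                    "protein_id": marker,
                    "sample_id": sample,
                    "light_area": float(ratio * heavy_area),
                    "heavy_area": heavy_area,
                    "apex_intensity": float(ratio * heavy_area),
                    "background_noise": config.background_noise,
                    "heavy_spike_amol_per_ug": config.spike_amol_per_ug,
                }
            )
    return pd.DataFrame(rows)
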