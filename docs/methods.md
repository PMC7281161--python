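# Methods

This note documents the statistical models, numerical choices, and known
limitations behind `prismpanel`. It is written for a reader who wants to
know exactly what each stage computes and what the synthetic-data tests do
and do not demonstrate.

## 1. Isotope-dilution SRM quantification

### Forward model and back-calculation

Each protein is quantified through one designated surrogate peptide. A
stable-isotope-labelled ("heavy") peptide standard is spiked into a pooled
tissue matrix at twelve concentrations (0, 0.6, 3, 12, 60, 300, 1500, 3000,
6000, 12 000, 24 000, 48 000 amol/µg; three injection replicates), and the
heavy-over-light (H/L) total peak-area ratio is modelled as linear in the
spike concentration:

    H/L = slope · C_heavy + intercept.

Because the pooled matrix contains the endogenous light peptide at a fixed
concentration `C_light`, the curve also determines that concentration. At
each of the three intermediate spike levels (300, 1500, 3000 amol/µg) the
measured mean H/L, corrected by the fitted intercept, gives a per-level
estimate `C_light = C_heavy / (H/L − intercept)`; the arithmetic mean of the
per-level estimates is used. We use *measured* ratios at those levels rather
than curve-predicted ones: with curve-predicted ratios the estimate would
collapse to `1/slope` identically and the three levels would carry no
information.

For a study sample with heavy spike `C_heavy` and measured light-over-heavy
ratio L/H, the endogenous concentration is the curve inversion

    C_endo = (L/H · C_heavy / C_light − intercept) / slope   [amol/µg].

The grouping of the first term is the algebraically consistent one: in the
ideal symmetric-response case (`slope = 1/C_light`, intercept 0) it reduces
to `C_endo = L/H · C_heavy`, the textbook isotope-dilution identity, and the
forward model inverts to the planted truth at machine precision. The
alternative grouping with `C_heavy` in the denominator does not recover
truth under any consistent forward model and is not implemented.

Negative back-calculations (possible when the measured ratio falls below the
intercept) are clamped to 0 and flagged `negative_clamped`. Values below the
assay LOD or LOQ keep their numeric value but carry `below_lod`/`below_loq`
flags; downstream analyses use the values as-is by default, since the
abundances enter the statistics only through a rank-preserving log
transform. The log transform floors non-positive values at half the
smallest positive value of the marker, the usual detection-floor imputation.

### Curve fitting and weighting

`fit_response_curve` fits all replicate points (not level means) by least
squares; with noiseless data the two are identical, and using all points
keeps the replicate design's information. The default is ordinary
(unweighted) least squares and agrees with the closed-form two-parameter OLS
solution on every input.

The quantification pipeline (`fit_calibration_curves`), however, defaults to
**1/x² weighted** least squares, the standard weighting for isotope-dilution
calibration over a wide dynamic range. The reason is numerical, not
cosmetic: SRM ratio noise is approximately multiplicative (constant CV), so
absolute residuals grow with the spike level. Across the five-decade level
range, an unweighted fit is dominated by the top levels, and the intercept —
whose scale matters at the 300 amol/µg matrix-estimation level, where the
signal is ~0.6 — acquires errors of the same order as that signal. In
simulation at 10% CV this corrupts the matrix light-concentration estimate
by factors of 2–7 for some assays. 1/x² weighting equalises relative
residuals, pins the intercept with the precision of the low levels, and
brings the median relative recovery error at 10% CV to ~7%. Weighted fits
exclude the zero-concentration blank (its weight is undefined); the blank
still participates in LOD/LOQ determination.

### LOD and LOQ

Signal-to-noise is the peak apex intensity divided by the highest background
in a ±15 s retention-time window (reported upstream; an S/N with zero
background and non-zero signal is the infinite sentinel). Per calibration
level, replicate S/N values are summarised by their **median** (the
summary statistic is not dictated by the protocol; the median is robust to a
single aberrant injection), and the replicate CV is the sample SD over the
mean of the H/L ratios. The LOD is the lowest non-zero level with median
S/N ≥ 3; the LOQ is the lowest non-zero level with median S/N ≥ 10 *and*
CV < 20%. The zero-concentration blank is excluded from candidacy: a
detection limit of zero is not meaningful. When no level qualifies — as
happens in practice under heavy-channel interference — both limits are the
`None` sentinel and downstream flags are simply not assigned.

## 2. Per-marker evaluation

Marker abundances are analysed on a standardized log10 scale (z-scores of
log concentrations). The transformation is a configurable pipeline stage:
cut-points are only meaningful relative to the chosen scale, and the
standardized log scale makes cut-points comparable across assays with very
different absolute abundances.

*Descriptives.* Continuous variables are compared across outcome groups
with one-way ANOVA and Kruskal–Wallis (both reported); categorical variables
with the chi-square test **without** continuity correction (validated
against a published 2×3 contingency example to four decimal places), or
Fisher's exact test when any expected cell count is below 5 (2×2 tables
only; larger sparse tables keep chi-square with an explicit note, since no
exact r×c test is available in the stack).

*AUC.* The AUC is the tie-corrected Mann–Whitney statistic divided by
`n_pos · n_neg`, i.e. the probability that a random event subject outranks a
random non-event subject with half-credit for ties. 95% CIs are percentile
bootstrap over 1000 resamples of the (value, label) pairs; single-class
resamples are discarded. The p-value is the two-sided asymptotic
Mann–Whitney test of AUC = 0.5. A family-wise significance threshold of
α/m = 0.05/16 = 0.003125 is applied when 16 markers are screened.

*Constrained cut-points.* For a marker oriented so higher values indicate
the event, candidate thresholds are the midpoints between consecutive sorted
unique values plus ±∞ sentinels. Among candidates whose NPV and specificity
meet the configured floors ("at least", i.e. ≥; a strictness flag switches
to >), the threshold with the highest sensitivity wins; ties break towards
higher specificity, then the larger threshold (the more conservative
positive call). Constraint pairs are (NPV ≥ 0.80, specificity ≥ 0.40) for
the metastasis endpoint and (0.70, 0.30) for biochemical recurrence. A
marker whose AUC is below 0.5 (e.g. tissue PSA for metastasis, which is
*lower* in progressing disease) is negated before the search and the
threshold mapped back, with the orientation recorded. The bootstrap CI
re-runs the entire search on each resample and takes the 2.5/97.5
percentiles of the feasible replicate thresholds. When no candidate is
feasible the result is flagged infeasible and carries no metrics.

*Panel screening.* Principal components are extracted from the marker
correlation matrix; components with eigenvalue > 1 (Kaiser rule) are
retained and their loadings (eigenvectors scaled by √eigenvalue) reported.

*Survival.* Kaplan–Meier product-limit estimates and the log-rank test
(df = groups − 1) are computed with `lifelines` and checked in the test
suite against hand product-limit tables and a direct observed-minus-expected
implementation.

## 3. Panel classifier

The development cohort is the metastasis + nonevent subset. It is split
70/30 by a **simple** (non-stratified) random permutation with
`floor(0.7·n)` training patients — a 214-patient cohort yields 149/65. The
split is intentionally not stratified: event proportions are allowed to
drift between halves, as they do in realistic splits.

Markers enter the panel through a univariable logistic screen: Wald
p < 0.05 *and* orientation-free AUC > 0.65, both strict. The panel model is
a maximum-likelihood multivariable logistic regression; the reported score
is the predicted probability × 100, which is naturally bounded on [0, 100]
and monotone in the linear predictor. (Min–max scaling of the linear
predictor is a documented alternative but not the default.) On perfect or
quasi-separation — common in bootstrap replicates of small cohorts — the fit
falls back to an L2-penalised logistic regression and the model is flagged
`penalized`.

The decision threshold applies the same constrained search as single-marker
cut-points to the training scores, with floors NPV ≥ 0.90 and
specificity ≥ 0.35. Its CI comes from 1000 bootstrap replicates in which
the logistic model is **re-fitted** on each resample before re-scoring and
re-thresholding ("bootstrapped multivariable logistic regression"); a
re-threshold-only mode (resampling fixed scores) is available.

Added value over standard-of-care covariates is assessed two ways. Nested
logistic models (SOC alone vs SOC + score) are compared by likelihood-ratio
test, with AUCs of both models reported. Cox proportional-hazards models of
metastasis-free survival include the classifier either dichotomised at its
threshold or as a continuous score, adjusting for the biopsy set (age, race,
NCCN stratum) or the pathology set (pathological T, grade group 5 vs 1–4,
surgical margin). The PH assumption is checked with the scaled-Schoenfeld
rank-transform trend test at α = 0.05 and reported, not enforced. Cox fits
that fail to converge (sparse event counts) are retried with a small ridge
penalty (0.1) and flagged.

## 4. Synthetic data generator

The generator exists so that every stage is testable without access to the
restricted patient cohort. Its defaults are the study conditions:

| parameter | default | basis |
|---|---|---|
| n patients | 338 | cohort size |
| outcome prevalences | 0.476 / 0.367 / 0.157 | nonevent / BCR / DM proportions |
| marker shifts d | √2·Φ⁻¹(AUC) per marker | published per-marker AUC scale |
| PSA orientation | negative | lower tissue PSA in metastatic disease |
| median time to BCR | 20.4 months | 1.7 years |
| median time to DM | 80.4 months | 6.7 years |
| nonevent follow-up | U[120, 253] months | ≥10-year nonevent definition |
| calibration levels | the 12-point series | assay design |
| measurement CV | 10% | typical inter-configuration variation |
| matrix light conc. | 500 amol/µg | mid-range assay; slope = 1/500 |
| sample heavy spike | 300 amol/µg | a matrix-estimation level |
| S/N gradient | S/N = level (amol/µg) | plants LOD = 3, LOQ = 12 |

Markers are equal-variance binormal on the standardized log scale:
nonevents N(0, 1), event groups shifted by d, so the theoretical
event-vs-nonevent AUC is Φ(|d|/√2) — the one quantitative handle the study
design provides, and the basis of the planted-recovery tests (empirical AUC
within ±0.02 of Φ(d/√2) at large n). Clinical covariates are drawn
independently per patient from per-group marginal frequency tables; they
reproduce the marginal group differences but **not** a causal
covariate–marker dependence. Event times are exponential, parameterised by
median (scale = median/ln 2); the metastasis time is the BCR time plus an
exponential increment, follow-up for event patients extends beyond the event
by an exponential tail, and nonevents are censored at a uniform follow-up of
at least 120 months.

SRM measurements are generated by inverting the concentration equation at
the planted curve — `L/H = C_light(slope·C_endo + intercept)/C_heavy` times
log-normal noise with unit mean and the configured CV — so the
generator and the quantification pipeline compose to the identity in the
noiseless limit. True concentrations map from the planted z-scores as
`C = 500 · 10^(0.35·z)` amol/µg.

What passing tests on this generator do *not* show: robustness to
inter-marker correlation (markers are independent by default; a common
factor is out of scope), batch effects, non-linear response saturation,
interference, missingness mechanisms, or covariate-driven confounding —
features of the real cohort that the generator deliberately omits.

## 5. Reproducibility and numerical conventions

Every stochastic operation takes an explicit seed (NumPy `default_rng`);
pipeline stages derive their seeds from the single configuration seed by
fixed offsets, so full reports are byte-identical across runs. Bootstrap
resamples that lose a class or produce no feasible threshold are discarded
rather than redrawn, keeping replicate counts ≤ B but preserving
determinism. Ties in ranks use midranks throughout. Empty predictive-value
denominators (no predicted negatives/positives) make the metric undefined
(NaN) and a threshold with undefined NPV is never feasible.

Problem sizes used in the shipped tests and the acceptance script — e.g.
cohorts of 338 and 5000, 200-replicate recovery simulations, 50-seed
protocol sweeps, reduced bootstrap depth where only a point estimate is
under test — are chosen as the smallest sizes at which each property is
statistically decidable; the study-condition constants (B = 1000,
constraint floors, prevalences) are never altered.
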