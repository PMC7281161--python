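# prismpanel

Targeted-proteomics quantification and prognostic panel classification for
prostate cancer progression.

## The problem

After radical prostatectomy, most screen-detected prostate cancers never
progress, but a minority recur biochemically (BCR) or metastasize (DM).
Tissue protein abundances measured by selected reaction monitoring (SRM)
with heavy-isotope internal standards can stratify that risk — if the raw
heavy/light peak-area ratios are first turned into calibrated
concentrations, and the concentrations into a validated decision rule.
`prismpanel` implements that full analysis route as a tested, reusable
library for biostatisticians and proteomics analysts:

1. **Quantification** (`prismpanel.srm_quant`): calibration ("response")
   curves `H/L = slope·C_heavy + intercept` fitted over a 12-point spike
   series, signal-to-noise-based LOD/LOQ rules (S/N ≥ 3 and ≥ 10 with
   replicate CV < 20%), and back-calculation of endogenous concentration

       C_endo = (L/H · C_heavy / C_light − intercept) / slope   [amol/µg]

2. **Marker evaluation** (`prismpanel.marker_eval`): Mann–Whitney AUC with
   bootstrap CIs and Bonferroni screening; *constrained cut-point
   optimisation* — the threshold maximising sensitivity subject to NPV and
   specificity floors — with bootstrapped CIs; PCA panel screening;
   Kaplan–Meier / log-rank survival analysis.

3. **Panel classifier** (`prismpanel.classifier`): 70/30 train/test split,
   univariable selection (p < 0.05, AUC > 0.65), multivariable logistic
   panel scored as predicted probability × 100, a bootstrapped
   constraint-satisfying decision threshold (NPV ≥ 90%, specificity ≥ 35%),
   likelihood-ratio tests of added value over standard-of-care covariates,
   and Cox proportional-hazards models of metastasis-free survival.

4. **Synthetic data** (`prismpanel.synthetic_data`): generators for
   calibration series, patient cohorts and SRM measurements with planted
   ground truth — binormal markers whose theoretical AUC is Φ(d/√2) — so
   every stage is testable without restricted patient data.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from prismpanel.synthetic_data import (SimulationConfig, simulate_calibration,
                                       simulate_cohort, simulate_srm_from_cohort)
from prismpanel import srm_quant as sq
from prismpanel.pipeline import run_pipeline, PipelineConfig

config = SimulationConfig(seed=42)                 # n=338 study conditions
calibration, _ = simulate_calibration(config, seed=42)
cohort, truth = simulate_cohort(config, seed=43)
report = simulate_srm_from_cohort(truth, config, seed=44)

curves = sq.fit_calibration_curves(calibration)    # 1/x^2-weighted fits
c = curves["PEP_SPARC"]
print(f"SPARC assay: slope={c.slope:.6f}, intercept={c.intercept:.4f}, "
      f"LOD={c.lod}, LOQ={c.loq}, matrix light={c.c_light_matrix:.1f} amol/ug")

conc, flags = sq.quantify_samples(report, curves)
print(f"concentration matrix: {conc.shape[0]} proteins x {conc.shape[1]} samples")

bundle = run_pipeline(cohort, list(config.marker_shifts),
                      PipelineConfig(B=200, seed=42))
thr, ev = bundle["threshold"], bundle["evaluation"]
print(f"selected markers: {bundle['selected_markers']}")
print(f"decision threshold: {thr.threshold:.2f} "
      f"(train sens={thr.sensitivity:.2f}, spec={thr.specificity:.2f}, npv={thr.npv:.2f})")
print(f"test AUC: {ev['test_auc']:.3f}; test NPV={ev['test_metrics']['npv']:.2f}, "
      f"sens={ev['test_metrics']['sensitivity']:.2f}, spec={ev['test_metrics']['specificity']:.2f}")
```

Output:

```
SPARC assay: slope=0.002024, intercept=-0.0001, LOD=3.0, LOQ=12.0, matrix light=470.5 amol/ug
concentration matrix: 16 proteins x 338 samples
selected markers: ['FOLH1', 'MMP9', 'PSA', 'SPARC', 'TGFB1']
decision threshold: 2.76 (train sens=0.97, spec=0.46, npv=0.98)
test AUC: 0.943; test NPV=1.00, sens=1.00, spec=0.35
```

Reading this: the fitted SPARC calibration recovers the planted curve
(slope 1/500 ≈ 0.002, LOD 3 and LOQ 12 amol/µg); quantification yields a
16 × 338 concentration matrix; the univariable screen keeps five markers
(the two strongest planted effects, SPARC and TGFB1, plus borderline ones —
the screen is noisy at n ≈ 150 by design); the training threshold honours
its NPV ≥ 0.90 / specificity ≥ 0.35 floors; and the held-out test set
confirms the classifier's discrimination (AUC 0.94 on this draw).

The same pipeline is scriptable from a shell:

```sh
prismpanel simulate --n-patients 338 --seed 42 --outdir data/
prismpanel quantify --calibration data/calibration.tsv \
    --transitions data/transitions.tsv --out data/matrix.tsv
prismpanel run --cohort data/cohort.tsv --matrix data/matrix.tsv \
    --seed 42 --outdir reports/
```

`prismpanel train` / `prismpanel test` serialize and apply a classifier
(`model.json`) separately.

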