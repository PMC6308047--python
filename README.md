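# glioradiomics

Multiregional multiparametric-MRI radiomics for predicting IDH1 mutation
status in glioblastoma — implemented as a fully tested, desk-scale pipeline
that runs end-to-end on synthetic phantom cohorts.

## The problem

IDH1-mutated glioblastomas are a prognostically distinct subgroup, but
genotyping requires tissue.  Radiomics offers a noninvasive alternative:
extract a large catalog of quantitative features from preoperative MRI
(T1w, contrast-enhanced T1, T2w, FLAIR) over multiple tumor subregions
(necrosis, edema, non-enhancement, enhancement, plus the tumor core and
whole tumor composites), select the all-relevant subset, and classify.

The package implements the complete chain:

1. **Synthetic cohorts** — seeded nested-ellipsoid phantoms with four MR
   channels, four tumor subregions, ~9 % mutated prevalence, per-scanner
   monotone intensity drift, and a planted class effect in both geometry
   (subregion proportions) and texture (autocorrelation length of the
   enhancement texture).
2. **Intensity standardization** — landmark-based piecewise-linear
   histogram mapping (deciles + 1st/99th percentiles onto a learned
   standard scale); exactly inverts affine scanner drift.
3. **Quantization** — deterministic Lloyd-Max quantization to 64 gray
   levels per case and channel.
4. **Feature extraction** — the exact 1614-feature multiregional catalog:
   2 location + 28 geometry + 336 first-order intensity + 1248 texture
   features (GLCM 21, GLRLM 13, GLSZM 13, NGTDM 5 per region × channel,
   computed with 26-voxel connectivity in 13 directions).
5. **Balancing** — SMOTE on the training table only; the minority class is
   raised to 64 instances along segments between nearest minority
   neighbors.
6. **Selection** — Boruta all-relevant selection: iterative comparison of
   random-forest importance against permuted shadow features with a
   binomial hit test.
7. **Models** — nine 300-tree random-forest configurations: four
   single-region, tumor core, whole tumor, all-region, clinical
   (age/sex/KPS), and combined.
8. **Evaluation** — ACC/SEN/SPE/PRE/F1 at the Youden cutoff
   (J = SEN + SPE − 1), ROC-AUC with midrank ties, precision-recall
   curves, and paired DeLong AUC comparisons.

Every numerical stage is verified against independent brute-force oracles
(exhaustive pair/run/zone/neighbor enumeration for the texture matrices,
closed forms for geometry, O(n²) pairwise sums for DeLong).

## Worked example

```python
from glioradiomics import (
    BalancingConfig, ExperimentConfig, run_experiment,
)

config = ExperimentConfig(
    n_train=120, n_validation=100,
    train_seed=11, validation_seed=22,
    balancing=BalancingConfig(target_minority_count=64, seed=33),
    models=("all_region", "clinical"),
)
result = run_experiment(config)
for name, report in result.reports.items():
    print(report.rounded())
print("DeLong all_region vs clinical: p =",
      round(result.delong["clinical"].p_value, 4))
```

prints (validation cohort):

```
{'model': 'all_region', 'ACC': 1.0, 'SEN': 1.0, 'SPE': 1.0, 'PRE': 1.0, 'F1': 1.0, 'AUC': 1.0}
{'model': 'clinical', 'ACC': 0.87, 'SEN': 0.08, 'SPE': 0.98, 'PRE': 0.33, 'F1': 0.13, 'AUC': 0.54}
DeLong all_region vs clinical: p = 0.0
```

Reading: on 100 held-out phantoms the all-region radiomics model fully
recovers the (deliberately strong) planted class signal, while the clinical
model — whose covariates are class-independent by construction — stays at
chance discrimination (AUC 0.54; its high accuracy merely reflects the ~90 %
wild-type base rate).  The DeLong test confirms the paired AUC difference.
Exact numbers are deterministic for the seeds shown.

A command-line interface mirrors the stages
(`glioradiomics synth | extract | balance | select | run-all`); volumes are
read and written as NIfTI and feature tables as CSV.

## Documentation

`docs/methods.md` documents the model and every numerical decision: the
phantom generator and what it does and does not emulate, the
standardization and quantization algorithms, the catalog construction, the
SMOTE/Boruta configurations, degenerate-case conventions, and known
limitations.
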