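# periradiomics

Do the few millimetres of tissue *around* a breast mass help tell
benign from malignant? `periradiomics` is a tested, reusable pipeline
for answering that question on mammography for non-spiculated,
noncalcified masses (NSNCM) — the masses whose margins and
calcifications give radiologists the least to work with. It builds
tumoral, peritumoral-ring and combined regions at physical distances
of 1–5 mm, extracts a full 2D radiomics feature set, trains a
classifier per region under leakage-safe cross-validation, and
compares regions with the DeLong test. Because clinical cohorts of
this kind are private, the package ships a synthetic phantom generator
with *known, injectable* class signal, so every stage is verifiable
against ground truth.

It is intended for researchers studying peritumoral imaging biomarkers
who need a transparent reference implementation, and for anyone who
needs its parts: a brute-force-verified 2D texture-feature engine
(GLCM/GLRLM/GLSZM/GLDM), a DeLong test, physical-unit ring ROIs, or a
phantom benchmark for radiomics pipelines.

## The method in brief

For tumour mask $T$ with pixel spacing in mm, the peritumoral ring at
distance $d$ is

$$R_d = \{p : \operatorname{dist}(p, T) \le d\,\text{mm}\} \setminus T \cap B,$$

where $B$ is the Otsu body mask (breast + pectoral muscle); the
combined region is $T \cup R_d$. Each region yields 97 features
(first-order, 2D shape, GLCM, GLRLM, GLSZM, GLDM — definitions in
`docs/methods.md`). Per region model: features with pairwise
$|r| > 0.9$ are pruned (keeping the member more associated with the
label), then an L1-penalised logistic regression is fitted on z-scored
features, with the penalty chosen by validation AUC. Evaluation uses
five patient-stratified folds in a 3:1:1 train/validation/test
rotation; AUC is the Mann–Whitney statistic, compared across regions
with the structural-components DeLong test:

$$z = \frac{\hat\theta_A - \hat\theta_B}
      {\sqrt{\operatorname{Var}(\hat\theta_A - \hat\theta_B)}},\qquad
  \operatorname{Var} = \tfrac{1}{m}S_{10} + \tfrac{1}{n}S_{01}.$$

Patient-level scores take the maximum over a patient's CC/MLO views.

## Worked example

Sixty phantom patients with the default class-texture contrasts, three
region models at 2 mm:

```python
from periradiomics import phantom, study

cfg = phantom.PhantomConfig(n_patients=60, seed=11)
cases = phantom.generate_dataset(cfg)
table = study.extract_feature_table(cases, distances_mm=[2.0])
res = study.run_study(table, distances_mm=[2.0], seed=11)
print(res.summary[["model", "level", "auc_mean", "ci_lo", "ci_hi",
                   "sensitivity", "specificity",
                   "delong_p_vs_tumoral"]].round(3).to_string(index=False))
```

```
          model   level  auc_mean  ci_lo  ci_hi  sensitivity  specificity  delong_p_vs_tumoral
        tumoral     roi     0.781  0.676  0.854         0.72        0.729                  NaN
peritumoral_2mm     roi     0.870  0.805  0.935         0.84        0.714                0.033
   combined_2mm     roi     0.866  0.805  0.943         0.80        0.829                0.007
        tumoral patient     0.834  0.691  0.914         0.92        0.600                  NaN
peritumoral_2mm patient     0.886  0.830  0.983         0.92        0.486                0.112
   combined_2mm patient     0.931  0.884  0.999         1.00        0.771                0.005
```

Read it as: with the phantom's default signal (3% excess texture
variance in the core, 6% in a 2 mm rim), the tumour-only model reaches
a cross-validated ROI-level AUC of 0.78; adding the rim lifts it to
0.87, and the DeLong comparison against the tumoral model is
significant (p = 0.007 at ROI level). `auc_mean` is the mean over the
five test folds; the CI comes from pooled out-of-fold scores;
sensitivity/specificity are at validation-chosen Youden thresholds.

The same study runs from the shell:

```
periradiomics simulate --n-patients 60 --seed 11 --out data/
periradiomics extract  --dataset data/ --out features.csv
periradiomics evaluate --features features.csv --seed 11 --out results/
periradiomics compare  --results results/
periradiomics clinstats          # cohort-table chi-square statistics
periradiomics report   --results results/ --out figures/
```

## Layout

| module | contents |
| --- | --- |
| `periradiomics.phantom` | synthetic mammogram cohorts with injectable core/rim texture signal |
| `periradiomics.regions` | Otsu body mask; distance-transform rings and combined regions |
| `periradiomics.features` | the 97-feature 2D radiomics engine |
| `periradiomics.modeling` | `CorrelationFilter`, `L1LogisticModel` (sklearn-style estimators) |
| `periradiomics.cnn` | small numpy CNN with class-activation maps |
| `periradiomics.evaluation` | AUC, DeLong test, CV plans, operating points |
| `periradiomics.study` | the cross-validated 11-model region comparison |
| `periradiomics.clinstats` | cohort-table chi-square / t statistics |
| `periradiomics.experiments` | the benchmark studies run by the acceptance script |
| `periradiomics.cli` | `periradiomics` command-line pipeline |
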