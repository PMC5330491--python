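# gliovol

Longitudinal volumetry of glioblastoma (GB) MRI follow-ups: does the
*change in absolute tumor volume* or the *registered, voxel-wise mask
subtraction* better detect disease progression?

Response assessment in GB rests on two tumor compartments: the
gadolinium contrast-enhancing volume (**CV**, segmented on T1-weighted
MPRage) and the FLAIR-hyperintense, tumor-related volume (**FV**, a
superset of CV that includes non-enhancing tumor and edema).  Between two
consecutive scans, four volumetric determinants can be computed:

- **dCV, dFV** — the delta volumes `V₂ − V₁`, divided by the absolute
  least significant change (LSC) of the measurement method,
  `dCV = (V₂ − V₁) / (LSC_CV · V₁)` with `LSC_CV = 0.352`,
  `LSC_FV = 0.144`.  A corrected delta with `|d| > 1` exceeds
  single-rater measurement precision.
- **sCV, sFV** — regional, segmentation-based subtractions: after rigid
  registration of the scan pair, the volume of voxels present in the
  follow-up mask but absent from the baseline mask (new tumor by
  location; always ≥ 0).

The binary progression endpoint per follow-up is a multidisciplinary
consensus (MC) built hierarchically from histopathology → tumor-board
decision → radiologic consensus (a 0–5 rating scale), dichotomized
(category 5 = progression; 0/1 = excluded).  The determinants enter a
logistic mixed-effects model with a per-patient random intercept,

```
logit P(progression_ij) = β₀ + β·x_ij + b_i ,   b_i ~ N(0, σ²),
```

fitted by marginal maximum likelihood (Gauss–Hermite quadrature).
Competing models (delta vs. subtraction) are compared by patient-grouped
5-fold cross-validated ROC curves, DeLong's test for correlated AUCs, and
an exact binomial test of classification accuracy against the
no-information rate.

Because clinical images cannot be redistributed, the package ships a
first-class synthetic cohort generator: ~30 patients × 3–12 scans with
realistic CV/FV trajectories (median CV ≈ 2.8 ml, FV ≈ 50 ml), known
progression ground truth driven chiefly by CV growth, 0–5 ratings with
configurable rater noise, and full 3D phantom rendering (lobulated
multi-ellipsoid tumors on rigidly displaced native grids) for end-to-end
validation of segmentation, registration and mask subtraction.

## Worked example

```python
import gliovol as gv

# synthetic 30-patient cohort with known ground truth
spec = gv.PhantomSpec(seed=1)
table, truth = gv.simulate_cohort_table(spec)

# per-pair change determinants and consensus labels
changes = gv.label_change_table(gv.build_change_table(table))
modelled = changes.dropna(subset=["label"])

# four-predictor logistic mixed model (Table-style output)
fit, coef = gv.fit_glmm(modelled, gv.ModelSpec())
print(coef.round(4))

# delta vs subtraction: cross-validated ROC comparison
res = gv.compare_models(modelled, fold_seed=1)
print(f"AUC delta {res['model_a'].auc:.3f} vs subtraction "
      f"{res['model_b'].auc:.3f}, DeLong P = {res['delong']['p']:.4f}")
```

prints (seed 1):

```
             Estimate  Std. Error       P
(Intercept)   -2.8521      0.5920  0.0000
dcv            1.4024      0.2579  0.0000
dfv            0.2232      0.1652  0.1766
scv_ml        -0.0510      0.0238  0.0322
sfv_ml         0.0230      0.0162  0.1566
AUC delta 0.917 vs subtraction 0.726, DeLong P = 0.0001
```

Only the LSC-corrected contrast-enhancement delta (`dcv`) is
significantly associated with progression; the delta model separates
progressive from non-progressive follow-ups better than the
registration-dependent subtraction model — subtraction volumes inherit
residual misalignment and boundary-redraw noise, which is exactly what
the phantom generator emulates.

The same analysis can start from rendered 3D images (`mode: image`), in
which case volumes come from two-plane seeded region-growing
segmentation and subtractions from rigidly registered, nearest-neighbour
resampled masks:

```bash
gliovol report --mode table --seed 1 --out-dir results/run1
gliovol simulate --seed 1 --out cohort.csv
gliovol delta --volumes cohort.csv --lsc-cv 0.352 --lsc-fv 0.144 --out changes.csv
gliovol label --changes changes.csv --out labelled.csv
gliovol fit --changes labelled.csv --predictors dcv,dfv,scv_ml,sfv_ml
gliovol evaluate --changes labelled.csv --compare dcv,dfv:scv_ml,sfv_ml
```

`gliovol report` writes a full bundle: descriptive medians with 25/75
percentiles, the coefficient table, out-of-fold predictions, ROC points,
`summary.json`, and ROC / predicted-probability figures.  Every output
embeds the config hash and seed; table-mode reruns are bit-identical.
Runs are configured with a YAML file (`gliovol report --config run.yaml`):

```yaml
mode: image                # or: table
out_dir: results/run1
seed: 1
n_folds: 5
progression_categories: [5]
tolerance_k: 2.5           # segmentation intensity band width
registration_threshold: 0.5
lsc: {lsc_cv: 0.352, lsc_fv: 0.144, reference: baseline}
phantom: {n_patients: 10, grid_shape: [96, 96, 96]}
write_nifti: false
```

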