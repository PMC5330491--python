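# Methods

## Volumetric determinants

Each consecutive scan pair (t → t+1) of a patient yields four candidate
predictors of progression.

**Delta volumes.**  `dV_ml = V₂ − V₁` (ml), computed independently for
the contrast-enhancing compartment (CV) and the FLAIR-hyperintense
compartment (FV).  Raw deltas are divided by the *absolute least
significant change* to remove the volume-proportional precision error of
semi-automated segmentation: `d = dV / (lsc · V_ref)`.  The LSC fractions
default to 0.352 (CV) and 0.144 (FV), the published single-rater
precision limits of this class of region-growing tool; `|d| > 1` marks a
change larger than measurement noise.  The reference volume `V_ref` is
the baseline volume of the pair (scan t).  The phrase "absolute LSC"
leaves the reference ambiguous; baseline was chosen because it yields a
dimensionless, scale-invariant quantity and corresponds to the question
"did the tumor change relative to what was there before?".  The pair
mean is available as `LscParams(reference="pair_mean")` for sensitivity
analysis.  Baselines below one voxel volume (post-resection scans with
no residual enhancement) are floored at `floor_ml = 0.001` and flagged,
keeping the quotient finite.

**Regional subtractions.**  After rigid registration of the pair, the
follow-up mask is resampled into the baseline grid (nearest neighbour,
so labels stay binary) and the subtraction mask is `followup ∧ ¬baseline`
— voxels occupied by tumor at follow-up but not at baseline.  Its volume
`s_ml ≥ 0` satisfies, exactly and on every pair,
`|followup| = |followup ∩ baseline| + s_ml`.  Only the growth direction
is fed to the models (the reverse subtraction can be computed by
swapping arguments); when follow-up ⊇ baseline, `s_ml` reduces to the
raw delta.

## Segmentation

Commercial smart-brush tools are proprietary; the implementation here is
a documented stand-in that reproduces the *workflow* (two orthogonal 2D
contours → rough 3D interpolation → manual correction) with a
transparent algorithm: the union of the axial and coronal seed regions
defines an intensity band `mean ± k·sd` (k = 2.5 by default, inclusive
bounds), the band is flood-filled from the seeds with 6-connected
(face-adjacent) growth, and a radius-1 morphological closing smooths the
result.  Necrosis, cavities and vessels are excluded by the band and by
`manual_edit` (set union/difference), not by a dedicated classifier.
Growth beyond a configurable volume cap raises a runaway-growth error
(the signal that the tolerance is too loose).  Loosening the tolerance
can only enlarge the mask (monotonicity), seeds are always contained,
and with closing disabled the result equals an exhaustive breadth-first
in-band flood fill (tested against a naive oracle).

## Registration

Consecutive pairs are aligned with a 6-DOF rigid transform maximising
Mattes mutual information (32 bins, full sampling by default) over a
3-level shrink pyramid with regular-step gradient descent.  MI was
chosen so the same code path works across MPRage/FLAIR contrasts;
within the pipeline the FLAIR pair is registered, because the large FV
compartment constrains the fit far better than a possibly sub-millilitre
enhancing lesion (small lesions are the classic rigid-registration
failure mode).  Acceptance is gated by a foreground-overlap score: the
Dice coefficient of the foreground voxel sets (above
`median + 0.25·(max − median)`) of the fixed and the aligned moving
image.  Aligned structured pairs score ≈ 0.9+, unrelated noise pairs
score near the chance foreground fraction (≈ 0.1–0.2); the default gate
is 0.5.  Rejected pairs are excluded from regional subtraction but not
from delta volumes, which need no registration.  Masks are resampled
nearest-neighbour; transforms serialise as plain-text 4×4 matrices.

## Consensus and endpoint

Scans are rated 0–5 (0 initial, 1 immediate postoperative, 2 regression,
3 stable, 4 uncertain progression, 5 progression).  Inter-rater
agreement is Cohen's κ on the nominal scale (κ defined as 1 when both
raters are constant and identical).  The multidisciplinary consensus
takes, in order: histopathology, tumor-board decision, radiologic
consensus; the tier used is recorded.  Dichotomization maps 5 → yes,
2/3 → no, and excludes 0/1 (no preceding comparison; postoperative
scans suffer brain shift and resection-cavity artefacts).  Category 4
("uncertain progression", e.g. pseudo-progression after radiotherapy)
maps to *no* by default — uncertainty is not evidence of progression —
with `progression_categories=(4, 5)` available as a config switch, since
the clinically correct handling is genuinely debatable.

## Progression model

Logistic regression with a per-patient random intercept, fitted by
*marginal maximum likelihood*: the intercept is integrated out with
25-node Gauss–Hermite quadrature (for a single scalar random effect at
the σ values seen here this is at least as accurate as a Laplace
approximation; agreement with lme4's adaptive-quadrature fits is ~1e-3
on coefficients in the cross-check test).  Optimisation is L-BFGS-B on
`(β, log σ)` with an analytic gradient; Wald standard errors and
two-sided P-values come from a finite-difference Hessian at the optimum,
matching the Estimate/SE/P reporting convention.  Separation or
non-convergence triggers a single ridge-penalised refit (penalty 1.0),
flagged in the result — never silently.

**Cross-validation.**  5-fold, *grouped by patient* by default so all
follow-ups of a patient share a fold; anything else leaks the random
intercept across folds (an observation-level option exists for
sensitivity analysis).  Held-out patients have no estimated intercept,
so out-of-fold probabilities use the population-level predictor
(b = 0).  Folds derive from a dedicated fold seed; training folds that
collapse to a single class fall back to the base rate and are logged.

**Evaluation.**  AUC follows the Mann–Whitney convention (ties ½) and is
tested against brute-force pair counting.  Two models on the same
observations are compared with DeLong's structural-components estimator
of the AUC-difference variance (placement values per case); identical
orderings give zero variance, reported as P = 1 with a degeneracy flag.
Both a pooled out-of-fold AUC and a mean-over-folds AUC are emitted,
since either pooling convention is found in practice.  Classification
accuracy uses a 0.5 probability threshold and is tested against the
no-information rate (majority-class rate) with an exact one-sided
binomial test.

## Synthetic cohort generator

The generator emulates a single-centre GB follow-up cohort and is the
ground truth for every end-to-end test.  Defaults (all overridable on
`PhantomSpec`):

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 30 | cohort size |
| `scans_per_patient` | 3–12 | drawn from the empirical histogram {3:6, 4:3, 5:7, 6:7, 7:4, 8:1, 10:1, 12:1} |
| `cv_baseline_median_ml`, `cv_baseline_sigma` | 1.5 ml, 0.8 | log-normal CV at cohort entry |
| `fv_to_cv_ratio_median`, `fv_to_cv_ratio_sigma` | 30, 0.5 | FV/CV at entry (FV ⊇ CV enforced throughout) |
| `progression_prob`, `regression_prob` | 0.55, 0.12 | per-follow-up event probabilities (constant hazard; the within-patient timing of events is deliberately a parameter, not a fixed schedule) |
| `growth_effect` | 1.9 | multiplicative CV change on progression (1 ⇒ null cohort) |
| `fv_coupling`, `fv_fluct_sd`, `fv_drift` | 0.3, 0.22, −0.04 | FV reacts weakly to CV events, fluctuates on its own (edema, steroids) and drifts slightly down under therapy |
| `pseudo_progression_prob` | 0.15 | enhancement increase without true progression (rated 4) |
| `uncertain_progression_prob` | 0.15 | true progression rated 4 at the time |
| `meas_sigma_cv/fv` | 0.352/2.77, 0.144/2.77 | log-scale measurement noise; σ = LSC/2.77 per the convention LSC = 1.96·√2·σ |
| `scv_shell_mm`, `sfv_shell_mm` | 1.5, 3.0 | effective misalignment of the subtraction surface-shell model |
| `noise_sd`, `misregistration_sd` | 0.08, 2.0 | image noise; inter-scan rigid offset (mm and degrees) |

Entry volumes, the scans histogram and the event rates were calibrated
once so that cohort-level medians bracket the reference clinical values
(median CV ≈ 2.8 ml, FV ≈ 50 ml across scans, ~55% progression among
follow-ups, rater κ ≈ 0.85); they are study conditions, not tuning
knobs.  Progression labels are 1 iff the growth effect was applied, so
labels correlate chiefly with CV increase — the structure the model
comparison is supposed to recover.  With `growth_effect = 1` (and the
other event effects neutralised) labels are independent of the volume
trajectories, giving a null cohort for calibration checks.

**Tabular subtraction model.**  In table mode, sCV/sFV are synthesised
as `max(dV, 0) + ½ · A(V) · m / 1000`, where `A(V) = 1.3·(36π)^⅓·(1000·V)^⅔`
is a lobulation-inflated sphere surface (mm²) and `m ~ |N(0, shell)|` an
effective misalignment combining residual registration error and
boundary-redraw jitter.  This is precisely the mechanism that makes
regional subtractions noisier than deltas — misalignment sweeps a
surface shell of spurious "new" voxels — and it reproduces the
qualitative orderings (median sFV ≫ median dFV; delta model AUC above
subtraction model AUC).  In image mode the subtractions are instead
*measured* from registered, resampled segmentation masks.

**Rendering.**  Tumors are unions of 2–5 random ellipsoids (QR-sampled
orientations, lobe centres on a 25 mm scale) with a smooth angular
lobulation of the implicit field; FV uses the same lobes at twice the
axes.  Because the implicit field is monotone in overall scale, a mask
of any requested volume is obtained exactly by thresholding the field at
the k-th smallest value (k = volume / voxel volume), after which the
stored true volume is set to the voxelised mask volume, making
mask-derived and stored volumes agree exactly.  Scans are rendered in
native grids related to the anatomy by per-scan rigid poses (the stored
ground-truth transforms); intensities are piecewise-constant
(background 0.2, FV 0.35/1.0, CV 1.0) plus Gaussian noise.  Tumors
touching the grid boundary raise a generation error.  Optional
confounders place a dark cavity with a bright enhancing rim adjacent to
— but disjoint from — the truth masks.

**What the phantoms do not emulate:** brain anatomy, bias fields, Rician
noise, partial-volume boundaries, resection-cavity collapse, nonrigid
brain shift, or therapy-specific enhancement dynamics beyond the generic
confounder toggle.  Passing tests therefore demonstrate the correctness
and statistical behaviour of the pipeline under known truth, not
clinical segmentation or registration performance on real MRI.

## Numerical choices

- Voxel convention: 0-based indices, world = origin + spacing · index,
  axis-aligned grids; volumes are exact voxel counts × voxel volume.
  Default voxel size 1×1×1 mm.
- Intensity band bounds inclusive; band half-width floored at 1e-9 so a
  noiseless (zero-variance) seed still defines a valid band.
- Percentiles: linear interpolation, 25th/75th.
- Quadrature: 25 Hermite nodes; `log σ` bounded in [log 1e-4, 5]; a fit
  at the lower bound is reported as σ = 0.
- Random streams: every stochastic component (cohort, per-scan image
  noise, fold assignment) derives from an explicit integer seed through
  independent `SeedSequence` keys, so table-mode reruns are
  bit-identical and image noise does not depend on rendering order.

## Problem sizes in the validation suite

Monte-Carlo checks use 1,000 mask pairs (16³) for mask algebra, 10
fixed instances × 10,000 bootstrap replicates for the DeLong variance,
100 replicates of 200 patients × 5 pairs for parameter recovery, 200
null-cohort replicates for P-value calibration, 50 study-scale cohorts
for the model-ordering check, and 50 rendered 96³ phantoms for
segmentation recovery; these sizes give stable pass/fail margins for the
stated thresholds.

## Known limitations

- The region-growing stand-in is not voxel-for-voxel equivalent to any
  commercial tool; its parameters are surfaced in config rather than
  claimed to match.
- Rigid registration of a single compact lesion constrains rotation
  weakly; the pipeline mitigates this by registering on FLAIR, and the
  acceptance gate flags the remainder.
- The mixed model uses Wald inference; profile-likelihood intervals are
  not implemented.
- Image-mode runs are CPU-bound (registration dominates); study-scale
  image cohorts take minutes, so the statistical claims are validated in
  table mode and image mode is exercised on mini-cohorts.
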