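"""Mixed-effects progression classification and ROC-based model comparison.

Fits logistic random-intercept (patient) models of the binary progression
endpoint from the volumetric determinants (dCV, dFV, sCV, sFV), evaluates
them with patient-grouped 5-fold cross-validation, and compares competing
models with DeLong's test for correlated ROC curves plus an exact binomial
test of classification accuracy against the no-information rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .glmm import MixedLogitResult, fit_mixed_logit

__all__ = [
    "ModelSpec",
    "ModelResult",
    "fit_glmm",
    "crossvalidate",
    "roc_auc",
    "delong_test",
    "binomial_accuracy_test",
    "compare_models",
]

DEFAULT_PREDICTORS = ("dcv", "dfv", "scv_ml", "sfv_ml")


@dataclass
class ModelSpec:
    """What to fit and how to cross-validate.

    ``predictors`` name columns of the change table; ``grouping`` is
    ``"patient"`` (all follow-ups of a patient share a fold, the default,
    which prevents random-effect leakage across folds) or
    ``"observation"`` for plain observation-level folds.
    """

    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    n_folds: int = 5
    fold_seed: int = 0
    grouping: str = "patient"
    n_nodes: int = 25

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("predictors must be non-empty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.grouping not in ("patient", "observation"):
            raise ValueError("grouping must be 'patient' or 'observation'")


@dataclass
class ModelResult:
    spec: ModelSpec
    fit: MixedLogitResult
    coefficients: pd.DataFrame  # Estimate / Std. Error / P per term
    cv_probabilities: np.ndarray  # out-of-fold predicted probabilities
    cv_labels: np.ndarray
    cv_fold: np.ndarray
    auc: float  # pooled out-of-fold AUC
    auc_ci: tuple[float, float]
    auc_mean_folds: float  # mean of per-fold AUCs (alternative convention)
    roc_points: pd.DataFrame
    accuracy: float
    accuracy_ci: tuple[float, float]
    binomial_p: float
    nir: float
    fold_notes: list[str] = field(default_factory=list)


def _design(data: pd.DataFrame, spec: ModelSpec):
    d = data.dropna(subset=[*spec.predictors, "label"])
    X = d[list(spec.predictors)].to_numpy(dtype=float)
    y = d["label"].to_numpy(dtype=float)
    groups = d["patient_id"].to_numpy()
    return d, X, y, groups


def fit_glmm(data: pd.DataFrame, spec: ModelSpec, penalty: float = 0.0,
             fixed_sigma: float | None = None) -> tuple[MixedLogitResult, pd.DataFrame]:
    """Fit the logistic mixed model on all labelled rows of a change table.

    Requires columns ``patient_id``, ``label`` and the spec's predictors;
    rows with NaN label (excluded categories) or NaN predictors are
    dropped.  Returns the fit and a coefficient table with Wald standard
    errors and two-sided P-values.
    """
    d, X, y, groups = _design(data, spec)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two patients")
    fit = fit_mixed_logit(
        X, y, groups, names=list(spec.predictors), n_nodes=spec.n_nodes,
        penalty=penalty, fixed_sigma=fixed_sigma,
    )
    coef = pd.DataFrame(
        {"Estimate": fit.params, "Std. Error": fit.se, "P": fit.pvalues},
        index=fit.names,
    )
    return fit, coef


def _assign_folds(d: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.fold_seed)
    if spec.grouping == "patient":
        units = np.unique(d["patient_id"].to_numpy())
    else:
        units = np.arange(len(d))
    if spec.n_folds > len(units):
        raise ValueError(
            f"n_folds={spec.n_folds} exceeds the number of groups ({len(units)})"
        )
    perm = rng.permutation(len(units))
    unit_fold = np.empty(len(units), dtype=int)
    for f, chunk in enumerate(np.array_split(perm, spec.n_folds)):
        unit_fold[chunk] = f
    if spec.grouping == "patient":
        lookup = dict(zip(units, unit_fold))
        return np.array([lookup[p] for p in d["patient_id"]])
    return unit_fold


def crossvalidate(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Patient-grouped K-fold out-of-fold predicted probabilities.

    Every labelled observation receives exactly one out-of-fold
    probability, computed from the population-level linear predictor
    (random effect 0 — held-out patients have no estimated intercept).
    Folds are reproducible from ``spec.fold_seed``.  Training folds whose
    outcome collapses to one class are refit as ridge-penalised logistic
    regression (logged in the returned notes).
    """
    d, X, y, groups = _design(data, spec)
    folds = _assign_folds(d, spec)
    probs = np.full(len(d), np.nan)
    notes: list[str] = []
    for f in range(spec.n_folds):
        test = folds == f
        Xtr, ytr, gtr = X[~test], y[~test], groups[~test]
        if ytr.min() == ytr.max():
            # degenerate training fold: fall back to the base rate
            probs[test] = float(ytr.mean())
            notes.append(f"fold {f}: single-class training outcome; base-rate fallback")
            continue
        try:
            fit = fit_mixed_logit(
                Xtr, ytr, gtr, n_nodes=spec.n_nodes, penalty=0.0
            )
            if fit.separated:
                notes.append(f"fold {f}: separation; ridge-penalised refit used")
        except Exception:  # non-convergence safeguard
            fit = fit_mixed_logit(Xtr, ytr, gtr, n_nodes=spec.n_nodes, penalty=1.0)
            notes.append(f"fold {f}: refit with ridge penalty after failure")
        probs[test] = fit.predict_population(X[test])
    return probs, y, folds, notes


def roc_auc(labels, probabilities) -> tuple[pd.DataFrame, float]:
    """ROC points and the AUC (Mann–Whitney convention, ties count 1/2)."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(probabilities, dtype=float)
    if y.min() == y.max():
        raise ValueError("ROC is undefined with a single class")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thr = roc_curve(y, s)
    pts = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return pts, float(auc)


def _placements(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (placement values) for one score vector."""
    pos = s[y == 1]
    neg = s[y == 0]
    # V10[i] = P(score_i > neg) with ties 1/2, per positive case
    v10 = (pos[:, None] > neg[None, :]).mean(axis=1) + 0.5 * (
        pos[:, None] == neg[None, :]
    ).mean(axis=1)
    v01 = (neg[:, None] < pos[None, :]).mean(axis=1) + 0.5 * (
        neg[:, None] == pos[None, :]
    ).mean(axis=1)
    return v10, v01, float(v10.mean())


def delong_auc_variance(labels, probabilities) -> tuple[float, float]:
    """(AUC, variance of the AUC) by DeLong's estimator."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(probabilities, dtype=float)
    v10, v01, auc = _placements(y, s)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    return auc, float(var)


def delong_test(labels, probs_a, probs_b) -> dict:
    """DeLong's test for two correlated ROC curves on the same observations.

    Returns auc_a, auc_b, the z statistic for ``auc_a - auc_b``, the
    two-sided P-value, and the variance of the difference.  Identical
    score orderings give zero variance; that case is reported as P = 1
    with ``degenerate=True``.
    """
    y = np.asarray(labels, dtype=float)
    sa = np.asarray(probs_a, dtype=float)
    sb = np.asarray(probs_b, dtype=float)
    if not (len(y) == len(sa) == len(sb)):
        raise ValueError("both models must score the same observations")
    v10a, v01a, auc_a = _placements(y, sa)
    v10b, v01b, auc_b = _placements(y, sb)
    n1, n0 = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    l = np.array([1.0, -1.0])
    var = float(l @ (s10 / n1 + s01 / n0) @ l)
    if var <= 0:
        return {
            "auc_a": auc_a, "auc_b": auc_b, "z": 0.0, "p": 1.0,
            "var_diff": 0.0, "degenerate": True,
        }
    z = (auc_a - auc_b) / np.sqrt(var)
    return {
        "auc_a": auc_a, "auc_b": auc_b, "z": float(z),
        "p": float(2.0 * stats.norm.sf(abs(z))), "var_diff": var,
        "degenerate": False,
    }


def binomial_accuracy_test(correct: int, total: int, nir: float) -> float:
    """Exact one-sided binomial P that accuracy exceeds the no-information
    rate: ``P(X >= correct | total, nir)``."""
    if not 0 <= correct <= total:
        raise ValueError("need 0 <= correct <= total")
    if not 0.0 < nir < 1.0:
        raise ValueError("nir must lie in (0, 1)")
    return float(stats.binomtest(correct, total, nir, alternative="greater").pvalue)


def _evaluate(spec: ModelSpec, data: pd.DataFrame, threshold: float = 0.5) -> ModelResult:
    fit, coef = fit_glmm(data, spec)
    probs, y, folds, notes = crossvalidate(data, spec)
    pts, auc = roc_auc(y, probs)
    _, var = delong_auc_variance(y, probs)
    se = np.sqrt(var)
    ci = (max(auc - 1.96 * se, 0.0), min(auc + 1.96 * se, 1.0))
    fold_aucs = []
    for f in np.unique(folds):
        yf, pf = y[folds == f], probs[folds == f]
        if yf.min() != yf.max():
            fold_aucs.append(roc_auc(yf, pf)[1])
    pred = (probs >= threshold).astype(float)
    correct = int((pred == y).sum())
    total = len(y)
    acc = correct / total
    acc_lo, acc_hi = stats.binomtest(correct, total).proportion_ci(0.95, method="exact")
    nir = float(max(y.mean(), 1.0 - y.mean()))
    return ModelResult(
        spec=spec,
        fit=fit,
        coefficients=coef,
        cv_probabilities=probs,
        cv_labels=y,
        cv_fold=folds,
        auc=auc,
        auc_ci=ci,
        auc_mean_folds=float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
        roc_points=pts,
        accuracy=acc,
        accuracy_ci=(float(acc_lo), float(acc_hi)),
        binomial_p=binomial_accuracy_test(correct, total, nir),
        nir=nir,
        fold_notes=notes,
    )


def compare_models(
    data: pd.DataFrame,
    predictors_a: tuple[str, ...] = ("dcv", "dfv"),
    predictors_b: tuple[str, ...] = ("scv_ml", "sfv_ml"),
    n_folds: int = 5,
    fold_seed: int = 0,
    grouping: str = "patient",
) -> dict:
    """Head-to-head cross-validated comparison of two predictor sets.

    The canonical comparison is delta volumes (dCV, dFV) versus regional
    subtractions (sCV, sFV).  Both models are evaluated on the same
    fold assignment and the same observations; DeLong's test compares the
    pooled out-of-fold ROC curves.
    """
    base = dict(n_folds=n_folds, fold_seed=fold_seed, grouping=grouping)
    # evaluate on the intersection of complete cases so both models score
    # the same observations
    needed = sorted(set(predictors_a) | set(predictors_b) | {"label"})
    d = data.dropna(subset=needed)
    res_a = _evaluate(ModelSpec(predictors=tuple(predictors_a), **base), d)
    res_b = _evaluate(ModelSpec(predictors=tuple(predictors_b), **base), d)
    dl = delong_test(res_a.cv_labels, res_a.cv_probabilities, res_b.cv_probabilities)
    return {"model_a": res_a, "model_b": res_b, "delong": dl}
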