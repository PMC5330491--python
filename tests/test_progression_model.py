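"""ROC/AUC, DeLong test, binomial accuracy test, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliovol.glmm import simulate_mixed_logit
from gliovol.progression_model import (
    ModelSpec,
    binomial_accuracy_test,
    compare_models,
    crossvalidate,
    delong_test,
    fit_glmm,
    roc_auc,
)


def _brute_force_auc(y, s):
    y, s = np.asarray(y), np.asarray(s)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_hand_example_three_of_four_concordant(self):
        _, auc = roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2])
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_equals_pair_counting_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 120))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            _, auc = roc_auc(y, s)
            assert auc == pytest.approx(_brute_force_auc(y, s), abs=1e-12)

    def test_uninformative_scores_near_half(self, rng):
        y = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        _, auc = roc_auc(y, s)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.5, 0.6])

    def test_roc_curve_monotone(self, rng):
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        pts, _ = roc_auc(y, s)
        assert np.all(np.diff(pts["tpr"]) >= 0)
        assert np.all(np.diff(pts["fpr"]) >= 0)


class TestDeLong:
    def test_identical_models_give_p_one(self, rng):
        y = rng.integers(0, 2, 40)
        y[:3], y[-3:] = 1, 0
        s = rng.random(40)
        res = delong_test(y, s, s)
        assert res["p"] == 1.0
        assert res["degenerate"]

    def test_antisymmetry(self, rng):
        y = rng.integers(0, 2, 60)
        y[0], y[-1] = 1, 0
        a, b = rng.random(60), rng.random(60)
        r1 = delong_test(y, a, b)
        r2 = delong_test(y, b, a)
        assert r1["z"] == pytest.approx(-r2["z"], abs=1e-12)
        assert r1["p"] == pytest.approx(r2["p"], abs=1e-12)

    def test_variance_matches_stratified_bootstrap(self):
        """DeLong variance of the AUC difference vs a 10,000-rep stratified
        bootstrap on small fixed instances (n = 20)."""
        rng = np.random.default_rng(2024)
        checked = 0
        for inst in range(10):
            y = np.array([1] * 10 + [0] * 10)
            signal = y * rng.normal(0.8, 0.3, 20)
            a = signal + rng.normal(0, 1.0, 20)
            b = signal + rng.normal(0, 1.0, 20)
            res = delong_test(y, a, b)
            if res["degenerate"]:
                continue
            pos_idx, neg_idx = np.where(y == 1)[0], np.where(y == 0)[0]
            boots = np.empty(10000)
            for r in range(10000):
                pi = rng.choice(pos_idx, 10, replace=True)
                ni = rng.choice(neg_idx, 10, replace=True)
                da = (a[pi][:, None] > a[ni][None, :]).mean() + 0.5 * (
                    a[pi][:, None] == a[ni][None, :]
                ).mean()
                db = (b[pi][:, None] > b[ni][None, :]).mean() + 0.5 * (
                    b[pi][:, None] == b[ni][None, :]
                ).mean()
                boots[r] = da - db
            boot_var = boots.var(ddof=1)
            assert res["var_diff"] == pytest.approx(boot_var, rel=0.35)
            checked += 1
        assert checked >= 8


class TestBinomialAccuracy:
    def test_expected_count_gives_about_half(self):
        total, nir = 200, 0.642
        p = binomial_accuracy_test(int(round(total * nir)), total, nir)
        assert 0.35 < p < 0.65

    def test_all_correct_closed_form(self):
        assert binomial_accuracy_test(12, 12, 0.642) == pytest.approx(0.642**12, rel=1e-9)

    def test_matches_bruteforce_tail_sum(self):
        correct, total, nir = 79, 109, 0.642
        p = binomial_accuracy_test(correct, total, nir)
        brute = sum(
            stats.binom.pmf(k, total, nir) for k in range(correct, total + 1)
        )
        assert p == pytest.approx(brute, rel=1e-9)


def _cohort_frame(n_groups=40, n_per=4, seed=0):
    X, y, g = simulate_mixed_logit(
        n_groups, n_per, beta=[-0.5, 0.9, 0.0], sigma=0.5, seed=seed
    )
    return pd.DataFrame(
        {"patient_id": g, "dcv": X[:, 0], "dfv": X[:, 1], "label": y}
    )


class TestCrossValidation:
    def test_every_observation_scored_once_and_deterministic(self):
        d = _cohort_frame()
        spec = ModelSpec(predictors=("dcv", "dfv"), fold_seed=9)
        p1, y1, f1, _ = crossvalidate(d, spec)
        p2, y2, f2, _ = crossvalidate(d, spec)
        assert np.isfinite(p1).all()
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(f1, f2)
        assert ((p1 >= 0) & (p1 <= 1)).all()

    def test_grouped_folds_keep_patients_together(self):
        d = _cohort_frame()
        spec = ModelSpec(predictors=("dcv",), fold_seed=1)
        _, _, folds, _ = crossvalidate(d, spec)
        per_patient = pd.DataFrame({"pid": d["patient_id"], "fold": folds}).groupby("pid")[
            "fold"
        ].nunique()
        assert (per_patient == 1).all()

    def test_leave_one_patient_out_boundary(self):
        d = _cohort_frame(n_groups=8, n_per=3)
        spec = ModelSpec(predictors=("dcv",), n_folds=8, fold_seed=2)
        probs, _, folds, _ = crossvalidate(d, spec)
        assert len(np.unique(folds)) == 8
        assert np.isfinite(probs).all()

    def test_too_many_folds_rejected(self):
        d = _cohort_frame(n_groups=3, n_per=3)
        with pytest.raises(ValueError):
            crossvalidate(d, ModelSpec(predictors=("dcv",), n_folds=10))

    def test_optimism_small_at_scale(self):
        """Cross-validated AUC close to training AUC for a strong signal at
        n >= 150 patients."""
        d = _cohort_frame(n_groups=150, n_per=4, seed=5)
        spec = ModelSpec(predictors=("dcv", "dfv"), fold_seed=3)
        fit, _ = fit_glmm(d, spec)
        train_probs = fit.predict_population(d[["dcv", "dfv"]].to_numpy())
        _, train_auc = roc_auc(d["label"], train_probs)
        probs, y, _, _ = crossvalidate(d, spec)
        _, cv_auc = roc_auc(y, probs)
        assert abs(train_auc - cv_auc) < 0.05


class TestFitGlmm:
    def test_constant_predictors_give_chance_auc(self):
        d = _cohort_frame(n_groups=60, n_per=3, seed=2)
        d["flat"] = 1.0
        fit, coef = fit_glmm(d, ModelSpec(predictors=("flat",)))
        probs = fit.predict_population(d[["flat"]].to_numpy())
        assert np.allclose(probs, probs[0])
        _, auc = roc_auc(d["label"], probs + 1e-9 * np.arange(len(d)))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_coefficient_table_layout(self, default_cohort):
        from gliovol.change_metrics import build_change_table
        from gliovol.consensus import label_change_table

        _, table, _ = default_cohort
        ch = label_change_table(build_change_table(table)).dropna(subset=["label"])
        fit, coef = fit_glmm(ch, ModelSpec())
        assert list(coef.columns) == ["Estimate", "Std. Error", "P"]
        assert list(coef.index) == ["(Intercept)", "dcv", "dfv", "scv_ml", "sfv_ml"]
        assert fit.converged


def test_compare_models_scores_same_observations(default_cohort):
    from gliovol.change_metrics import build_change_table
    from gliovol.consensus import label_change_table

    _, table, _ = default_cohort
    ch = label_change_table(build_change_table(table)).dropna(subset=["label"])
    res = compare_models(ch, fold_seed=4)
    a, b = res["model_a"], res["model_b"]
    assert len(a.cv_probabilities) == len(b.cv_probabilities)
    np.testing.assert_array_equal(a.cv_labels, b.cv_labels)
    assert 0.0 <= res["delong"]["p"] <= 1.0
    assert 0.0 <= a.auc <= 1.0 and 0.0 <= b.auc <= 1.0
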