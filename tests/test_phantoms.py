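"""Synthetic cohort generator: determinism, calibration, containment."""

import numpy as np
import pandas as pd
import pytest

from gliovol.phantoms import (
    GenerationError,
    PhantomSpec,
    render_scan,
    simulate_cohort_table,
    true_pair_transform,
)


def test_same_seed_reproduces_table_exactly():
    spec = PhantomSpec(seed=5)
    t1, _ = simulate_cohort_table(spec)
    t2, _ = simulate_cohort_table(PhantomSpec(seed=5))
    pd.testing.assert_frame_equal(t1, t2)


def test_different_seeds_differ():
    t1, _ = simulate_cohort_table(PhantomSpec(seed=1))
    t2, _ = simulate_cohort_table(PhantomSpec(seed=2))
    assert not t1["cv_ml"].equals(t2["cv_ml"])


def test_cohort_structure(default_cohort):
    spec, table, truth = default_cohort
    assert table["patient_id"].nunique() == spec.n_patients
    sizes = table.groupby("patient_id").size()
    assert sizes.min() >= 3 and sizes.max() <= 12
    assert table["rating"].between(0, 5).all()
    assert (table["fv_ml"] >= table["cv_ml"]).all()
    # every follow-up has a progression label; first scans do not
    firsts = table["scan_index"] == 0
    assert table.loc[firsts, "progression"].isna().all()
    assert table.loc[~firsts, "progression"].isin([0.0, 1.0]).all()


def test_marginal_medians_emulate_study_cohort():
    """Cohort-level CV/FV medians bracket the reference values (2.80 /
    50.10 ml) with wide tolerance at the default spec."""
    cv_meds, fv_meds = [], []
    for seed in (0, 1, 2, 3, 4):
        table, _ = simulate_cohort_table(PhantomSpec(seed=seed))
        cv_meds.append(table["cv_ml"].median())
        fv_meds.append(table["fv_ml"].median())
    assert 2.80 * 0.5 <= np.median(cv_meds) <= 2.80 * 1.5
    assert 50.10 * 0.5 <= np.median(fv_meds) <= 50.10 * 1.5


def test_fixed_seed_cv_median_within_band():
    table, _ = simulate_cohort_table(PhantomSpec(seed=1, n_patients=30))
    assert 2.1 <= table["cv_ml"].median() <= 3.5


def test_null_generator_labels_independent_of_volumes():
    """growth_effect = 1 (with all event effects neutralised) leaves the
    volume trajectory uninformative about the progression labels."""
    spec = PhantomSpec(
        seed=3, n_patients=100, growth_effect=1.0, regression_effect=1.0,
        pseudo_progression_growth=(1.0, 1.0), growth_noise_sd=0.12,
    )
    table, _ = simulate_cohort_table(spec)
    fu = table.dropna(subset=["progression"])
    dcv = fu.groupby("patient_id")["cv_ml"].diff().dropna()
    lab = fu.loc[dcv.index, "progression"]
    r = np.corrcoef(dcv, lab)[0, 1]
    assert abs(r) < 0.1


def test_spec_validation_errors():
    with pytest.raises(ValueError):
        PhantomSpec(scans_per_patient=(2, 5))
    with pytest.raises(ValueError):
        PhantomSpec(grid_shape=(300, 96, 96))
    with pytest.raises(ValueError):
        PhantomSpec(growth_effect=-1.0)
    with pytest.raises(ValueError):
        PhantomSpec(progression_prob=1.5)


class TestRendering:
    def test_noiseless_threshold_recovers_truth_masks(self, mini_image_spec):
        from dataclasses import replace

        spec = replace(mini_image_spec, noise_sd=0.0, misregistration_sd=0.0)
        _, truth = simulate_cohort_table(spec)
        pat = truth.patients[0]
        r = render_scan(spec, pat, pat.scans[0])
        # tumor/background midpoint threshold
        np.testing.assert_array_equal(r.mprage.data >= 0.6, r.cv_mask.grid)
        np.testing.assert_array_equal(r.flair.data >= 0.6, r.fv_mask.grid)
        assert np.all(r.pose_translation_mm == 0.0)

    def test_fv_contains_cv_and_volumes_match_masks(self, mini_image_spec):
        _, truth = simulate_cohort_table(mini_image_spec)
        pat = truth.patients[0]
        for scan in pat.scans[:2]:
            r = render_scan(mini_image_spec, pat, scan)
            assert not (r.cv_mask.grid & ~r.fv_mask.grid).any()
            # stored true volumes regenerate exactly from the masks
            assert r.cv_mask.volume_ml == pytest.approx(scan.true_cv_ml, abs=0)
            assert r.fv_mask.volume_ml == pytest.approx(scan.true_fv_ml, abs=0)

    def test_rendered_volume_calibrated_to_requested(self, mini_image_spec):
        _, truth = simulate_cohort_table(mini_image_spec)
        pat = truth.patients[0]
        requested = pat.scans[0].true_cv_ml
        r = render_scan(mini_image_spec, pat, pat.scans[0])
        # voxelisation quantises to (about) one voxel
        assert abs(r.cv_mask.volume_ml - requested) <= 0.001

    def test_consecutive_scans_differ_by_stored_rigid_offset(self, mini_image_spec):
        """Mapping follow-up truth-mask voxels through the stored pair
        transform lands them on the baseline truth mask (up to resampling)."""
        from gliovol.registration import resample_mask

        spec = PhantomSpec(
            seed=9, n_patients=1, grid_shape=(64, 64, 64),
            cv_baseline_median_ml=3.0, fv_to_cv_ratio_median=8.0,
            progression_prob=0.0, regression_prob=0.0, stable_sd=0.0,
            fv_fluct_sd=0.0, fv_drift=0.0, pseudo_progression_prob=0.0,
            start_at_diagnosis_prob=0.0, noise_sd=0.0, misregistration_sd=1.5,
            meas_sigma_cv=1e-6, meas_sigma_fv=1e-6,
        )
        _, truth = simulate_cohort_table(spec)
        pat = truth.patients[0]
        r0 = render_scan(spec, pat, pat.scans[0])
        r1 = render_scan(spec, pat, pat.scans[1])
        t = true_pair_transform(spec, pat.scans[0], pat.scans[1])
        moved = resample_mask(r1.fv_mask, t, r0.flair)
        inter = (moved.grid & r0.fv_mask.grid).sum()
        dice = 2.0 * inter / (moved.grid.sum() + r0.fv_mask.grid.sum())
        assert dice >= 0.95

    def test_tumor_exceeding_grid_raises(self):
        spec = PhantomSpec(seed=0, n_patients=1, grid_shape=(16, 16, 16),
                           cv_baseline_median_ml=50.0)
        _, truth = simulate_cohort_table(spec)
        pat = truth.patients[0]
        pat.scans[0].true_cv_ml = 500.0
        with pytest.raises(GenerationError):
            render_scan(spec, pat, pat.scans[0])

    def test_confounder_structures_stay_outside_truth_masks(self):
        from dataclasses import replace

        spec = PhantomSpec(
            seed=2, n_patients=1, grid_shape=(72, 72, 72),
            cv_baseline_median_ml=1.5, fv_to_cv_ratio_median=6.0,
            include_confounders=True, noise_sd=0.0, misregistration_sd=0.0,
        )
        _, truth = simulate_cohort_table(spec)
        pat = truth.patients[0]
        r = render_scan(spec, pat, pat.scans[0])
        # inside the truth masks the intensities are untouched
        assert np.all(r.mprage.data[r.cv_mask.grid] == 1.0)
        assert np.all(r.flair.data[r.fv_mask.grid] == 1.0)
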