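"""HbT contrast, ROC analysis, score combination and group tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrnirst import diagnostics as dx
from mrnirst.phantom_synth import InvalidParameterError


def records_from(malignant, benign, **extra):
    recs = []
    for i, v in enumerate(malignant):
        recs.append(dx.SubjectRecord(subject_id=f"M{i}", hbt_contrast=v,
                                     pathology_label="malignant", **extra))
    for i, v in enumerate(benign):
        recs.append(dx.SubjectRecord(subject_id=f"B{i}", hbt_contrast=v,
                                     pathology_label="benign", **extra))
    return recs


def concordance_auc(malignant, benign):
    """Brute-force pairwise concordance with ties counted half."""
    wins = sum((1.0 if m > b else 0.5 if m == b else 0.0)
               for m in malignant for b in benign)
    return wins / (len(malignant) * len(benign))


class TestHbtContrast:
    def test_uniform_map_is_one(self):
        roi = np.zeros(50, bool)
        roi[:5] = True
        assert dx.hbt_contrast(np.full(50, 0.02), roi) == pytest.approx(1.0)

    def test_simple_ratio(self):
        hbt = np.array([2.0, 2.0, 1.0, 1.0, 1.0])
        roi = np.array([True, True, False, False, False])
        assert dx.hbt_contrast(hbt, roi) == pytest.approx(2.0)

    def test_piecewise_phantom_ratio_exact(self, coarse_mesh):
        import mrnirst as mn
        ph = mn.make_phantom(coarse_mesh, mn.TissueProperties.from_hbt(0.02),
                             ((0, 0), 10.0, mn.TissueProperties.from_hbt(0.05)))
        assert dx.hbt_contrast(ph.hbt, ph.inclusion_mask) \
            == pytest.approx(2.5, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        hbt = rng.uniform(0.01, 0.05, 100)
        roi = rng.random(100) < 0.2
        c1 = dx.hbt_contrast(hbt, roi)
        c2 = dx.hbt_contrast(hbt * 7.3, roi)
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(dx.MaskError):
            dx.hbt_contrast(np.ones(10), np.zeros(10, bool))
        with pytest.raises(dx.MaskError):
            dx.hbt_contrast(np.ones(10), np.ones(10, bool))


class TestRoiFromPrior:
    def test_bimodal_gamma(self):
        gamma = np.where(np.arange(300) < 30, 0.9, 0.2)
        mask = dx.roi_from_prior(gamma)
        assert np.array_equal(mask, gamma > 0.55)

    def test_constant_gamma_raises(self):
        with pytest.raises(dx.MaskError):
            dx.roi_from_prior(np.full(100, 0.4))

    def test_mask_size_tracks_lesion(self, coarse_mesh):
        import mrnirst as mn
        from mrnirst.prior_regularization import sample_prior_to_nodes
        mesh = mn.generate_mesh(40.0, 4.0)
        ph = mn.make_phantom(mesh, mn.TissueProperties(),
                             ((0, 0), 10.0, mn.TissueProperties.from_hbt(0.05)))
        prior = mn.render_grayscale_prior(ph, blur_mm=1.0, noise_sd=200.0,
                                          rng=np.random.default_rng(1))
        gamma = sample_prior_to_nodes(prior, mesh)
        mask = dx.roi_from_prior(gamma, mesh.node_adjacency())
        true_size = ph.inclusion_mask.sum()
        assert 0.8 * true_size <= mask.sum() <= 1.2 * true_size


class TestRocAnalysis:
    def test_perfect_separation(self):
        recs = records_from([2.0, 3.0, 2.5], [0.5, 1.0])
        roc = dx.roc_analysis(recs)
        assert roc.auc == pytest.approx(1.0)
        assert roc.best_sensitivity == 1.0
        assert roc.best_specificity == 1.0

    def test_worked_example_auc_075(self):
        recs = records_from([2.0, 1.0], [1.5, 0.5])
        roc = dx.roc_analysis(recs)
        assert roc.auc == pytest.approx(0.75, abs=1e-12)

    def test_null_scores_give_half_auc(self):
        rng = np.random.default_rng(2)
        recs = records_from(rng.normal(size=300) + 2.8,
                            rng.normal(size=300) + 2.8)
        roc = dx.roc_analysis(recs)
        assert roc.auc == pytest.approx(0.5, abs=0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 8), min_size=2, max_size=12),
           st.lists(st.integers(0, 8), min_size=2, max_size=12))
    def test_trapezoid_equals_concordance(self, mal, ben):
        # integer scores force ties; trapezoidal AUC must equal the
        # tie-corrected pairwise concordance exactly
        recs = records_from([m + 1.0 for m in mal], [b + 1.0 for b in ben])
        roc = dx.roc_analysis(recs)
        assert roc.auc == pytest.approx(concordance_auc(
            [m + 1.0 for m in mal], [b + 1.0 for b in ben]), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        mal = rng.normal(2.5, 0.8, 16)
        ben = rng.normal(1.0, 0.4, 8)
        recs = records_from(mal, ben)
        roc = dx.roc_analysis(recs)
        y = [1] * 16 + [0] * 8
        assert roc.auc == pytest.approx(
            roc_auc_score(y, np.concatenate([mal, ben])), abs=1e-12)

    def test_best_cutoff_maximizes_youden_sum(self):
        rng = np.random.default_rng(4)
        recs = records_from(rng.normal(2.5, 1.0, 16), rng.normal(1.2, 0.6, 8))
        roc = dx.roc_analysis(recs)
        scores = [r.hbt_contrast for r in recs]
        best = max(
            (sum(dx.performance_at_cutoff(recs, "hbt_contrast", c)[:2]), )
            for c in list(scores) + [min(scores) - 1])[0]
        got = roc.best_sensitivity + roc.best_specificity
        assert got == pytest.approx(best, abs=1e-12)

    def test_cutoff_performance_consistency(self):
        rng = np.random.default_rng(5)
        recs = records_from(rng.normal(2.5, 1.0, 16), rng.normal(1.2, 0.6, 8))
        roc = dx.roc_analysis(recs)
        sens, spec, acc = dx.performance_at_cutoff(recs, "hbt_contrast",
                                                   roc.best_cutoff)
        assert (sens, spec, acc) == (roc.best_sensitivity,
                                     roc.best_specificity, roc.best_accuracy)

    def test_single_class_rejected(self):
        with pytest.raises(dx.ClassError):
            dx.roc_analysis(records_from([2.0, 1.5], []))


class TestPerformanceAtCutoff:
    def test_cutoff_below_everything(self):
        recs = records_from([2.0, 1.5], [1.0])
        assert dx.performance_at_cutoff(recs, "hbt_contrast", 0.1) \
            == (1.0, 0.0, pytest.approx(2 / 3))

    def test_cutoff_above_everything(self):
        recs = records_from([2.0, 1.5], [1.0])
        assert dx.performance_at_cutoff(recs, "hbt_contrast", 5.0) \
            == (0.0, 1.0, pytest.approx(1 / 3))

    def test_clinical_case_contrasts_at_cutoff_1p1(self):
        # the per-case contrast values with the clinical HbT cutoff of 1.1
        recs = records_from([3.3, 2.8, 1.5], [0.9, 0.5])
        assert dx.performance_at_cutoff(recs, "hbt_contrast", 1.1) \
            == (1.0, 1.0, 1.0)


class TestCombineScores:
    def test_single_perfect_separator(self):
        recs = records_from([2.0, 2.5, 3.0], [0.5, 1.0], birads_score=3)
        out, _coef, ridge = dx.combine_scores(recs, ("hbt_contrast",))
        roc = dx.roc_analysis(out, "combined_score")
        assert roc.auc == pytest.approx(1.0)
        assert ridge  # separable data trip the ridge fallback

    def test_duplicated_field_adds_nothing(self):
        from dataclasses import replace
        rng = np.random.default_rng(6)
        mal, ben = np.exp(rng.normal(0.7, 0.5, 10)), np.exp(rng.normal(0, 0.5, 10))
        recs = records_from(mal, ben)
        single, _, _ = dx.combine_scores(recs, ("hbt_contrast",))
        dup = [replace(r, birads_score=r.hbt_contrast) for r in recs]
        double, _, _ = dx.combine_scores(dup, ("hbt_contrast", "birads_score"))
        a1 = dx.roc_analysis(single, "combined_score").auc
        a2 = dx.roc_analysis(double, "combined_score").auc
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_constant_field_dropped_with_warning(self):
        recs = records_from([2.0, 2.5, 1.4], [0.5, 1.0], birads_score=3)
        with pytest.warns(UserWarning, match="constant"):
            out, coef, _ = dx.combine_scores(recs,
                                             ("hbt_contrast", "birads_score"))
        assert "birads_score" not in coef
        assert all(r.combined_score is not None for r in out)

    def test_two_informative_fields_help(self):
        from dataclasses import replace
        rng = np.random.default_rng(7)
        wins = 0
        for _ in range(10):
            n_m, n_b = 30, 30
            a_m, a_b = rng.normal(1.2, 1.0, n_m), rng.normal(0, 1.0, n_b)
            b_m, b_b = rng.normal(1.2, 1.0, n_m), rng.normal(0, 1.0, n_b)
            recs = records_from(np.exp(a_m), np.exp(a_b))
            recs = [replace(r, birads_score=b)
                    for r, b in zip(recs, np.concatenate([b_m, b_b]))]
            out, _, _ = dx.combine_scores(recs)
            aucs = {f: dx.roc_analysis(out, f).auc
                    for f in ("hbt_contrast", "birads_score",
                              "combined_score")}
            if aucs["combined_score"] >= max(aucs["hbt_contrast"],
                                             aucs["birads_score"]):
                wins += 1
        assert wins >= 9


class TestGroupTTest:
    def test_identical_groups(self):
        recs = records_from([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        t, p, _ = dx.group_t_test(recs)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_pooled_t(self):
        # {4,5,6} vs {1,2,3}: pooled variance 1, se = sqrt(2/3),
        # t = 3 / sqrt(2/3)
        recs = records_from([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        t, p, means = dx.group_t_test(recs)
        expected_t = 3.0 / np.sqrt(2.0 / 3.0)
        assert t == pytest.approx(expected_t, rel=1e-12)
        from scipy import stats
        assert p == pytest.approx(2 * stats.t.sf(expected_t, df=4), rel=1e-9)
        assert means == (5.0, 2.0)

    def test_translation_invariance(self):
        recs1 = records_from([4.0, 5.0, 6.5], [1.0, 2.5, 3.0])
        recs2 = records_from([14.0, 15.0, 16.5], [11.0, 12.5, 13.0])
        assert dx.group_t_test(recs1)[0] == pytest.approx(
            dx.group_t_test(recs2)[0], rel=1e-12)

    def test_welch_option_differs_under_unequal_variance(self):
        recs = records_from([4.0, 8.0, 12.0, 2.0], [3.0, 3.1, 2.9])
        t_pooled, _, _ = dx.group_t_test(recs)
        t_welch, _, _ = dx.group_t_test(recs, welch=True)
        assert t_pooled != t_welch


class TestSimulateBirads:
    def test_scores_are_valid_ordinals(self):
        rng = np.random.default_rng(8)
        labels = ["malignant"] * 50 + ["benign"] * 50
        scores = dx.simulate_birads(labels, rng)
        assert scores.min() >= 1 and scores.max() <= 5
        assert scores[:50].mean() > scores[50:].mean()

    def test_end_to_end_monotonic_discrimination(self):
        # raising the malignant contrast law raises the cohort AUC
        rng = np.random.default_rng(9)
        aucs = []
        for shift in (0.2, 1.5):
            recs = records_from(np.exp(rng.normal(shift, 0.4, 60)),
                                np.exp(rng.normal(0.0, 0.4, 30)))
            aucs.append(dx.roc_analysis(recs).auc)
        assert aucs[1] > aucs[0]


def test_subject_record_validation():
    with pytest.raises(InvalidParameterError):
        dx.SubjectRecord("X", -1.0, "malignant")
    with pytest.raises(InvalidParameterError):
        dx.SubjectRecord("X", 1.0, "weird")
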