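"""PU core: scoring, bounded KDE, class-prior estimation, calibration."""

import numpy as np
import pytest
import scipy.stats

from pugene import (
    bounded_kde,
    calibrate_probabilities,
    elkan_noto_alpha,
    estimate_alpha,
    impute_probable_positives,
    oof_scores,
    run_pu_iterations,
)
from pugene.labels import PUDataset
from pugene.pu import kde_grid
import scipy.sparse as sp


def dense_dataset(X, y):
    n = len(y)
    return PUDataset(
        X=sp.csr_matrix(np.asarray(X, dtype=np.float32)),
        y=np.asarray(y),
        row_ids=[f"G{i:04d}" for i in range(n)],
        col_ids=[f"T{j:03d}" for j in range(np.asarray(X).shape[1])],
    )


class TestOofScores:
    def test_separable_limit(self, fast_learner):
        X = np.r_[np.ones((60, 8)), np.zeros((60, 8))]
        ds = dense_dataset(X, np.r_[np.ones(60), np.zeros(60)].astype(int))
        sc = oof_scores(ds, n_folds=3, learner_config=fast_learner, seed=1)
        assert sc.scores_pos.min() > 0.9
        assert sc.scores_unl.max() < 0.1

    def test_no_signal_scores_near_base_rate(self, fast_learner):
        X = np.ones((90, 5))
        ds = dense_dataset(X, np.r_[np.ones(30), np.zeros(60)].astype(int))
        sc = oof_scores(ds, n_folds=3, learner_config=fast_learner, seed=2)
        all_scores = np.r_[sc.scores_pos, sc.scores_unl]
        assert np.allclose(all_scores, 1 / 3, atol=0.05)

    def test_deterministic_rerun(self, small_dataset, fast_learner):
        ds, _ = small_dataset
        a = oof_scores(ds, 5, fast_learner, seed=3)
        b = oof_scores(ds, 5, fast_learner, seed=3)
        np.testing.assert_array_equal(a.scores_pos, b.scores_pos)
        np.testing.assert_array_equal(a.scores_unl, b.scores_unl)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_each_instance_scored_once(self, small_dataset, fast_learner):
        ds, _ = small_dataset
        sc = oof_scores(ds, 5, fast_learner, seed=4)
        assert len(sc.scores_pos) == ds.n_pos
        assert len(sc.scores_unl) == ds.n_unl
        assert set(np.unique(sc.fold_assignment)) == set(range(5))

    def test_rejects_single_class(self, fast_learner):
        ds = dense_dataset(np.ones((20, 3)), np.ones(20, dtype=int))
        with pytest.raises(ValueError, match="both classes"):
            oof_scores(ds, 3, fast_learner, seed=0)

    def test_rejects_bad_fold_count(self, small_dataset, fast_learner):
        ds, _ = small_dataset
        with pytest.raises(ValueError):
            oof_scores(ds, 1, fast_learner, seed=0)


class TestBoundedKde:
    def test_uniform_density_flat(self):
        rng = np.random.default_rng(5)
        d = bounded_kde(rng.uniform(0, 1, 10_000))
        grid = kde_grid()
        inner = (grid >= 0.05) & (grid <= 0.95)
        assert np.abs(d[inner] - 1.0).max() < 0.1

    def test_integrates_to_one(self):
        rng = np.random.default_rng(6)
        for sample in (rng.uniform(0, 1, 500), rng.beta(9, 1, 500),
                       np.full(100, 0.5)):
            d = bounded_kde(sample)
            assert abs(np.trapezoid(d, kde_grid()) - 1.0) < 1e-3
            assert (d >= 0).all()

    def test_point_mass_becomes_spike_at_half(self):
        d = bounded_kde(np.full(200, 0.5))
        grid = kde_grid()
        assert abs(grid[np.argmax(d)] - 0.5) < 0.01

    def test_beta_density_recovered(self):
        """Sup-distance to the closed-form Beta(2,5) pdf.

        The sup statistic is heavy-tailed across draws (scipy's
        gaussian_kde shows the same occasional 0.13-0.17 excursions on
        this target), so the check uses the median over five draws.
        """
        grid = kde_grid()
        inner = (grid >= 0.05) & (grid <= 0.95)
        truth = scipy.stats.beta(2, 5).pdf(grid[inner])
        sups = []
        for s in range(5):
            d = bounded_kde(np.random.default_rng(s).beta(2, 5, 10_000))
            sups.append(np.abs(d[inner] - truth).max())
        assert np.median(sups) <= 0.1

    def test_boundary_mass_not_lost(self):
        # half the sample sits exactly at 0; reflection must keep its mass
        s = np.r_[np.zeros(500), np.full(500, 0.8)]
        d = bounded_kde(s, bandwidth=0.05)
        grid = kde_grid()
        low = np.trapezoid(d[grid <= 0.3], grid[grid <= 0.3])
        assert abs(low - 0.5) < 0.05

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            bounded_kde(np.linspace(0, 1, 9))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bounded_kde(np.r_[np.linspace(0, 1, 20), 1.2])


class TestEstimateAlpha:
    def test_pure_positive_limit(self):
        """Unlabeled drawn from the positive score law -> alpha near 1."""
        vals = []
        for s in range(3):
            rng = np.random.default_rng(800 + s)
            vals.append(estimate_alpha(
                rng.beta(8, 2, 5000), rng.beta(8, 2, 5000), seed=s
            ))
        assert np.mean(vals) >= 0.95

    def test_zero_contamination_limit(self):
        rng = np.random.default_rng(9)
        sp_ = np.clip(rng.normal(0.95, 0.02, 2000), 0, 1)
        su_ = np.clip(rng.normal(0.05, 0.02, 2000), 0, 1)
        assert estimate_alpha(sp_, su_, seed=0) <= 0.02

    def test_beta_mixture_recovery(self):
        """Planted 30% contamination recovered within +-0.05."""
        ests = []
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            sp_ = rng.beta(8, 2, 5000)
            k = rng.binomial(5000, 0.3)
            su_ = np.r_[rng.beta(8, 2, k), rng.beta(2, 8, 5000 - k)]
            ests.append(estimate_alpha(sp_, su_, seed=s))
        assert abs(np.mean(ests) - 0.3) <= 0.05

    def test_agreement_with_elkan_noto_in_separable_limit(self):
        """Disjoint score distributions: both estimators hit the planted
        fraction.  (Elkan-Noto requires negatives to score near zero —
        with overlapping Beta components it is biased up by design.)
        """
        rng = np.random.default_rng(11)
        sp_ = np.clip(rng.normal(0.9, 0.02, 5000), 0, 1)
        k = rng.binomial(5000, 0.3)
        su_ = np.clip(np.r_[rng.normal(0.9, 0.02, k),
                            np.abs(rng.normal(0.004, 0.002, 5000 - k))], 0, 1)
        em = estimate_alpha(sp_, su_, seed=0)
        en = elkan_noto_alpha(sp_, su_)
        planted = k / 5000
        assert abs(em - planted) <= 0.02
        assert abs(en - planted) <= 0.02
        assert abs(em - en) <= 0.02

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        sp_, su_ = rng.beta(5, 2, 1000), rng.beta(2, 5, 1000)
        assert estimate_alpha(sp_, su_, seed=5) == estimate_alpha(sp_, su_, seed=5)

    def test_monotone_in_contamination(self):
        """More planted contamination never lowers the mean estimate."""
        means = []
        for a in (0.1, 0.3, 0.5):
            ests = []
            for s in range(5):
                rng = np.random.default_rng(300 + s)
                sp_ = rng.beta(8, 2, 3000)
                k = rng.binomial(3000, a)
                su_ = np.r_[rng.beta(8, 2, k), rng.beta(2, 8, 3000 - k)]
                ests.append(estimate_alpha(sp_, su_, seed=s))
            means.append(np.mean(ests))
        assert means[0] <= means[1] <= means[2]


class TestElkanNoto:
    def test_arithmetic(self):
        assert elkan_noto_alpha([0.8, 0.8], [0.24, 0.24]) == pytest.approx(0.3)

    def test_clips_to_one(self):
        assert elkan_noto_alpha([0.2, 0.2], [0.5, 0.5]) == 1.0

    def test_zero_positive_mean_rejected(self):
        with pytest.raises(ValueError):
            elkan_noto_alpha([0.0, 0.0], [0.1])


class TestCalibration:
    def test_alpha_zero_and_one(self):
        s = np.array([0.2, 0.5, 0.9])
        assert calibrate_probabilities(s, 0.0).tolist() == [0, 0, 0]
        assert calibrate_probabilities(s, 1.0).tolist() == [1, 1, 1]

    def test_constant_scores_give_constant_alpha(self):
        out = calibrate_probabilities(np.full(50, 0.42), 0.3)
        assert np.allclose(out, 0.3, atol=1e-9)

    @pytest.mark.parametrize("seed,alpha", [(0, 0.05), (1, 0.3), (2, 0.7), (3, 0.97)])
    def test_mean_matches_and_ranking_preserved(self, seed, alpha):
        rng = np.random.default_rng(seed)
        s = rng.beta(2, 3, 400)
        cal = calibrate_probabilities(s, alpha)
        assert abs(cal.mean() - alpha) < 1e-6
        assert ((cal >= 0) & (cal <= 1)).all()
        np.testing.assert_array_equal(np.argsort(s, kind="stable"),
                                      np.argsort(cal, kind="stable"))

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            calibrate_probabilities(np.array([0.5]), 1.5)


class TestImputation:
    def test_ceiling_count(self):
        ids = [f"G{i}" for i in range(10)]
        p = np.linspace(0.05, 0.95, 10)
        top = impute_probable_positives(ids, p, 0.3)
        assert top == ["G9", "G8", "G7"]

    def test_tie_breaks_lexicographic(self):
        out = impute_probable_positives(["Gb", "Ga"], [0.5, 0.5], 0.5)
        assert out == ["Ga"]

    def test_zero_count_empty(self):
        assert impute_probable_positives(["Ga"], [0.9], 0.0) == []

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_full_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"G{i:03d}" for i in range(57)]
        p = rng.random(57).round(2)   # rounding forces some ties
        alpha = 0.37
        got = impute_probable_positives(ids, p, alpha)
        order = sorted(zip(-p, ids))
        k = int(np.ceil(alpha * 57))
        assert got == [g for _, g in order[:k]]


class TestRunPuIterations:
    def test_single_iteration_ci_collapses(self, small_dataset, fast_learner):
        ds, _ = small_dataset
        est, _ = run_pu_iterations(ds, n_iterations=1, base_seed=5,
                                   learner_config=fast_learner)
        assert est.ci95 == (est.alpha, est.alpha)

    def test_deterministic_rerun(self, small_dataset, fast_learner):
        ds, _ = small_dataset
        a = run_pu_iterations(ds, n_iterations=2, base_seed=7,
                              learner_config=fast_learner)
        b = run_pu_iterations(ds, n_iterations=2, base_seed=7,
                              learner_config=fast_learner)
        np.testing.assert_array_equal(a[0].per_iteration_alphas,
                                      b[0].per_iteration_alphas)
        np.testing.assert_array_equal(a[1].calibrated, b[1].calibrated)
        assert a[1].imputed_positives == b[1].imputed_positives

    def test_calibration_conserves_alpha_each_iteration(
        self, small_dataset, fast_learner
    ):
        ds, _ = small_dataset
        est, cal = run_pu_iterations(ds, n_iterations=3, base_seed=9,
                                     learner_config=fast_learner)
        for a, row in zip(est.per_iteration_alphas, cal.calibrated):
            assert abs(row.mean() - a) < 1e-6

    def test_imputed_count_is_ceiling_of_alpha(self, small_dataset, fast_learner):
        ds, _ = small_dataset
        est, cal = run_pu_iterations(ds, n_iterations=2, base_seed=11,
                                     learner_config=fast_learner)
        assert len(cal.imputed_positives) == int(np.ceil(est.alpha * ds.n_unl))
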