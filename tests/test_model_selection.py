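"""Cross-validated penalty tuning and bootstrap stability selection."""

import numpy as np
import pytest

from neuroscca import (
    ConfigError,
    DataError,
    PenaltyPair,
    bootstrap_stability,
    fit_full,
    generate_coupled_dataset,
    make_penalty_grid,
    tune_penalties,
)


class TestPenaltyGrid:
    def test_grid_spans_budget_range_sorted_by_sparsity(self):
        grid = make_penalty_grid(246, 51, 8, 8)
        assert len(grid) == 64
        c1s = {g.c1 for g in grid}
        assert min(c1s) == pytest.approx(1.0)
        assert max(c1s) == pytest.approx(np.sqrt(246))
        totals = [g.c1 + g.c2 for g in grid]
        assert totals == sorted(totals)


class TestTunePenalties:
    def test_single_point_grid_is_returned_verbatim(self, planted_small):
        X, Y, _ = planted_small
        grid = [PenaltyPair(2.0, 1.5)]
        report = tune_penalties(X, Y, grid=grid, k_folds=3, seed=0)
        assert report.final_penalties == PenaltyPair(2.0, 1.5)
        assert all(b == PenaltyPair(2.0, 1.5) for b in report.per_fold_best)

    def test_same_seed_reproduces_report(self, planted_small):
        X, Y, _ = planted_small
        grid = make_penalty_grid(X.shape[1], Y.shape[1], 3, 3)
        a = tune_penalties(X, Y, grid=grid, k_folds=4, seed=5)
        b = tune_penalties(X, Y, grid=grid, k_folds=4, seed=5)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_array_equal(a.per_fold_heldout_rho, b.per_fold_heldout_rho)
        assert a.final_penalties == b.final_penalties

    def test_fold_assignment_is_a_partition(self, planted_small):
        X, Y, _ = planted_small
        report = tune_penalties(
            X, Y, grid=[PenaltyPair(2.0, 1.5)], k_folds=5, seed=2
        )
        counts = np.bincount(report.fold_assignment, minlength=5)
        assert counts.sum() == len(X)
        assert counts.min() >= len(X) // 5

    def test_final_penalties_average_fold_bests(self, planted_small):
        X, Y, _ = planted_small
        grid = make_penalty_grid(X.shape[1], Y.shape[1], 3, 3)
        report = tune_penalties(X, Y, grid=grid, k_folds=3, seed=7)
        assert report.final_penalties.c1 == pytest.approx(
            np.mean([g.c1 for g in report.per_fold_best])
        )
        assert report.final_penalties.c2 == pytest.approx(
            np.mean([g.c2 for g in report.per_fold_best])
        )

    def test_heldout_rho_bounded_and_near_zero_on_null_data(self):
        """Leakage check: with no planted effect, training-only
        standardization must keep held-out correlations centered near 0."""
        rhos = []
        for seed in range(3):
            X, Y, _ = generate_coupled_dataset(
                150, 30, 12, 5, 4, latent_strength=0.0, noise_sd=1.0, seed=seed
            )
            report = tune_penalties(
                X, Y, grid=make_penalty_grid(30, 12, 3, 3), k_folds=5, seed=seed
            )
            vals = report.per_fold_heldout_rho
            assert np.all(vals[np.isfinite(vals)] <= 1.0)
            assert np.all(vals[np.isfinite(vals)] >= -1.0)
            rhos.extend(vals[np.isfinite(vals)].ravel())
        assert abs(np.mean(rhos)) < 0.15

    def test_cv_tuned_fit_recovers_planted_support(self):
        """Planted data at moderate signal: the CV-tuned full fit should
        select most of the true support in most seeds."""
        hits = 0
        for seed in range(5):
            X, Y, truth = generate_coupled_dataset(
                300, 40, 20, 6, 5, latent_strength=3.0, noise_sd=1.0, seed=seed
            )
            report = tune_penalties(
                X, Y, grid=make_penalty_grid(40, 20, 5, 5), k_folds=5, seed=seed
            )
            sol = fit_full(X, Y, report.final_penalties)
            recovered = np.intersect1d(sol.selected_regions, truth.region_support).size
            hits += recovered >= 0.8 * truth.region_support.size
        assert hits >= 4

    def test_too_few_subjects_rejected(self, planted_small):
        X, Y, _ = planted_small
        with pytest.raises(DataError):
            tune_penalties(X.iloc[:6], Y.iloc[:6], grid=[PenaltyPair(2, 2)], k_folds=5)
        with pytest.raises(ConfigError):
            tune_penalties(X, Y, grid=[PenaltyPair(2, 2)], k_folds=1)


class TestBootstrapStability:
    def test_single_replicate_gives_indicator_frequencies(self, planted_small):
        X, Y, _ = planted_small
        report = bootstrap_stability(X, Y, PenaltyPair(2.0, 1.5), n_boot=1, frac=0.8, seed=1)
        assert set(np.unique(report.region_freq)) <= {0.0, 1.0}
        assert set(np.unique(report.question_freq)) <= {0.0, 1.0}

    def test_subsample_size_is_floor_of_fraction(self):
        X, Y, _ = generate_coupled_dataset(284, 10, 6, 3, 2, 2.0, 1.0, seed=0)
        report = bootstrap_stability(X, Y, PenaltyPair(1.5, 1.3), n_boot=2, frac=0.8, seed=0)
        assert report.n_subsample == 227

    def test_frequencies_in_unit_interval_and_deterministic(self, planted_small):
        X, Y, _ = planted_small
        a = bootstrap_stability(X, Y, PenaltyPair(2.0, 1.5), n_boot=25, seed=9)
        b = bootstrap_stability(X, Y, PenaltyPair(2.0, 1.5), n_boot=25, seed=9)
        assert np.all((a.region_freq >= 0) & (a.region_freq <= 1))
        np.testing.assert_array_equal(a.region_freq, b.region_freq)
        np.testing.assert_array_equal(a.question_freq, b.question_freq)

    def test_true_support_selected_more_often_than_null(self):
        for seed in range(3):
            X, Y, truth = generate_coupled_dataset(
                200, 30, 12, 5, 4, latent_strength=3.0, noise_sd=1.0, seed=seed
            )
            report = bootstrap_stability(
                X, Y, PenaltyPair(2.2, 1.8), n_boot=60, frac=0.8, seed=seed
            )
            on = report.region_freq[truth.region_support].mean()
            off_mask = np.ones(30, bool)
            off_mask[truth.region_support] = False
            assert on > report.region_freq[off_mask].mean()

    def test_overlap_compares_full_fit_with_top_frequent(self, planted_small):
        X, Y, _ = planted_small
        pen = PenaltyPair(2.0, 1.5)
        full = fit_full(X, Y, pen)
        report = bootstrap_stability(X, Y, pen, n_boot=40, seed=3, full_fit=full)
        k = full.selected_regions.size
        assert report.overlap_regions["k"] == k
        assert 0 <= report.overlap_regions["count"] <= k
        assert report.overlap_regions["percentage"] == pytest.approx(
            100.0 * report.overlap_regions["count"] / k
        )

    def test_frequency_stability_under_more_replicates(self, planted_small):
        """Doubling the replicate count moves no frequency by more than
        3/sqrt(n_boot) (Monte-Carlo convergence)."""
        X, Y, _ = planted_small
        pen = PenaltyPair(2.2, 1.8)
        a = bootstrap_stability(X, Y, pen, n_boot=100, seed=21)
        b = bootstrap_stability(X, Y, pen, n_boot=200, seed=21)
        tol = 3 / np.sqrt(100)
        assert np.max(np.abs(a.region_freq - b.region_freq)) <= tol
        assert np.max(np.abs(a.question_freq - b.question_freq)) <= tol

    def test_tiny_subsample_rejected(self, planted_small):
        X, Y, _ = planted_small
        with pytest.raises(ConfigError):
            bootstrap_stability(X, Y, PenaltyPair(2, 2), n_boot=5, frac=1.2)
        with pytest.raises(DataError):
            bootstrap_stability(X.iloc[:4], Y.iloc[:4], PenaltyPair(2, 2), n_boot=5, frac=0.8)
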