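"""CV tuning, nested CV bookkeeping, metrics, PIT, loess."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

import panssboost as pb
from panssboost import family
from panssboost.boosting import BetaBoostLSS
from panssboost.scale import discrete_cdf_interval
from panssboost.validation import (
    loess_smooth,
    make_folds,
    nested_cv,
    pit_histogram_from_intervals,
    pseudo_r2,
    rmse_logit,
    select_mstop,
)


class TestFolds:
    @pytest.mark.parametrize("n,k", [(20, 2), (23, 5), (100, 10)])
    def test_partition_balanced(self, n, k):
        rng = np.random.default_rng(0)
        folds = make_folds(n, k, rng)
        assert folds.size == n
        sizes = np.bincount(folds, minlength=k)
        assert sizes.max() - sizes.min() <= 1

    def test_seeded_reproducibility(self):
        a = make_folds(50, 5, np.random.default_rng(7))
        b = make_folds(50, 5, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestMetrics:
    def test_perfect_and_affine_predictions(self):
        y = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        assert pseudo_r2(y, logit(y)) == pytest.approx(1.0)
        assert pseudo_r2(y, 2.0 + 0.5 * logit(y)) == pytest.approx(1.0)
        assert rmse_logit(y, logit(y)) == 0.0

    def test_three_point_example(self):
        # frozen from an independent hand computation of the correlation of
        # logit(0.2, 0.4, 0.6) with (-1, -0.5, 0.5) and its RMSE
        y = np.array([0.2, 0.4, 0.6])
        eta = np.array([-1.0, -0.5, 0.5])
        assert pseudo_r2(y, eta) == pytest.approx(0.941253, abs=1e-5)
        assert rmse_logit(y, eta) == pytest.approx(0.236006, abs=1e-5)

    def test_constant_vector_returns_zero(self):
        y = np.array([0.2, 0.4, 0.6])
        assert pseudo_r2(y, np.zeros(3)) == 0.0

    def test_constant_offset_rmse(self):
        y = np.array([0.2, 0.4, 0.6, 0.8])
        assert rmse_logit(y, logit(y) + 0.7) == pytest.approx(0.7)


class TestSelectMstop:
    def test_single_grid_value_returned(self, small_cohort):
        assert select_mstop(small_cohort, "negative", grid=[7], k=3, seed=1) == 7

    def test_path_equals_refit_from_scratch(self, small_cohort):
        """Risk recorded along one path matches separate refits per grid point."""
        df = small_cohort.iloc[:40]
        grid = [3, 7, 12]
        k, seed = 3, 5
        best, path = select_mstop(
            df, "negative", grid=grid, k=k, seed=seed, return_path=True
        )
        rng = np.random.default_rng(seed)
        folds = make_folds(len(df), k, rng)
        for gi, g in enumerate(grid):
            risks = []
            for fold in range(k):
                train = df.iloc[folds != fold]
                test = df.iloc[folds == fold]
                res = BetaBoostLSS.from_cohort(train, "negative").fit(g)
                eta = res.eta(test)
                y_test = pb.rescale(test["negative_dis"].to_numpy(), "negative")
                risks.append(
                    family.mean_nll(
                        y_test, eta["eta_mu"].to_numpy(), eta["eta_sigma"].to_numpy()
                    )
                )
            assert path["cv_risk"].iloc[gi] == pytest.approx(np.mean(risks), abs=1e-10)

    def test_signal_selects_deeper_stopping_than_noise(self):
        df = pb.generate_cohort(n=300, seed=8)
        cohort, _ = pb.split_truth(df)
        m_signal = select_mstop(cohort, "negative", k=4, seed=2, mstop_max=120)
        # same covariates, outcome shuffled: no structure to learn
        noise = cohort.copy()
        noise["negative_dis"] = (
            noise["negative_dis"].sample(frac=1, random_state=0).to_numpy()
        )
        m_noise = select_mstop(noise, "negative", k=4, seed=2, mstop_max=120)
        assert m_signal > 1
        assert m_noise < m_signal

    def test_invalid_grid_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            select_mstop(small_cohort, "negative", grid=[0, 5], k=3)
        with pytest.raises(ValueError):
            select_mstop(small_cohort, "negative", grid=[1500], k=3)


class TestNestedCV:
    def test_bookkeeping_single_repeat_two_folds(self):
        df = pb.generate_cohort(n=20, seed=9)
        cohort, _ = pb.split_truth(df)
        cv = nested_cv(cohort, "depressed", repeats=1, k=2, inner_k=2,
                       grid=[3, 6], seed=4)
        assert len(cv.records) == 2
        assert cv.records["n_test"].tolist() == [10, 10]
        assert cv.records["n_train"].tolist() == [10, 10]
        # every row tested exactly `repeats` times
        assert cv.pit_lo.size == 20

    def test_every_row_tested_once_per_repeat(self):
        df = pb.generate_cohort(n=30, seed=10)
        cohort, _ = pb.split_truth(df)
        cv = nested_cv(cohort, "excited", repeats=3, k=3, inner_k=2,
                       grid=[4], seed=5)
        assert len(cv.records) == 9
        assert cv.pit_lo.size == 3 * 30

    def test_optimism_direction_on_synthetic_truth(self, cohort):
        cv = nested_cv(cohort.iloc[:150], "negative", repeats=2, k=3, inner_k=3,
                       mstop_max=80, seed=6)
        opt = cv.optimism()
        assert opt["optimism_pseudo_r2"] >= 0.0
        assert opt["optimism_rmse"] >= 0.0

    def test_determinism_end_to_end(self):
        df = pb.generate_cohort(n=40, seed=12)
        cohort, _ = pb.split_truth(df)
        a = nested_cv(cohort, "positive", repeats=1, k=2, inner_k=2, grid=[5], seed=3)
        b = nested_cv(cohort, "positive", repeats=1, k=2, inner_k=2, grid=[5], seed=3)
        assert a.records.equals(b.records)
        assert np.array_equal(a.pit_lo, b.pit_lo)


class TestPIT:
    def test_single_observation_spread(self):
        h = pit_histogram_from_intervals([0.2], [0.4], bins=10)
        expected = np.zeros(10)
        expected[2] = expected[3] = 0.5
        assert h.masses == pytest.approx(expected, abs=1e-12)

    def test_masses_sum_to_one(self):
        rng = np.random.default_rng(14)
        lo = rng.uniform(0, 0.9, 500)
        hi = lo + rng.uniform(0, 0.1, 500)
        h = pit_histogram_from_intervals(lo, np.clip(hi, 0, 1), bins=10)
        assert h.masses.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(h.masses >= 0)

    @staticmethod
    def _pit_under_truth(n, seed):
        rng = np.random.default_rng(seed)
        mu = np.clip(rng.beta(4, 6, n), 0.05, 0.95)
        sigma = np.full(n, 0.3)
        cont = np.clip(family.rvs(mu, sigma, rng), 1e-9, (36.5 / 37.0) - 1e-9)
        y = pb.unrescale(cont, "negative")
        lo, hi = discrete_cdf_interval(y, mu, sigma, "negative")
        return pit_histogram_from_intervals(lo, hi, bins=10)

    def test_uniform_under_true_model(self):
        h = self._pit_under_truth(2000, 15)
        n = 2000
        p = stats.chisquare(h.masses * n).pvalue
        assert p > 0.01

    def test_deviation_shrinks_with_sample_size(self):
        dev = [
            np.max(np.abs(self._pit_under_truth(n, 16).masses - 0.1))
            for n in (200, 2000)
        ]
        assert dev[1] < dev[0]

    def test_inflated_mu_depletes_top_bins(self):
        rng = np.random.default_rng(17)
        n = 2000
        mu = np.clip(rng.beta(4, 6, n), 0.05, 0.7)
        sigma = np.full(n, 0.3)
        cont = np.clip(family.rvs(mu, sigma, rng), 1e-9, (36.5 / 37.0) - 1e-9)
        y = pb.unrescale(cont, "negative")
        lo, hi = discrete_cdf_interval(y, np.clip(mu * 1.3, 0.05, 0.97), sigma, "negative")
        h = pit_histogram_from_intervals(lo, hi, bins=10)
        assert h.masses[-1] < 0.1  # over-forecasting signature


class TestLoess:
    def test_constant_reproduced(self):
        x = np.linspace(0, 1, 30)
        grid, fitted = loess_smooth(x, np.full(30, 3.3))
        assert np.allclose(fitted, 3.3, atol=1e-10)

    def test_linear_reproduced_exactly(self):
        rng = np.random.default_rng(18)
        x = rng.uniform(-2, 2, 60)
        y = 1.5 - 0.7 * x
        grid, fitted = loess_smooth(x, y)
        assert np.max(np.abs(fitted - (1.5 - 0.7 * grid))) < 1e-8

    def test_matches_direct_wls_at_grid_point(self):
        rng = np.random.default_rng(19)
        x = rng.uniform(0, 10, 80)
        y = np.sin(x) + rng.normal(0, 0.2, 80)
        span = 0.6
        grid, fitted = loess_smooth(x, y, span=span, n_grid=100)
        i = 37
        x0 = grid[i]
        d = np.abs(x - x0)
        q = int(np.ceil(span * x.size))
        dq = np.sort(d)[q - 1]
        w = np.clip(1 - (d / dq) ** 3, 0, None) ** 3
        B = np.column_stack([np.ones_like(x), x - x0, (x - x0) ** 2])
        W = np.diag(w)
        beta = np.linalg.solve(B.T @ W @ B, B.T @ W @ y)
        assert fitted[i] == pytest.approx(beta[0], abs=1e-8)

    def test_too_small_span_rejected(self):
        x = np.linspace(0, 1, 12)
        with pytest.raises(ValueError):
            loess_smooth(x, x, span=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth(np.arange(5.0), np.arange(5.0))
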