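"""Conjugate updates, tail probabilities and superiority probabilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from adaptrial.posteriors import (
    BetaPosterior,
    NormalPosterior,
    VAGUE_LOG_HR_PRIOR,
    prob_hr_below_one,
    prob_superiority,
    sample_predictive_events,
    sample_predictive_events_batch,
    update_beta,
    update_normal,
)


def quad_superiority(control: BetaPosterior, intervention: BetaPosterior) -> float:
    """Brute-force integral oracle: int f_ctrl(x) F_int(x) dx."""
    value, _ = integrate.quad(
        lambda x: stats.beta.pdf(x, control.alpha, control.beta)
        * stats.beta.cdf(x, intervention.alpha, intervention.beta),
        0.0,
        1.0,
        limit=200,
    )
    return value


class TestNormalModel:
    def test_symmetric_zero_update(self):
        post = update_normal(VAGUE_LOG_HR_PRIOR, 0.0, 0.04)
        assert post.mean == 0.0
        # harmonic combination of the prior and data variances
        assert post.variance == pytest.approx(0.04 * 10_000 / 10_000.04, rel=1e-12)

    def test_precision_weighting_matches_grid_bayes(self):
        """Posterior mean/variance agree with numerical Bayes on a grid."""
        est, v = math.log(0.7), 0.02
        post = update_normal(VAGUE_LOG_HR_PRIOR, est, v)
        expected_mean = est * (1 / v) / (1 / v + 1 / 10_000)
        assert post.mean == pytest.approx(expected_mean, rel=1e-12)
        # independent oracle: discretised Bayes rule
        grid = np.linspace(-2, 2, 400_001)
        like = stats.norm.pdf(est, grid, math.sqrt(v))
        prior = stats.norm.pdf(grid, 0.0, 100.0)
        w = like * prior
        w /= w.sum()
        assert float(np.sum(w * grid)) == pytest.approx(post.mean, abs=1e-8)
        var = float(np.sum(w * (grid - post.mean) ** 2))
        assert var == pytest.approx(post.variance, rel=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            update_normal(VAGUE_LOG_HR_PRIOR, 0.1, 0.0)
        with pytest.raises(ValueError):
            NormalPosterior(0.0, -1.0)

    def test_prior_and_data_dominance_limits(self):
        flat = NormalPosterior(0.0, 1e12)
        post = update_normal(flat, 0.3, 0.02)
        assert post.mean == pytest.approx(0.3, rel=1e-6)
        assert post.variance == pytest.approx(0.02, rel=1e-6)
        vague_data = update_normal(NormalPosterior(0.1, 0.5), 5.0, 1e12)
        assert vague_data.mean == pytest.approx(0.1, rel=1e-6)
        assert vague_data.variance == pytest.approx(0.5, rel=1e-6)

    @pytest.mark.parametrize(
        "mean,variance,expected",
        [
            (0.0, 0.7, 0.5),
            (math.log(0.7), 0.02, stats.norm.cdf(-math.log(0.7) / math.sqrt(0.02))),
            (-10.0, 0.01, 1.0),
        ],
    )
    def test_prob_hr_below_one(self, mean, variance, expected):
        assert prob_hr_below_one(NormalPosterior(mean, variance)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_prob_hr_below_one_matches_quadrature(self):
        post = NormalPosterior(-0.21, 0.035)
        oracle, _ = integrate.quad(
            lambda x: stats.norm.pdf(x, post.mean, post.sd), -np.inf, 0.0
        )
        assert prob_hr_below_one(post) == pytest.approx(oracle, abs=1e-10)


class TestBetaModel:
    @pytest.mark.parametrize(
        "events,patients,expected",
        [(10, 20, (11, 11)), (0, 0, (1, 1)), (3, 3, (4, 1))],
    )
    def test_update_counts(self, events, patients, expected):
        post = update_beta(BetaPosterior(1, 1), events, patients)
        assert (post.alpha, post.beta) == expected

    def test_update_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            update_beta(BetaPosterior(1, 1), 5, 3)
        with pytest.raises(ValueError):
            update_beta(BetaPosterior(1, 1), -1, 3)

    def test_superiority_exchangeable_arms(self):
        assert prob_superiority(BetaPosterior(1, 1), BetaPosterior(1, 1)) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_superiority_closed_form(self):
        """control Beta(2,1) vs intervention Beta(1,2): int 2x(1-(1-x)^2) dx = 5/6."""
        assert prob_superiority(BetaPosterior(2, 1), BetaPosterior(1, 2)) == pytest.approx(
            5 / 6, abs=1e-10
        )

    def test_superiority_matches_integral_oracle_on_random_shapes(self):
        """Implementation agrees with the brute-force integral on 100 pairs."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            if rng.random() < 0.5:  # integer shapes exercise the exact sum
                a = BetaPosterior(*(int(x) for x in rng.integers(1, 400, size=2)))
                b = BetaPosterior(*(int(x) for x in rng.integers(1, 400, size=2)))
            else:
                a = BetaPosterior(*np.exp(rng.uniform(-1, 4, size=2)))
                b = BetaPosterior(*np.exp(rng.uniform(-1, 4, size=2)))
            assert prob_superiority(a, b) == pytest.approx(
                quad_superiority(a, b), abs=1e-6
            )

    @given(
        shapes=st.tuples(
            *(st.floats(min_value=0.2, max_value=150.0, allow_nan=False) for _ in range(4))
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_superiority_complement_symmetry(self, shapes):
        a = BetaPosterior(shapes[0], shapes[1])
        b = BetaPosterior(shapes[2], shapes[3])
        assert prob_superiority(a, b) + prob_superiority(b, a) == pytest.approx(
            1.0, abs=1e-8
        )

    def test_superiority_monotone_in_intervention_events(self):
        control = BetaPosterior(45, 60)
        values = [
            prob_superiority(control, BetaPosterior(1 + s, 1 + 100 - s)) for s in range(0, 101, 5)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))


class TestPredictiveSampling:
    def test_zero_future_patients(self, rng):
        assert sample_predictive_events(BetaPosterior(3, 7), 0, rng) == 0

    def test_degenerate_posterior(self, rng):
        assert sample_predictive_events(BetaPosterior(1, 10**9), 100, rng) == 0

    def test_negative_future_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_predictive_events(BetaPosterior(1, 1), -1, rng)

    @pytest.mark.parametrize("alpha,beta,n", [(1, 1, 1), (3, 9, 40)])
    def test_empirical_mean_matches_beta_binomial(self, alpha, beta, n, rng):
        """Mean over 1e5 draws within 3 SE of n * alpha / (alpha + beta)."""
        draws = sample_predictive_events_batch(BetaPosterior(alpha, beta), n, 100_000, rng)
        mean = stats.betabinom.mean(n, alpha, beta)
        se = stats.betabinom.std(n, alpha, beta) / math.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se
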