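"""Closed-form conjugate posterior updates and superiority probabilities.

Two conjugate families cover both monitored endpoints:

* a normal-normal model for the log hazard ratio of a two-arm
  time-to-event comparison, monitored through ``Pr(HR < 1 | data)``;
* independent beta-binomial models for the per-arm event rate of a binary
  outcome, monitored through ``Pr(theta_intervention < theta_control | data)``.

Everything here is deterministic apart from :func:`sample_predictive_events`,
which draws from the beta-binomial posterior predictive distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "NormalPosterior",
    "BetaPosterior",
    "VAGUE_LOG_HR_PRIOR",
    "UNIFORM_RATE_PRIOR",
    "update_normal",
    "prob_hr_below_one",
    "update_beta",
    "prob_superiority",
    "sample_predictive_events",
    "sample_predictive_events_batch",
]


@dataclass(frozen=True)
class NormalPosterior:
    """Normal prior/posterior for the log hazard ratio.

    ``mean`` is on the log-HR scale (negative favours the intervention);
    ``variance`` must be strictly positive.
    """

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be > 0, got {self.variance}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class BetaPosterior:
    """Beta prior/posterior for one arm's event probability.

    ``alpha`` counts events plus the prior's pseudo-events, ``beta`` counts
    non-events plus the prior's pseudo-non-events; both strictly positive.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"beta shapes must be > 0, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


#: Near-flat prior on the log hazard ratio: N(0, 10 000).
VAGUE_LOG_HR_PRIOR = NormalPosterior(0.0, 10_000.0)

#: Uniform prior on an event rate: Beta(1, 1).
UNIFORM_RATE_PRIOR = BetaPosterior(1.0, 1.0)


def update_normal(
    prior: NormalPosterior, estimate: float, estimate_variance: float
) -> NormalPosterior:
    """Precision-weighted normal-normal conjugate update.

    The posterior precision is the sum of prior and data precisions; the
    posterior mean is the precision-weighted average of the prior mean and
    the data estimate.

    Parameters
    ----------
    prior
        Current normal prior/posterior for the log HR.
    estimate, estimate_variance
        Estimated log HR and its (strictly positive) sampling variance.
    """
    if not estimate_variance > 0:
        raise ValueError(f"estimate_variance must be > 0, got {estimate_variance}")
    w0 = 1.0 / prior.variance
    w1 = 1.0 / estimate_variance
    variance = 1.0 / (w0 + w1)
    mean = (w0 * prior.mean + w1 * estimate) * variance
    return NormalPosterior(mean, variance)


def prob_hr_below_one(posterior: NormalPosterior) -> float:
    """``Pr(HR < 1 | data)`` — the lower tail of the log-HR posterior at 0."""
    return float(special.ndtr(-posterior.mean / posterior.sd))


def update_beta(prior: BetaPosterior, events: int, patients: int) -> BetaPosterior:
    """Beta-binomial conjugate update with ``events`` among ``patients``."""
    events = int(events)
    patients = int(patients)
    if events < 0 or patients < 0:
        raise ValueError("counts must be non-negative")
    if events > patients:
        raise ValueError(f"events ({events}) exceed patients ({patients})")
    return BetaPosterior(prior.alpha + events, prior.beta + (patients - events))


# Exact finite sums are used up to this control-arm alpha; beyond it the
# adaptive quadrature branch takes over (never reached with trial-sized counts).
_MAX_EXACT_TERMS = 20_000


def _is_integral(x: float) -> bool:
    return abs(x - round(x)) < 1e-9


def prob_superiority(control: BetaPosterior, intervention: BetaPosterior) -> float:
    """``Pr(theta_intervention < theta_control)`` for independent beta laws.

    When the control shape ``alpha`` is a (modest) integer the probability is
    the exact finite sum

    ``sum_{i=0}^{a_c-1} B(a_i + i, b_c + b_i) / [(b_c + i) B(1 + i, b_c) B(a_i, b_i)]``

    evaluated through log-gamma for stability; otherwise the integral
    ``int f_ctrl(x) F_int(x) dx`` is computed by adaptive quadrature with
    breakpoints at both posterior means, to absolute accuracy <= 1e-8.
    Both arms are continuous, so ties have probability zero.
    """
    a1, b1 = control.alpha, control.beta
    a2, b2 = intervention.alpha, intervention.beta
    if _is_integral(a1) and round(a1) <= _MAX_EXACT_TERMS:
        return _clip01(_exact_sum(a1, b1, a2, b2))
    if _is_integral(a2) and round(a2) <= _MAX_EXACT_TERMS:
        # complement identity: Pr(int < ctrl) = 1 - Pr(ctrl < int)
        return _clip01(1.0 - _exact_sum(a2, b2, a1, b1))
    # canonical orientation keeps p(A,B) + p(B,A) = 1 exact for the
    # numerical branch as well
    if (a1, b1) <= (a2, b2):
        return _clip01(_quad_prob_greater(a1, b1, a2, b2))
    return _clip01(1.0 - _quad_prob_greater(a2, b2, a1, b1))


def _clip01(x: float) -> float:
    return min(max(float(x), 0.0), 1.0)


def _exact_sum(a1: float, b1: float, a2: float, b2: float) -> float:
    """P(X1 > X2) for X1 ~ Beta(a1, b1) with integral a1, X2 ~ Beta(a2, b2)."""
    i = np.arange(int(round(a1)))
    log_terms = (
        special.betaln(a2 + i, b1 + b2)
        - np.log(b1 + i)
        - special.betaln(1 + i, b1)
        - special.betaln(a2, b2)
    )
    return float(np.exp(special.logsumexp(log_terms)))


def _quad_prob_greater(a1: float, b1: float, a2: float, b2: float) -> float:
    """P(X1 > X2) by quadrature.

    Substituting u = F_1(x) turns the integral into
    int_0^1 F_2(F_1^-1(u)) du with a bounded monotone integrand, immune to
    the endpoint singularities of small beta shapes.
    """
    value, _ = integrate.quad(
        lambda u: stats.beta.cdf(stats.beta.ppf(u, a1, b1), a2, b2),
        0.0,
        1.0,
        limit=200,
        epsabs=1e-10,
        epsrel=1e-10,
    )
    return value


def sample_predictive_events(
    posterior: BetaPosterior, n_future: int, rng: np.random.Generator
) -> int:
    """One beta-binomial posterior-predictive draw of events among ``n_future``."""
    n_future = int(n_future)
    if n_future < 0:
        raise ValueError(f"n_future must be >= 0, got {n_future}")
    if n_future == 0:
        return 0
    theta = rng.beta(posterior.alpha, posterior.beta)
    return int(rng.binomial(n_future, theta))


def sample_predictive_events_batch(
    posterior: BetaPosterior, n_future: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Vector of ``size`` independent beta-binomial predictive draws."""
    n_future = int(n_future)
    if n_future < 0:
        raise ValueError(f"n_future must be >= 0, got {n_future}")
    if n_future == 0:
        return np.zeros(size, dtype=np.int64)
    theta = rng.beta(posterior.alpha, posterior.beta, size=size)
    return rng.binomial(n_future, theta).astype(np.int64)
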