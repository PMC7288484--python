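"""Patient-level simulator for a two-arm binary-outcome adaptive trial.

Models a BALTI-2-style superiority trial: 1:1 allocation in permuted blocks
of two, a 28-day outcome observed with a follow-up lag under deterministic
accrual, interim analyses at pre-specified recruitment counts, and
posterior-predictive stopping rules:

* efficacy stop when ``P_curr`` — the predictive probability that the trial
  would already meet its final success criterion at the *current* sample
  size once every enrolled patient completes follow-up — exceeds its bar;
* futility stop when ``P_max`` — the predictive probability of success at
  the *maximum* sample size, imputing both incomplete and not-yet-enrolled
  patients — falls below its bar.

The final analysis declares success when
``Pr(theta_intervention < theta_control | data)`` exceeds the final bar.
All inequalities are strict.

Predictive probabilities are Monte-Carlo estimates over beta-binomial
imputations.  Each imputation's success indicator is resolved through a
cached critical boundary: for given per-arm totals and a control event
count, the largest intervention event count that still clears the
superiority bar is found once by bisection over the exact
:func:`~adaptrial.posteriors.prob_superiority` and reused, which keeps
many-thousand-trial runs cheap without any approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import substream
from .posteriors import (
    BetaPosterior,
    prob_superiority,
    sample_predictive_events_batch,
)
from .results import EFFICACY, FINAL, FUTILITY, TrialResult

__all__ = [
    "BinaryDesign",
    "Scenario",
    "TrialState",
    "NULL_BALTI",
    "TARGET_BALTI",
    "build_even_schedule",
    "predictive_prob_success_current",
    "predictive_prob_success_max",
    "simulate_binary_trial",
    "final_superiority_probability",
]

CONTROL, INTERVENTION = 0, 1


@dataclass(frozen=True)
class Scenario:
    """True 28-day event (mortality) probabilities per arm."""

    control_rate: float
    intervention_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        for r in (self.control_rate, self.intervention_rate):
            if not 0.0 < r < 1.0:
                raise ValueError("rates must lie in (0, 1)")


#: Null scenario of the BALTI-2 redesign: 44% mortality in both arms.
NULL_BALTI = Scenario(0.44, 0.44, "null")
#: Target-effect scenario: 9-point absolute reduction (44% vs 35%).
TARGET_BALTI = Scenario(0.44, 0.35, "target")


def build_even_schedule(n_max: int, n_interims: int) -> list[int]:
    """Interim recruitment counts evenly spaced over ``n_max`` patients.

    The k-th of ``n_interims`` looks happens after ``round(k*n_max/(K+1))``
    patients (round half up); the final analysis is always at ``n_max`` and
    is not part of the returned list.
    """
    if n_interims < 0:
        raise ValueError("n_interims must be >= 0")
    schedule = [
        int(math.floor(k * n_max / (n_interims + 1) + 0.5)) for k in range(1, n_interims + 1)
    ]
    if any(b <= a for a, b in zip(schedule, schedule[1:])) or (
        schedule and (schedule[0] < 1 or schedule[-1] >= n_max)
    ):
        raise ValueError(
            f"{n_interims} interims cannot be evenly spaced over {n_max} patients "
            "without two looks colliding"
        )
    return schedule


@dataclass(frozen=True)
class BinaryDesign:
    """Design of the binary-outcome adaptive trial.

    Defaults are the BALTI-2 redesign: 1334 patients at most, uniform
    Beta(1, 1) priors per arm, efficacy stop at ``P_curr > 0.99``, futility
    stop at ``P_max < 0.10`` (either rule may be disabled with ``None``),
    final success bar 0.98, 28-day follow-up under deterministic accrual of
    2 patients/day.  ``schedule`` lists the recruitment counts of the
    interim looks; build it with :func:`build_even_schedule` or give any
    strictly increasing counts below ``n_max``.
    """

    n_max: int = 1334
    schedule: tuple[int, ...] = ()
    efficacy_threshold: float | None = 0.99
    futility_threshold: float | None = 0.10
    final_success_threshold: float = 0.98
    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    followup_days: float = 28.0
    accrual_rate: float = 2.0
    n_imputations: int = 500
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", tuple(int(n) for n in self.schedule))
        if self.n_max < 2 or self.n_max % 2:
            raise ValueError("n_max must be an even count >= 2 for 1:1 allocation")
        sched = self.schedule
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("interim schedule must be strictly increasing")
        if sched and (sched[0] < 1 or sched[-1] >= self.n_max):
            raise ValueError("interim schedule entries must lie in [1, n_max)")
        # the closed endpoints are allowed as degenerate never-firing rules:
        # strict inequalities make an efficacy bar of 1 and a futility bar of
        # 0 unreachable, reproducing the interim-free design on the same stream
        for name in ("efficacy_threshold", "futility_threshold"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.final_success_threshold < 1.0:
            raise ValueError("final_success_threshold must lie in (0, 1)")
        if self.prior_alpha <= 0 or self.prior_beta <= 0:
            raise ValueError("prior shapes must be positive")
        if self.accrual_rate <= 0 or self.followup_days < 0:
            raise ValueError("accrual_rate must be positive and followup_days >= 0")
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def prior(self) -> BetaPosterior:
        return BetaPosterior(self.prior_alpha, self.prior_beta)

    @property
    def n_max_per_arm(self) -> int:
        return self.n_max // 2


@dataclass(frozen=True)
class TrialState:
    """Accrued data at one analysis; tuples are (control, intervention)."""

    enrolled: tuple[int, int]
    completed: tuple[int, int]
    events: tuple[int, int]
    calendar_time: float = float("nan")

    def __post_init__(self) -> None:
        for arm in (CONTROL, INTERVENTION):
            if not 0 <= self.completed[arm] <= self.enrolled[arm]:
                raise ValueError("completed counts must lie in [0, enrolled]")
            if not 0 <= self.events[arm] <= self.completed[arm]:
                raise ValueError("event counts must lie in [0, completed]")

    def posterior(self, design: BinaryDesign, arm: int) -> BetaPosterior:
        return BetaPosterior(
            design.prior_alpha + self.events[arm],
            design.prior_beta + (self.completed[arm] - self.events[arm]),
        )


# ---------------------------------------------------------------------------
# critical-boundary cache

_CRIT_CACHE: dict[tuple, int] = {}


def _critical_events(
    n_ctrl: int,
    n_int: int,
    s_ctrl: int,
    threshold: float,
    prior_alpha: float,
    prior_beta: float,
) -> int:
    """Largest intervention event count that still clears the superiority bar.

    Returns the largest ``s`` with
    ``prob_superiority(ctrl posterior, int posterior with s/n_int) > threshold``,
    or -1 when even zero events fail.  Monotonicity in ``s`` (more
    intervention events can only lower the superiority probability) makes
    the bisection valid; results are memoised globally.
    """
    key = (n_ctrl, n_int, s_ctrl, threshold, prior_alpha, prior_beta)
    cached = _CRIT_CACHE.get(key)
    if cached is not None:
        return cached
    control = BetaPosterior(prior_alpha + s_ctrl, prior_beta + n_ctrl - s_ctrl)

    def clears(s: int) -> bool:
        interv = BetaPosterior(prior_alpha + s, prior_beta + n_int - s)
        return prob_superiority(control, interv) > threshold

    if not clears(0):
        crit = -1
    elif clears(n_int):
        crit = n_int
    else:
        lo, hi = 0, n_int  # invariant: clears(lo), not clears(hi)
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if clears(mid):
                lo = mid
            else:
                hi = mid
        crit = lo
    _CRIT_CACHE[key] = crit
    return crit


def _success_fraction(
    s_ctrl: np.ndarray,
    s_int: np.ndarray,
    n_ctrl: int,
    n_int: int,
    threshold: float,
    prior_alpha: float,
    prior_beta: float,
) -> float:
    """Fraction of (s_ctrl, s_int) pairs clearing the superiority bar."""
    uniq, inverse = np.unique(s_ctrl, return_inverse=True)
    crit = np.array(
        [
            _critical_events(n_ctrl, n_int, int(s), threshold, prior_alpha, prior_beta)
            for s in uniq
        ]
    )
    return float(np.mean(s_int <= crit[inverse]))


def _success_indicator(
    s_ctrl: int,
    s_int: int,
    n_ctrl: int,
    n_int: int,
    threshold: float,
    prior_alpha: float,
    prior_beta: float,
) -> bool:
    return s_int <= _critical_events(n_ctrl, n_int, s_ctrl, threshold, prior_alpha, prior_beta)


# ---------------------------------------------------------------------------
# predictive probabilities


def _check_state(state: TrialState) -> None:
    if sum(state.enrolled) == 0:
        raise ValueError("predictive probabilities need at least one enrolled patient")


def predictive_prob_success_current(
    state: TrialState, design: BinaryDesign, rng: np.random.Generator
) -> float:
    """``P_curr``: predictive probability of success at the current sample size.

    Outcomes of enrolled patients without completed follow-up are imputed
    from each arm's current beta posterior (``design.n_imputations``
    beta-binomial draws); the returned value is the fraction of imputed
    completions in which the final success rule would already be met on the
    currently enrolled patients.  With no incomplete patient the value is
    exactly the 0/1 current success indicator.
    """
    _check_state(state)
    incomplete = tuple(state.enrolled[a] - state.completed[a] for a in (CONTROL, INTERVENTION))
    pa, pb = design.prior_alpha, design.prior_beta
    if incomplete == (0, 0):
        return float(
            _success_indicator(
                state.events[CONTROL],
                state.events[INTERVENTION],
                state.enrolled[CONTROL],
                state.enrolled[INTERVENTION],
                design.final_success_threshold,
                pa,
                pb,
            )
        )
    draws = [
        state.events[arm]
        + sample_predictive_events_batch(
            state.posterior(design, arm), incomplete[arm], design.n_imputations, rng
        )
        for arm in (CONTROL, INTERVENTION)
    ]
    return _success_fraction(
        draws[CONTROL],
        draws[INTERVENTION],
        state.enrolled[CONTROL],
        state.enrolled[INTERVENTION],
        design.final_success_threshold,
        pa,
        pb,
    )


def predictive_prob_success_max(
    state: TrialState, design: BinaryDesign, rng: np.random.Generator
) -> float:
    """``P_max``: predictive probability of success at the maximum sample size.

    Same imputation scheme as ``P_curr`` but every unobserved outcome up to
    ``n_max`` per arm — incomplete follow-up *and* patients not yet
    enrolled — is drawn from the beta-binomial predictive, and the success
    rule is evaluated at the maximum per-arm totals.
    """
    _check_state(state)
    n_arm = design.n_max_per_arm
    unobserved = tuple(n_arm - state.completed[a] for a in (CONTROL, INTERVENTION))
    if min(unobserved) < 0:
        raise ValueError("completed counts exceed the per-arm maximum")
    pa, pb = design.prior_alpha, design.prior_beta
    if unobserved == (0, 0):
        return float(
            _success_indicator(
                state.events[CONTROL],
                state.events[INTERVENTION],
                n_arm,
                n_arm,
                design.final_success_threshold,
                pa,
                pb,
            )
        )
    draws = [
        state.events[arm]
        + sample_predictive_events_batch(
            state.posterior(design, arm), unobserved[arm], design.n_imputations, rng
        )
        for arm in (CONTROL, INTERVENTION)
    ]
    return _success_fraction(
        draws[CONTROL],
        draws[INTERVENTION],
        n_arm,
        n_arm,
        design.final_success_threshold,
        pa,
        pb,
    )


# ---------------------------------------------------------------------------
# trial simulation


def _patient_stream(
    design: BinaryDesign, scenario: Scenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arms, event outcomes and dropout flags for all n_max patients.

    Allocation is 1:1 in permuted blocks of two; outcomes are compared
    against per-arm true rates through shared uniforms so scenarios can be
    varied under common random numbers.
    """
    n = design.n_max
    first = rng.integers(0, 2, size=(n + 1) // 2).astype(np.int8)
    arms = np.empty(n, dtype=np.int8)
    arms[0::2] = first[: arms[0::2].size]
    arms[1::2] = 1 - first[: arms[1::2].size]
    rates = np.array([scenario.control_rate, scenario.intervention_rate])
    outcomes = rng.random(n) < rates[arms]
    if design.dropout_rate > 0:
        dropped = rng.random(n) < design.dropout_rate
    else:
        dropped = np.zeros(n, dtype=bool)
    return arms, outcomes, dropped


def _state_at(
    design: BinaryDesign,
    arms: np.ndarray,
    outcomes: np.ndarray,
    dropped: np.ndarray,
    n_recruited: int,
) -> TrialState:
    """Observable data once ``n_recruited`` patients have been enrolled.

    Under deterministic accrual the patients with completed follow-up are
    exactly the first ``n_recruited - followup_days * accrual_rate`` enrolled
    (dropouts excluded from both enrolment and analysis counts).
    """
    lag = design.followup_days * design.accrual_rate
    n_completed = max(0, min(n_recruited, int(math.floor(n_recruited - lag + 1e-9))))
    keep = ~dropped
    enrolled = tuple(
        int(np.sum((arms[:n_recruited] == arm) & keep[:n_recruited])) for arm in (0, 1)
    )
    completed = tuple(
        int(np.sum((arms[:n_completed] == arm) & keep[:n_completed])) for arm in (0, 1)
    )
    events = tuple(
        int(np.sum((arms[:n_completed] == arm) & keep[:n_completed] & outcomes[:n_completed]))
        for arm in (0, 1)
    )
    return TrialState(enrolled, completed, events, n_recruited / design.accrual_rate)


def final_superiority_probability(
    design: BinaryDesign,
    arms: np.ndarray,
    outcomes: np.ndarray,
    dropped: np.ndarray,
) -> float:
    """Posterior ``Pr(theta_int < theta_ctrl)`` with every outcome observed."""
    keep = ~dropped
    post = []
    for arm in (0, 1):
        in_arm = (arms == arm) & keep
        post.append(
            BetaPosterior(
                design.prior_alpha + int(np.sum(in_arm & outcomes)),
                design.prior_beta + int(np.sum(in_arm & ~outcomes)),
            )
        )
    return prob_superiority(post[CONTROL], post[INTERVENTION])


def simulate_binary_trial(
    design: BinaryDesign,
    scenario: Scenario,
    rng: np.random.Generator,
    imputation_entropy=None,
) -> TrialResult:
    """Simulate one adaptive trial and return its :class:`TrialResult`.

    ``rng`` drives the patient-level data (allocation, outcomes, dropout).
    If ``imputation_entropy`` is given, the imputation stream of the look at
    recruitment count ``n`` is derived from it with spawn key ``(n,)`` —
    independent of which other looks the design performs — so designs
    sharing a look also share its predictive-probability estimate exactly;
    otherwise imputation draws continue on ``rng``.
    """
    arms, outcomes, dropped = _patient_stream(design, scenario, rng)
    for stage, n_look in enumerate(design.schedule, start=1):
        state = _state_at(design, arms, outcomes, dropped, n_look)
        if imputation_entropy is not None:
            look_rng = substream(imputation_entropy, n_look)
        else:
            look_rng = rng
        if design.efficacy_threshold is not None:
            p_curr = predictive_prob_success_current(state, design, look_rng)
            if p_curr > design.efficacy_threshold:
                return TrialResult(True, EFFICACY, True, n_look, stage)
        if design.futility_threshold is not None:
            p_max = predictive_prob_success_max(state, design, look_rng)
            if p_max < design.futility_threshold:
                return TrialResult(True, FUTILITY, False, n_look, stage)
    keep = ~dropped
    s = [int(np.sum((arms == a) & keep & outcomes)) for a in (0, 1)]
    n = [int(np.sum((arms == a) & keep)) for a in (0, 1)]
    success = _success_indicator(
        s[CONTROL],
        s[INTERVENTION],
        n[CONTROL],
        n[INTERVENTION],
        design.final_success_threshold,
        design.prior_alpha,
        design.prior_beta,
    )
    return TrialResult(False, FINAL, bool(success), design.n_max, len(design.schedule) + 1)
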