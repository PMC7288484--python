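"""Simulation-based tuning of stopping/success thresholds.

The probability-threshold families used here are monotone: raising the
efficacy/final bar can only remove successes.  Calibration therefore
simulates the per-look posterior summaries of the null scenario *once* and
treats a candidate threshold as a pure filter over that shared stream —
there is no Monte-Carlo noise between candidates, bisection is valid, and
the whole search is deterministic given the seed.

``calibrate_threshold`` returns the least stringent threshold whose
estimated type I error does not exceed ``target_alpha + tolerance``.
``compare_schedules`` gives a paired (common-random-number) estimate of the
type-I-error difference between two interim schedules of the same design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._rng import substream
from .binary import (
    BinaryDesign,
    Scenario,
    _patient_stream,
    final_superiority_probability,
)
from .oc import binary_success_vector, run_oc
from .results import OperatingCharacteristics
from .tte import HazardScenario, TTEDesign, apply_tte_rules, tte_path_matrix

__all__ = ["CalibrationResult", "ScheduleComparison", "calibrate_threshold", "compare_schedules"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a threshold search.

    ``converged`` is False when no threshold in the bracket attains the
    target within tolerance; ``degenerate`` flags the boundary solutions
    (e.g. target 0 forcing a never-succeed threshold of 1).
    """

    threshold: float
    achieved_type_i_error: float
    mc_standard_error: float
    n_sims: int
    trace: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    converged: bool = True
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "achieved_type_i_error": self.achieved_type_i_error,
            "mc_standard_error": self.mc_standard_error,
            "n_sims": self.n_sims,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "trace": [list(t) for t in self.trace],
        }


def _tte_alpha_fn(design: TTEDesign, hr: float, n_sims: int, seed):
    p_interim, p_final = tte_path_matrix(design, hr, n_sims, substream(seed, 0))

    if design.interim_rule == "efficacy":

        def alpha(b: float) -> float:
            success, _, _ = apply_tte_rules(
                design, p_interim, p_final, final_threshold=b, interim_threshold=b
            )
            return float(np.mean(success))

    else:
        # rule 'none' (final bar only) or 'futility' (futility bar untouched)
        def alpha(b: float) -> float:
            success, _, _ = apply_tte_rules(design, p_interim, p_final, final_threshold=b)
            return float(np.mean(success))

    return alpha


def _binary_alpha_fn(design: BinaryDesign, scenario: Scenario, n_sims: int, seed):
    if design.schedule:
        raise ValueError(
            "threshold calibration supports binary designs without interims only: "
            "the predictive stopping probabilities depend on the final threshold, "
            "so thresholds are not a pure filter over precomputed summaries"
        )
    probs = np.empty(n_sims)
    for i in range(n_sims):
        arms, outcomes, dropped = _patient_stream(design, scenario, substream(seed, 0, i))
        probs[i] = final_superiority_probability(design, arms, outcomes, dropped)

    def alpha(b: float) -> float:
        return float(np.mean(probs > b))

    return alpha


def calibrate_threshold(
    design,
    target_alpha: float,
    scenario,
    tolerance: float = 0.002,
    n_sims: int = 100_000,
    seed=0,
    bracket: tuple[float, float] = (0.5, 1.0 - 1e-12),
    max_iter: int = 60,
) -> CalibrationResult:
    """Least stringent shared threshold attaining the target type I error.

    For a time-to-event design the candidate threshold replaces the final
    success bar and — for an efficacy design — the interim bar as well (one
    shared stringency scalar, as when tightening 0.9 to 0.95 at both looks);
    a futility design keeps its futility bar fixed.  For an interim-free
    binary design the threshold filters the per-sim final superiority
    probability.

    The search bisects on the precomputed null stream; non-convergence
    within ``max_iter`` is flagged on the result, never raised.
    """
    if not 0.0 <= target_alpha <= 1.0:
        raise ValueError("target_alpha must lie in [0, 1]")
    if isinstance(design, TTEDesign):
        hr = scenario.hr if isinstance(scenario, HazardScenario) else float(scenario)
        alpha = _tte_alpha_fn(design, hr, n_sims, seed)
    elif isinstance(design, BinaryDesign):
        alpha = _binary_alpha_fn(design, scenario, n_sims, seed)
    else:
        raise TypeError(f"unsupported design type {type(design).__name__}")

    lo, hi = bracket
    trace: list[tuple[float, float]] = []

    def measure(b: float) -> float:
        a = alpha(b)
        trace.append((b, a))
        return a

    def result(threshold, achieved, converged, degenerate=False):
        se = float(np.sqrt(achieved * (1.0 - achieved) / n_sims))
        logger.info(
            "calibration: threshold %.6f achieves type I error %.5f (target %.5f)",
            threshold,
            achieved,
            target_alpha,
        )
        return CalibrationResult(
            float(threshold), achieved, se, n_sims, tuple(trace), converged, degenerate
        )

    if target_alpha <= 0.0:
        # only the never-succeed rule guarantees zero type I error
        return result(1.0, measure(1.0), True, degenerate=True)
    a_lo = measure(lo)
    if a_lo <= target_alpha + tolerance:
        # even the least stringent candidate meets the target
        return result(lo, a_lo, True, degenerate=target_alpha >= 1.0)
    a_hi = measure(hi)
    if a_hi > target_alpha + tolerance:
        # nothing in the bracket attains the target: report the never-succeed
        # boundary, flagged
        return result(1.0, a_hi, False, degenerate=True)
    # invariant: alpha(lo) > target + tol >= alpha(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if measure(mid) > target_alpha + tolerance:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return result(hi, alpha(hi), True)


@dataclass(frozen=True)
class ScheduleComparison:
    """Paired comparison of two interim schedules under common random numbers."""

    oc_a: OperatingCharacteristics
    oc_b: OperatingCharacteristics
    difference: float  # success proportion of B minus A
    difference_se: float


def compare_schedules(
    template: BinaryDesign,
    schedule_a: Sequence[int],
    schedule_b: Sequence[int],
    scenario: Scenario,
    n_sims: int,
    seed,
) -> ScheduleComparison:
    """Common-random-number comparison of two interim schedules.

    Both runs share patient-level streams and per-look imputation streams,
    so the paired difference estimate ``p_b - p_a`` has far smaller variance
    than two independent runs; identical schedules give exactly zero.
    """
    for sched in (schedule_a, schedule_b):
        if any(s >= template.n_max for s in sched):
            raise ValueError("schedule entries must be below n_max")
    design_a = replace(template, schedule=tuple(schedule_a))
    design_b = replace(template, schedule=tuple(schedule_b))
    succ_a = binary_success_vector(design_a, scenario, n_sims, seed)
    succ_b = binary_success_vector(design_b, scenario, n_sims, seed)
    diff = succ_b.astype(float) - succ_a.astype(float)
    se = float(np.std(diff, ddof=1) / np.sqrt(n_sims)) if n_sims > 1 else 0.0
    label = scenario.label or "scenario"

    def agg(succ, sched):
        p = float(np.mean(succ))
        return OperatingCharacteristics(
            label=f"{label} @ [{','.join(str(s) for s in sched)}]",
            n_sims=n_sims,
            success_proportion=p,
            mc_standard_error=float(np.sqrt(p * (1.0 - p) / n_sims)),
            mean_information_at_stop=float("nan"),
            early_stop_proportions={},
        )

    return ScheduleComparison(
        agg(succ_a, schedule_a), agg(succ_b, schedule_b), float(np.mean(diff)), se
    )
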