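"""Result containers shared by the endpoint-specific simulators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

EFFICACY = "efficacy"
FUTILITY = "futility"
FINAL = "final"
_REASONS = (EFFICACY, FUTILITY, FINAL)


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial.

    Attributes
    ----------
    stopped_early
        True if an interim stopping rule fired before full information.
    stop_reason
        ``"efficacy"``, ``"futility"`` or ``"final"``.
    success
        Whether the trial was declared successful (early efficacy stop, or
        final analysis clearing the success bar).
    information_at_stop
        Events observed (time-to-event) or patients recruited (binary) when
        the trial terminated.
    stage
        1-based index of the analysis at which the trial terminated; the
        final analysis is ``number of interims + 1``.
    """

    stopped_early: bool
    stop_reason: str
    success: bool
    information_at_stop: int
    stage: int

    def __post_init__(self) -> None:
        if self.stop_reason not in _REASONS:
            raise ValueError(f"unknown stop_reason {self.stop_reason!r}")
        if self.stopped_early and self.stop_reason == FINAL:
            raise ValueError("early stop cannot carry reason 'final'")
        if self.success and self.stop_reason == FUTILITY:
            raise ValueError("a futility stop cannot be a success")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Per-scenario frequentist summary of a design, estimated by simulation.

    ``success_proportion`` is the type I error under a null scenario and the
    power under a target-effect scenario.  ``mc_standard_error`` is the
    binomial Monte-Carlo standard error sqrt(p(1-p)/n).
    """

    label: str
    n_sims: int
    success_proportion: float
    mc_standard_error: float
    mean_information_at_stop: float
    early_stop_proportions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.success_proportion <= 1.0:
            raise ValueError("success_proportion outside [0, 1]")
        if self.mc_standard_error < 0:
            raise ValueError("mc_standard_error negative")
        if sum(self.early_stop_proportions.values()) > 1.0 + 1e-12:
            raise ValueError("early-stop proportions exceed 1")

    @classmethod
    def from_results(
        cls, label: str, results: Iterable[TrialResult]
    ) -> "OperatingCharacteristics":
        results = list(results)
        n = len(results)
        if n == 0:
            raise ValueError("no results to aggregate")
        p = sum(r.success for r in results) / n
        se = float(np.sqrt(p * (1.0 - p) / n))
        info = float(np.mean([r.information_at_stop for r in results]))
        early = {
            reason: sum(r.stopped_early and r.stop_reason == reason for r in results) / n
            for reason in (EFFICACY, FUTILITY)
        }
        return cls(label, n, p, se, info, early)
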