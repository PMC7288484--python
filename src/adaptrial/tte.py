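"""Two-arm time-to-event trial simulator monitored on the log hazard ratio.

The trial is summarised at each analysis directly by an estimated log hazard
ratio: at ``d`` events under 1:1 allocation the estimator is approximately
normal with variance ``4/d``, so no patient-level survival times need to be
generated.  A vague normal prior (default N(0, 10 000)) is combined with the
estimate by conjugate updating and the design decisions are driven by the
posterior probability ``Pr(HR < 1 | data)``.

Two look-dependence models are available:

``independent``
    the interim and final estimates are drawn independently of each other.
    This is the default.
``correlated-increments``
    the canonical group-sequential structure: the final score statistic is
    the interim score plus an independent increment, with Fisher
    information ``events / 4``.

Only the independent model admits the closed-form success probability in
:func:`analytic_success_probability`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from ._rng import substream
from .posteriors import NormalPosterior, VAGUE_LOG_HR_PRIOR
from .results import EFFICACY, FINAL, FUTILITY, TrialResult

__all__ = [
    "INDEPENDENT",
    "CORRELATED",
    "TTEDesign",
    "HazardScenario",
    "sample_loghr_estimate",
    "simulate_tte_trial",
    "tte_path_matrix",
    "apply_tte_rules",
    "analytic_success_probability",
]

INDEPENDENT = "independent"
CORRELATED = "correlated-increments"
_RULES = ("none", "futility", "efficacy")


@dataclass(frozen=True)
class TTEDesign:
    """Design of the time-to-event trial.

    Defaults describe a 200-event trial with one optional interim at 100
    events, a final success rule ``Pr(HR < 1 | data) > 0.9``, futility
    stopping below 0.5 and efficacy stopping above the final bar.
    """

    total_events: int = 200
    interim_events: int | None = 100
    interim_rule: str = "none"
    interim_threshold: float | None = None
    final_success_threshold: float = 0.9
    prior: NormalPosterior = VAGUE_LOG_HR_PRIOR
    look_dependence: str = INDEPENDENT
    variance_factor: float = 4.0

    def __post_init__(self) -> None:
        if self.interim_rule not in _RULES:
            raise ValueError(f"interim_rule must be one of {_RULES}")
        if self.look_dependence not in (INDEPENDENT, CORRELATED):
            raise ValueError("look_dependence must be 'independent' or 'correlated-increments'")
        if self.total_events <= 0:
            raise ValueError("total_events must be positive")
        if self.interim_rule != "none" and self.interim_events is None:
            raise ValueError("an interim rule needs interim_events")
        if self.interim_events is not None and not 0 < self.interim_events < self.total_events:
            raise ValueError("interim_events must lie strictly between 0 and total_events")
        if not 0.0 < self.final_success_threshold < 1.0:
            raise ValueError("final_success_threshold must lie in (0, 1)")
        if self.interim_threshold is not None and not 0.0 < self.interim_threshold < 1.0:
            raise ValueError("interim_threshold must lie in (0, 1)")
        if self.variance_factor <= 0:
            raise ValueError("variance_factor must be positive")

    @property
    def effective_interim_threshold(self) -> float:
        """Threshold applied at the interim look.

        Defaults to 0.5 for futility (continue only while
        ``Pr(HR < 1) >= 0.5``) and to the final success bar for efficacy.
        """
        if self.interim_threshold is not None:
            return self.interim_threshold
        return 0.5 if self.interim_rule == "futility" else self.final_success_threshold


@dataclass(frozen=True)
class HazardScenario:
    """A true-effect scenario for the time-to-event endpoint."""

    hr: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.hr > 0:
            raise ValueError("hazard ratio must be positive")


def sample_loghr_estimate(
    true_hr: float,
    events: int,
    rng: np.random.Generator,
    variance_factor: float = 4.0,
) -> tuple[float, float]:
    """Draw one estimated log HR at ``events`` observed events.

    The estimate is normal with mean ``log(true_hr)`` and variance
    ``variance_factor / events`` (4/d for 1:1 allocation).  Returns the
    ``(estimate, variance)`` pair fed to the conjugate update.
    """
    if not true_hr > 0:
        raise ValueError("true_hr must be positive")
    if not events > 0:
        raise ValueError("events must be positive")
    variance = variance_factor / events
    return float(rng.normal(math.log(true_hr), math.sqrt(variance))), variance


def _posterior_prob(estimates: np.ndarray, variance: float, prior: NormalPosterior) -> np.ndarray:
    """Vectorised Pr(HR < 1 | estimate) after the conjugate update."""
    w0 = 1.0 / prior.variance
    w1 = 1.0 / variance
    post_var = 1.0 / (w0 + w1)
    post_mean = (w0 * prior.mean + w1 * np.asarray(estimates)) * post_var
    return special.ndtr(-post_mean / math.sqrt(post_var))


def tte_path_matrix(
    design: TTEDesign, true_hr: float, n_sims: int, rng: np.random.Generator
) -> tuple[np.ndarray | None, np.ndarray]:
    """Per-look posterior probabilities ``Pr(HR < 1)`` for ``n_sims`` trials.

    Returns ``(p_interim, p_final)``; ``p_interim`` is None when the design
    has no interim look.  The interim estimate is drawn whenever
    ``interim_events`` is set — even under ``interim_rule='none'`` — so that
    designs differing only in their decision rules consume identical random
    streams and can be compared path-wise.
    """
    if not true_hr > 0:
        raise ValueError("true_hr must be positive")
    mu = math.log(true_hr)
    v_final = design.variance_factor / design.total_events
    if design.interim_events is None:
        estimates_final = rng.normal(mu, math.sqrt(v_final), size=n_sims)
        return None, _posterior_prob(estimates_final, v_final, design.prior)

    v_interim = design.variance_factor / design.interim_events
    if design.look_dependence == INDEPENDENT:
        est_interim = rng.normal(mu, math.sqrt(v_interim), size=n_sims)
        est_final = rng.normal(mu, math.sqrt(v_final), size=n_sims)
    else:
        info_interim = 1.0 / v_interim
        info_final = 1.0 / v_final
        score_interim = rng.normal(info_interim * mu, math.sqrt(info_interim), size=n_sims)
        increment = rng.normal(
            (info_final - info_interim) * mu,
            math.sqrt(info_final - info_interim),
            size=n_sims,
        )
        est_interim = score_interim / info_interim
        est_final = (score_interim + increment) / info_final
    return (
        _posterior_prob(est_interim, v_interim, design.prior),
        _posterior_prob(est_final, v_final, design.prior),
    )


def apply_tte_rules(
    design: TTEDesign,
    p_interim: np.ndarray | None,
    p_final: np.ndarray,
    final_threshold: float | None = None,
    interim_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the design's decision rules to precomputed per-look probabilities.

    A pure filter: thresholds may be overridden (used by the calibration
    search) without re-simulating.  Returns boolean ``success``, integer
    ``stage`` of termination (1 = interim, 2 = final; always the final stage
    when there is no interim rule) and ``events_at_stop``.

    Inequalities are strict as printed: success/efficacy require ``p > b``;
    futility stops when ``p < b_L`` so a tie at the futility bar continues.
    """
    b = design.final_success_threshold if final_threshold is None else final_threshold
    p_final = np.asarray(p_final)
    n = p_final.shape[0]
    if design.interim_rule == "none" or p_interim is None:
        success = p_final > b
        stage = np.full(n, 2 if p_interim is not None else 1, dtype=np.int8)
        events = np.full(n, design.total_events, dtype=np.int64)
        return success, stage, events

    t = design.effective_interim_threshold if interim_threshold is None else interim_threshold
    p_interim = np.asarray(p_interim)
    stage = np.full(n, 2, dtype=np.int8)
    events = np.full(n, design.total_events, dtype=np.int64)
    if design.interim_rule == "efficacy":
        stop = p_interim > t
        success = stop | (p_final > b)
    else:  # futility
        stop = p_interim < t
        success = (~stop) & (p_final > b)
    stage[stop] = 1
    events[stop] = design.interim_events
    return success, stage, events


def simulate_tte_trial(
    design: TTEDesign, true_hr: float, rng: np.random.Generator
) -> TrialResult:
    """Simulate a single trial and return its :class:`TrialResult`."""
    p_interim, p_final = tte_path_matrix(design, true_hr, 1, rng)
    success, stage, events = apply_tte_rules(design, p_interim, p_final)
    stopped = bool(stage[0] == 1) and design.interim_rule != "none"
    if stopped:
        reason = EFFICACY if design.interim_rule == "efficacy" else FUTILITY
    else:
        reason = FINAL
    return TrialResult(stopped, reason, bool(success[0]), int(events[0]), int(stage[0]))


def _look_success_prob(
    threshold: float,
    events: int,
    true_hr: float,
    prior: NormalPosterior,
    variance_factor: float,
) -> float:
    """P(posterior prob at this look exceeds ``threshold``) under ``true_hr``.

    Inverts the conjugate update exactly: the prior's shrinkage is included,
    and the expression reduces to Phi(Phi^-1(1-b) - log hr / sqrt(v)) in the
    flat-prior limit.
    """
    v = variance_factor / events
    w0 = 1.0 / prior.variance
    w1 = 1.0 / v
    post_var = 1.0 / (w0 + w1)
    # success iff posterior mean < -z_b * post_sd
    cut = (-special.ndtri(threshold) * math.sqrt(post_var) - w0 * prior.mean * post_var) / (
        w1 * post_var
    )
    return float(special.ndtr((cut - math.log(true_hr)) / math.sqrt(v)))


def analytic_success_probability(design: TTEDesign, true_hr: float) -> float:
    """Closed-form success probability under independently drawn looks.

    With per-look success probabilities ``p_k``: an efficacy design succeeds
    unless both looks fail, ``1 - (1 - p_int)(1 - p_fin)``; a futility design
    succeeds when it continues at the interim (probability from the
    continuation rule) and then clears the final bar; a design without an
    interim rule succeeds with ``p_fin`` alone.
    """
    if design.look_dependence != INDEPENDENT:
        raise ValueError("no closed form under correlated-increments look dependence")
    if not true_hr > 0:
        raise ValueError("true_hr must be positive")
    p_final = _look_success_prob(
        design.final_success_threshold,
        design.total_events,
        true_hr,
        design.prior,
        design.variance_factor,
    )
    if design.interim_rule == "none":
        return p_final
    p_interim = _look_success_prob(
        design.effective_interim_threshold,
        design.interim_events,
        true_hr,
        design.prior,
        design.variance_factor,
    )
    if design.interim_rule == "efficacy":
        return 1.0 - (1.0 - p_interim) * (1.0 - p_final)
    # futility: continue iff Pr(HR < 1) >= b_L, then clear the final bar.
    return p_interim * p_final
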