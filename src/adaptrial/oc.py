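"""Replicated-simulation driver: operating characteristics across scenarios.

Runs many simulated trials of a design under a true-effect scenario and
aggregates frequentist summaries: the success proportion (type I error under
a null scenario, power under a target-effect scenario), its binomial
Monte-Carlo standard error, mean information at termination, and early-stop
proportions by reason.

Reproducibility contract: every trial's random stream is keyed by
``(master seed, sim index)``, so results are bit-identical regardless of
execution order or batching, and two designs run with the same seed share
their patient-level streams (common random numbers).
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .binary import BinaryDesign, Scenario, build_even_schedule, simulate_binary_trial
from .results import EFFICACY, FUTILITY, OperatingCharacteristics, TrialResult
from .tte import HazardScenario, TTEDesign, apply_tte_rules, tte_path_matrix

__all__ = [
    "run_oc",
    "sweep_interims",
    "binary_trial_results",
    "binary_success_vector",
    "results_to_frame",
    "oc_table",
    "plot_sweep",
]

logger = logging.getLogger(__name__)

_LOG_EVERY = 2000


def _scenario_label(scenario) -> str:
    label = getattr(scenario, "label", "")
    if label:
        return label
    if isinstance(scenario, HazardScenario):
        return f"HR={scenario.hr:g}"
    if isinstance(scenario, Scenario):
        return f"{scenario.control_rate:g}/{scenario.intervention_rate:g}"
    return str(scenario)


def _run_tte(design: TTEDesign, hr: float, n_sims: int, seed, label: str):
    rng = substream(seed, 0)
    p_interim, p_final = tte_path_matrix(design, hr, n_sims, rng)
    success, stage, events = apply_tte_rules(design, p_interim, p_final)
    p = float(np.mean(success))
    early = {EFFICACY: 0.0, FUTILITY: 0.0}
    if design.interim_rule in (EFFICACY, FUTILITY):
        early[design.interim_rule] = float(np.mean(stage == 1))
    return OperatingCharacteristics(
        label=label,
        n_sims=n_sims,
        success_proportion=p,
        mc_standard_error=float(np.sqrt(p * (1.0 - p) / n_sims)),
        mean_information_at_stop=float(np.mean(events)),
        early_stop_proportions=early,
    )


def binary_trial_results(
    design: BinaryDesign, scenario: Scenario, n_sims: int, seed
) -> Iterator[TrialResult]:
    """Yield per-trial results; trial ``i`` uses substreams keyed by ``i``."""
    for i in range(n_sims):
        yield simulate_binary_trial(
            design,
            scenario,
            substream(seed, 0, i),
            imputation_entropy=(seed, 1, i) if not isinstance(seed, tuple) else (*seed, 1, i),
        )
        if (i + 1) % _LOG_EVERY == 0:
            logger.info("binary simulation: %d/%d trials done", i + 1, n_sims)


def binary_success_vector(
    design: BinaryDesign, scenario: Scenario, n_sims: int, seed
) -> np.ndarray:
    """Boolean per-trial success indicators (for path-wise comparisons)."""
    return np.array(
        [r.success for r in binary_trial_results(design, scenario, n_sims, seed)], dtype=bool
    )


def run_oc(design, scenario, n_sims: int, seed, label: str | None = None):
    """Simulate ``n_sims`` trials of ``design`` under ``scenario``.

    ``design`` is a :class:`~adaptrial.tte.TTEDesign` (scenario: a hazard
    ratio or :class:`~adaptrial.tte.HazardScenario`) or a
    :class:`~adaptrial.binary.BinaryDesign` (scenario: a
    :class:`~adaptrial.binary.Scenario`).  Returns
    :class:`~adaptrial.results.OperatingCharacteristics`.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if isinstance(design, TTEDesign):
        if isinstance(scenario, (int, float)):
            scenario = HazardScenario(float(scenario))
        label = label or _scenario_label(scenario)
        return _run_tte(design, scenario.hr, n_sims, seed, label)
    if isinstance(design, BinaryDesign):
        label = label or _scenario_label(scenario)
        results = binary_trial_results(design, scenario, n_sims, seed)
        oc = OperatingCharacteristics.from_results(label, results)
        logger.info(
            "%s: success %.4f (MC SE %.4f) over %d sims",
            label,
            oc.success_proportion,
            oc.mc_standard_error,
            n_sims,
        )
        return oc
    raise TypeError(f"unsupported design type {type(design).__name__}")


def sweep_interims(
    template: BinaryDesign,
    interim_counts: Sequence[int],
    scenarios: Sequence[Scenario],
    n_sims: int,
    seed,
    schedules: Sequence[Sequence[int]] | None = None,
    common_random_numbers: bool = True,
) -> pd.DataFrame:
    """Operating characteristics across interim counts and scenarios.

    One row per (interim count, scenario).  ``schedules`` may override the
    evenly spaced schedules (then ``interim_counts`` are just row labels).
    Under common random numbers (default) all designs within a scenario
    share patient-level streams and per-look imputation streams, so
    path-wise comparisons between designs are exact; set
    ``common_random_numbers=False`` for independent streams per design.
    """
    rows = []
    for d_idx, k in enumerate(interim_counts):
        if schedules is not None:
            schedule = tuple(schedules[d_idx])
        else:
            schedule = tuple(build_even_schedule(template.n_max, int(k)))
        design = replace(template, schedule=schedule)
        for scenario in scenarios:
            design_seed = seed if common_random_numbers else (seed, 1000 + d_idx)
            oc = run_oc(design, scenario, n_sims, design_seed)
            rows.append(
                {
                    "n_interims": int(k),
                    "schedule": ",".join(str(s) for s in schedule),
                    "scenario": oc.label,
                    "n_sims": oc.n_sims,
                    "success_proportion": oc.success_proportion,
                    "mc_standard_error": oc.mc_standard_error,
                    "mean_n_at_stop": oc.mean_information_at_stop,
                    "prop_stopped_efficacy": oc.early_stop_proportions.get(EFFICACY, 0.0),
                    "prop_stopped_futility": oc.early_stop_proportions.get(FUTILITY, 0.0),
                }
            )
    return pd.DataFrame(rows)


def results_to_frame(results: Iterable[TrialResult]) -> pd.DataFrame:
    """Per-trial results as a DataFrame (columns match the streamed CSV)."""
    return pd.DataFrame(
        {
            "sim_id": i,
            "stop_stage": r.stage,
            "stop_reason": r.stop_reason,
            "success": r.success,
            "n_enrolled_at_stop": r.information_at_stop,
        }
        for i, r in enumerate(results)
    )


def oc_table(ocs: Iterable[OperatingCharacteristics], **extra) -> pd.DataFrame:
    """Tabulate OperatingCharacteristics rows, with optional constant columns."""
    rows = []
    for oc in ocs:
        row = {
            "scenario": oc.label,
            "n_sims": oc.n_sims,
            "success_proportion": oc.success_proportion,
            "mc_standard_error": oc.mc_standard_error,
            "mean_information_at_stop": oc.mean_information_at_stop,
            "prop_stopped_efficacy": oc.early_stop_proportions.get(EFFICACY, 0.0),
            "prop_stopped_futility": oc.early_stop_proportions.get(FUTILITY, 0.0),
        }
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_sweep(table: pd.DataFrame, value: str = "success_proportion", ax=None):
    """Convenience line chart of an OC quantity against the interim count."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for scenario, group in table.groupby("scenario"):
        group = group.sort_values("n_interims")
        ax.plot(group["n_interims"], group[value], marker="o", label=str(scenario))
    ax.set_xlabel("number of interim analyses")
    ax.set_ylabel(value.replace("_", " "))
    ax.legend()
    return ax
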