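"""Binary-outcome simulator: schedules, predictive probabilities, stopping."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from adaptrial._rng import substream
from adaptrial.binary import (
    NULL_BALTI,
    TARGET_BALTI,
    BinaryDesign,
    Scenario,
    TrialState,
    build_even_schedule,
    predictive_prob_success_current,
    predictive_prob_success_max,
    simulate_binary_trial,
)
from adaptrial.posteriors import BetaPosterior, prob_superiority


def enumerate_p_curr(state: TrialState, design: BinaryDesign) -> float:
    """Exact P_curr: enumerate imputed event splits weighted by their
    beta-binomial probabilities (feasible for few incomplete patients)."""
    total = 0.0
    m = [state.enrolled[a] - state.completed[a] for a in (0, 1)]
    post = [state.posterior(design, a) for a in (0, 1)]
    for x_c in range(m[0] + 1):
        w_c = stats.betabinom.pmf(x_c, m[0], post[0].alpha, post[0].beta)
        for x_i in range(m[1] + 1):
            w_i = stats.betabinom.pmf(x_i, m[1], post[1].alpha, post[1].beta)
            ctrl = BetaPosterior(
                design.prior_alpha + state.events[0] + x_c,
                design.prior_beta + state.enrolled[0] - state.events[0] - x_c,
            )
            interv = BetaPosterior(
                design.prior_alpha + state.events[1] + x_i,
                design.prior_beta + state.enrolled[1] - state.events[1] - x_i,
            )
            if prob_superiority(ctrl, interv) > design.final_success_threshold:
                total += w_c * w_i
    return total


class TestSchedule:
    def test_balti_even_schedules(self):
        assert build_even_schedule(1334, 3) == [334, 667, 1001]
        assert build_even_schedule(1334, 1) == [667]
        assert build_even_schedule(1334, 0) == []

    def test_overcrowded_schedule_rejected(self):
        with pytest.raises(ValueError):
            build_even_schedule(10, 20)

    def test_schedule_strictly_increasing_below_n_max(self):
        for k in (2, 5, 10, 25, 50):
            sched = build_even_schedule(1334, k)
            assert all(b > a for a, b in zip(sched, sched[1:]))
            assert sched[-1] < 1334


class TestPredictiveProbabilities:
    design = BinaryDesign(schedule=(334, 667, 1001), n_imputations=2000)

    def test_fully_observed_state_is_indicator(self, rng):
        # strongly favourable data: success indicator 1
        state = TrialState((300, 300), (300, 300), (130, 50))
        assert predictive_prob_success_current(state, self.design, rng) == 1.0
        # exchangeable data: indicator 0
        state = TrialState((300, 300), (300, 300), (130, 130))
        assert predictive_prob_success_current(state, self.design, rng) == 0.0

    def test_empty_trial_rejected(self, rng):
        state = TrialState((0, 0), (0, 0), (0, 0))
        with pytest.raises(ValueError):
            predictive_prob_success_current(state, self.design, rng)

    def test_p_curr_matches_enumeration_oracle(self, rng):
        """Monte-Carlo P_curr within 3 binomial SE of the exact enumeration."""
        for events in [(60, 30), (55, 40), (45, 45)]:
            state = TrialState((110, 110), (100, 100), events)
            exact = enumerate_p_curr(state, self.design)
            approx = predictive_prob_success_current(state, self.design, rng)
            se = math.sqrt(max(exact * (1 - exact), 1e-6) / self.design.n_imputations)
            assert abs(approx - exact) <= 3 * se + 1e-9

    def test_p_curr_near_one_for_strong_effect(self, rng):
        state = TrialState((310, 310), (300, 300), (130, 50))
        assert predictive_prob_success_current(state, self.design, rng) > 0.99

    def test_p_max_indicator_at_full_information(self, rng):
        design = replace(self.design, n_max=600, schedule=())
        state = TrialState((300, 300), (300, 300), (130, 50))
        assert predictive_prob_success_max(state, design, rng) == 1.0

    def test_p_max_low_for_identical_arms(self, rng):
        state = TrialState((450, 450), (450, 450), (200, 200))
        assert predictive_prob_success_max(state, self.design, rng) < 0.5

    def test_p_max_equals_p_curr_with_no_future_patients(self, rng):
        design = replace(self.design, n_max=600, schedule=())
        state = TrialState((300, 300), (295, 295), (130, 60))
        seed_state = rng.integers(2**31)
        p_curr = predictive_prob_success_current(state, design, np.random.default_rng(seed_state))
        p_max = predictive_prob_success_max(state, design, np.random.default_rng(seed_state))
        assert p_curr == p_max

    def test_probabilities_within_unit_interval(self, rng):
        state = TrialState((120, 120), (90, 90), (40, 35))
        for fn in (predictive_prob_success_current, predictive_prob_success_max):
            assert 0.0 <= fn(state, self.design, rng) <= 1.0


class TestTrialSimulation:
    def test_identical_seed_identical_results(self):
        design = BinaryDesign(schedule=(100, 200), n_max=400, n_imputations=100)
        runs = [
            [
                simulate_binary_trial(
                    design, NULL_BALTI, substream(9, 0, i), imputation_entropy=(9, 1, i)
                )
                for i in range(20)
            ]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_unreachable_rules_match_no_interim_design(self):
        """Thresholds at the extremes never fire, so results coincide with
        the interim-free design on the same stream."""
        base = dict(n_max=400, n_imputations=100)
        lenient = BinaryDesign(
            schedule=(100, 200),
            efficacy_threshold=1.0,
            futility_threshold=0.0,
            **base,
        )
        fixed = BinaryDesign(schedule=(), **base)
        for i in range(25):
            r_lenient = simulate_binary_trial(
                lenient, TARGET_BALTI, substream(21, 0, i), imputation_entropy=(21, 1, i)
            )
            r_fixed = simulate_binary_trial(
                fixed, TARGET_BALTI, substream(21, 0, i), imputation_entropy=(21, 1, i)
            )
            assert r_lenient.success == r_fixed.success
            assert not r_lenient.stopped_early

    def test_efficacy_stop_is_a_success_at_the_interim(self):
        design = BinaryDesign(
            schedule=(300,),
            n_max=600,
            efficacy_threshold=0.5,
            futility_threshold=None,
            n_imputations=200,
        )
        strong = Scenario(0.6, 0.05, "strong")
        result = simulate_binary_trial(design, strong, substream(2, 0, 0))
        assert result.stopped_early and result.stop_reason == "efficacy"
        assert result.success and result.information_at_stop == 300

    def test_futility_stop_is_a_failure(self):
        design = BinaryDesign(
            schedule=(300,),
            n_max=600,
            efficacy_threshold=None,
            futility_threshold=0.5,
            n_imputations=200,
        )
        harmful = Scenario(0.05, 0.6, "harmful")
        result = simulate_binary_trial(design, harmful, substream(2, 0, 1))
        assert result.stopped_early and result.stop_reason == "futility"
        assert not result.success

    def test_allocation_is_one_to_one(self):
        from adaptrial.binary import _patient_stream

        design = BinaryDesign(n_max=400)
        arms, outcomes, dropped = _patient_stream(design, NULL_BALTI, substream(1, 0))
        assert arms.sum() == 200  # exact balance with permuted blocks of 2
        # every even prefix is balanced
        assert abs(arms[:100].sum() - 50) <= 0

    def test_followup_lag_controls_incomplete_count(self):
        from adaptrial.binary import _patient_stream, _state_at

        design = BinaryDesign(accrual_rate=2.0, followup_days=28.0)
        arms, outcomes, dropped = _patient_stream(design, NULL_BALTI, substream(1, 1))
        state = _state_at(design, arms, outcomes, dropped, 334)
        assert sum(state.enrolled) == 334
        assert sum(state.completed) == 334 - 56

    def test_design_validation(self):
        with pytest.raises(ValueError):
            BinaryDesign(schedule=(100, 100))
        with pytest.raises(ValueError):
            BinaryDesign(schedule=(1400,))
        with pytest.raises(ValueError):
            BinaryDesign(n_max=1333)
        with pytest.raises(ValueError):
            BinaryDesign(efficacy_threshold=1.5)
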