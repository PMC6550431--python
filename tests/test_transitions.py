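"""Transition-kernel behaviour: age bands, mortality, relapse, full rows."""

import numpy as np
import pytest

import her2ce as h
from her2ce.parameters import AGE_BANDS, band_by_label
from her2ce.transitions import (
    PatientContext,
    State,
    attained_age_band,
    background_mortality,
    post_quit_ramp,
    relapse_probability,
    transition_distribution,
)


def ctx(arm="TH", state=State.RELAPSE_FREE, month=20, start_age=40.0, **kw):
    return PatientContext(arm_id=arm, current_state=state, month=month, start_age=start_age, **kw)


@pytest.mark.parametrize(
    "start_age, month, label",
    [
        (40, 1, "40-49"),
        (40, 120, "40-49"),  # attained 49.92
        (40, 121, "50-59"),  # attained exactly 50
        (40, 361, "70-79"),
        (70, 121, "80+"),
        (80, 500, "80+"),  # open-ended top band
    ],
)
def test_attained_age_band(start_age, month, label):
    assert attained_age_band(start_age, month).label == label


@pytest.mark.parametrize(
    "arm, band, month, expected",
    [
        ("NT", "40-49", 12, 0.00040),  # early-years override
        ("NT", "40-49", 24, 0.00040),
        ("NT", "40-49", 25, 0.00034),
        ("NT", "80+", 12, 0.01485),
        ("TH", "40-49", 1, 0.00034),  # no override outside NT
        ("TH", "80+", 500, 0.01485),
    ],
)
def test_background_mortality(base, arm, band, month, expected):
    assert background_mortality(base, arm, band_by_label(band), month) == expected


def test_mortality_nondecreasing_in_band(base):
    for arm in h.ARM_IDS:
        vals = [base.arms[arm].mortality.by_band[b.label] for b in AGE_BANDS]
        assert vals == sorted(vals)


class TestRelapseProbability:
    def test_zero_during_treatment(self, base):
        for arm, last in (("TH", 12), ("NT", 6)):
            for m in range(1, last + 1):
                assert relapse_probability(base, ctx(arm, State.ADJUVANT, m)) == 0.0

    def test_schedule_by_year_band(self, base):
        assert relapse_probability(base, ctx("TH", month=20)) == 0.00042
        assert relapse_probability(base, ctx("TH", month=25)) == 0.00051  # year 3
        assert relapse_probability(base, ctx("NT", month=7)) == 0.007
        assert relapse_probability(base, ctx("NT", month=130)) == 0.0016  # year 11+

    def test_horizon_reverts_to_untreated_schedule(self, base_copy):
        base_copy.effect_horizon_years = 4
        assert relapse_probability(base_copy, ctx("TH", month=60)) == 0.0045  # NT years 5-8
        assert relapse_probability(base_copy, ctx("TH", month=48)) == 0.00051  # still own schedule
        # the untreated arm is unaffected by construction
        assert relapse_probability(base_copy, ctx("NT", month=60)) == 0.0045

    def test_quit_ramp_then_untreated_schedule(self, base):
        c = ctx("TH", month=12, quit=True, quit_month=12)
        assert relapse_probability(base, c) == 0.0126
        c2 = ctx("TH", month=30, quit=True, quit_month=5)
        assert relapse_probability(base, c2) == 0.0085  # NT years 3-4 after the ramp

    def test_rejects_dead_and_relapse_states(self, base):
        with pytest.raises(ValueError):
            relapse_probability(base, ctx("TH", State.RELAPSE, 20))


class TestPostQuitRamp:
    def test_endpoints(self):
        # at the quit month the hazard is the scheduled value
        assert post_quit_ramp(0.00042, 4, 4, 12, 0.0126) == 0.00042
        # at the planned treatment end it reaches the ceiling
        assert post_quit_ramp(0.00042, 4, 12, 12, 0.0126) == 0.0126

    def test_midpoint_is_mean_of_endpoints(self):
        v = post_quit_ramp(0.002, 4, 8, 12, 0.0126)
        assert v == pytest.approx((0.002 + 0.0126) / 2)

    def test_month_before_quit_rejected(self):
        with pytest.raises(ValueError):
            post_quit_ramp(0.001, 6, 5, 12, 0.0126)


class TestTransitionDistribution:
    def test_th_adjuvant_month2_published_probabilities(self, base):
        dist = transition_distribution(base, ctx("TH", State.ADJUVANT, 2))
        assert dist[State.DEAD] == pytest.approx(0.00034)
        assert dist[State.HIGH_TOX] == pytest.approx(0.00170 + 0.00340)
        assert dist[State.LOW_TOX] == pytest.approx(0.00761 + 0.00148)
        assert dist[State.ADJUVANT] == pytest.approx(1 - 0.00034 - 0.0017 - 0.0034 - 0.00761 - 0.00148)

    def test_relapse_state_death_is_excess_plus_background(self, base):
        dist = transition_distribution(base, ctx("TH", State.RELAPSE, 30))
        assert dist[State.DEAD] == pytest.approx(0.02734 + 0.00034)
        assert dist[State.RELAPSE] == pytest.approx(1 - 0.02734 - 0.00034)

    def test_final_treatment_month_moves_to_relapse_free(self, base):
        dist = transition_distribution(base, ctx("TH", State.ADJUVANT, 12))
        assert State.HIGH_TOX not in dist and State.LOW_TOX not in dist
        assert dist[State.RELAPSE_FREE] == pytest.approx(1 - 0.00034)

    def test_toxicity_lasts_one_month(self, base):
        dist = transition_distribution(base, ctx("TH", State.HIGH_TOX, 5))
        assert dist[State.ADJUVANT] == pytest.approx(1 - 0.00034)
        # quit-pending toxicity month exits to relapse-free instead
        dist_q = transition_distribution(base, ctx("TH", State.HIGH_TOX, 5, quit_pending=True))
        assert dist_q[State.RELAPSE_FREE] == pytest.approx(1 - 0.00034)

    def test_no_transition_from_dead(self, base):
        with pytest.raises(ValueError):
            transition_distribution(base, ctx("TH", State.DEAD, 5))

    def test_rows_sum_to_one_everywhere(self, base):
        """Sum-to-one over a sweep of reachable contexts, fixture + random sets."""
        psets = [base] + [h.random_scenario(s) for s in range(100)]
        months = [1, 2, 5, 6, 7, 11, 12, 13, 24, 25, 48, 100, 300, 700]
        for pset in psets:
            for arm in h.ARM_IDS:
                tm = pset.arms[arm].treatment_months
                for m in months:
                    for state in (State.ADJUVANT, State.RELAPSE_FREE, State.RELAPSE):
                        kw = {}
                        if state == State.RELAPSE_FREE and m > 3:
                            kw = {"quit": True, "quit_month": min(m, tm)}
                        dist = transition_distribution(pset, ctx(arm, state, m, **kw))
                        total = sum(dist.values())
                        assert abs(total - 1.0) < 1e-12
                        assert all(p >= 0 for p in dist.values())


def test_event_sum_above_one_raises(base_copy):
    base_copy.arms["ACTH"].toxicity.p_low_event = 0.999
    with pytest.raises(ValueError, match="exceed"):
        transition_distribution(base_copy, ctx("ACTH", State.ADJUVANT, 2))
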