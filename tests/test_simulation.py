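"""Microsimulation engine, trajectory scoring, and the cohort-trace oracle."""

import copy

import numpy as np
import pytest

import her2ce as h
from her2ce.parameters import MAX_AGE_YEARS
from her2ce.simulation import PatientTrajectory, _simulate_cohort, max_months
from her2ce.transitions import State


def _forced_death_pset(base):
    """Parameter set in which every patient dies in the first month."""
    p = copy.deepcopy(base)
    for arm in h.ARM_IDS:
        for b in p.arms[arm].mortality.by_band:
            p.arms[arm].mortality.by_band[b] = 1.0
        if p.arms[arm].mortality.early_override_by_band:
            for b in p.arms[arm].mortality.early_override_by_band:
                p.arms[arm].mortality.early_override_by_band[b] = 1.0
        if p.arms[arm].toxicity:
            p.arms[arm].toxicity.p_high_event = 0.0
            p.arms[arm].toxicity.p_low_event = 0.0
            p.arms[arm].toxicity.p_quit_high = 0.0
            p.arms[arm].toxicity.p_quit_low = 0.0
    return p


class TestSimulatePatient:
    def test_certain_death_gives_one_alive_month(self, base):
        p = _forced_death_pset(base)
        traj = h.simulate_patient(p, "TH", np.random.default_rng(0))
        alive = [s for _, s in traj.states if s != State.DEAD]
        assert alive == [State.ADJUVANT]
        assert traj.states[-1] == (2, State.DEAD)
        assert (2, "death") in traj.events

    def test_same_stream_reproduces_trajectory(self, base):
        a = h.simulate_patient(base, "TH", np.random.default_rng(42))
        b = h.simulate_patient(base, "TH", np.random.default_rng(42))
        assert a.states == b.states and a.events == b.events

    def test_starts_in_adjuvant_dead_absorbing(self, base):
        traj = h.simulate_patient(base, "NT", np.random.default_rng(5))
        assert traj.states[0] == (1, State.ADJUVANT)
        dead_months = [m for m, s in traj.states if s == State.DEAD]
        assert len(dead_months) == 1 and traj.states[-1][1] == State.DEAD

    def test_age_cap_terminates(self, base_copy):
        for arm in h.ARM_IDS:
            for b in base_copy.arms[arm].mortality.by_band:
                base_copy.arms[arm].mortality.by_band[b] = 0.0
            base_copy.arms[arm].mortality.early_override_by_band = None
            base_copy.arms[arm].mortality.early_override_months = None
            for band in base_copy.arms[arm].relapse.bands:
                band.monthly_prob = 0.0
        traj = h.simulate_patient(base_copy, "NT", np.random.default_rng(0))
        assert traj.forced_termination
        assert traj.states[-1][0] == max_months(40.0) + 1
        assert traj.states[-1][0] / 12 + 40 >= MAX_AGE_YEARS


class TestScoreTrajectory:
    def test_hand_built_three_month_cost(self, base):
        traj = PatientTrajectory(
            states=[(1, State.ADJUVANT), (2, State.ADJUVANT), (3, State.DEAD)],
            events=[(3, "death")],
        )
        out = h.score_trajectory(traj, base, "TH")
        df = lambda m: 1.03 ** (-(m - 1) / 12)
        expected = 7812.34 * df(1) + 7812.34 * df(2) + 10000 * df(3)
        assert out.disc_cost == pytest.approx(expected)
        assert out.ly == pytest.approx(2 / 12)
        assert out.months_alive == 2

    def test_zero_utilities_zero_qaly_positive_ly(self, base_copy):
        for a in h.ARM_IDS:
            base_copy.utilities.therapy[a] = 0.0
        base_copy.utilities.relapse_free_post_therapy = 0.0
        base_copy.utilities.relapse = 0.0
        base_copy.utilities.high_tox = base_copy.utilities.low_tox = 0.0
        traj = h.simulate_patient(base_copy, "NT", np.random.default_rng(3))
        out = h.score_trajectory(traj, base_copy, "NT")
        assert out.disc_qaly == 0.0 and out.ly > 0

    def test_relapse_entry_charges_retreatment_once(self, base):
        traj = PatientTrajectory(
            states=[(1, State.ADJUVANT)]
            + [(m, State.ADJUVANT) for m in range(2, 7)]
            + [(7, State.RELAPSE_FREE), (8, State.RELAPSE), (9, State.RELAPSE), (10, State.DEAD)],
            events=[(8, "relapse"), (10, "death")],
            retreated=True,
        )
        out = h.score_trajectory(traj, base, "NT")
        df = lambda m: 1.03 ** (-(m - 1) / 12)
        treat = 5896.59
        expected = (
            sum(treat * df(m) for m in range(1, 7))
            + 286.0 * df(7)
            + (286.0 + treat * 6) * df(8)  # relapse month: state cost + full course
            + 286.0 * df(9)
            + 10000 * df(10)
        )
        assert out.disc_cost == pytest.approx(expected)

    def test_qaly_bounded_by_ly(self, base):
        for seed in range(20):
            traj = h.simulate_patient(base, "TH", np.random.default_rng(seed))
            out = h.score_trajectory(traj, base, "TH")
            assert out.disc_qaly <= out.ly + 1e-12

    def test_no_discount_unit_utility_qaly_equals_ly(self, base_copy):
        base_copy.discount_rate_annual = 0.0
        for a in h.ARM_IDS:
            base_copy.utilities.therapy[a] = 1.0
        base_copy.utilities.relapse_free_post_therapy = 0.90  # anchor: full baseline
        base_copy.utilities.relapse = 1.0
        base_copy.utilities.high_tox = base_copy.utilities.low_tox = 1.0
        for b in base_copy.utilities.baseline_by_band:
            base_copy.utilities.baseline_by_band[b] = 1.0
        traj = h.simulate_patient(base_copy, "NT", np.random.default_rng(11))
        out = h.score_trajectory(traj, base_copy, "NT")
        assert out.disc_qaly == pytest.approx(out.ly, rel=1e-12)


class TestVectorizedEngine:
    def test_matches_scalar_engine_patient_by_patient(self, base):
        """The vectorized cohort engine and the scalar walk consume the same
        uniform stream and must produce identical outcomes."""
        n, cap = 60, max_months(40.0)
        uniforms = np.random.default_rng(123).random((n, cap))
        res = _simulate_cohort(base, "TH", uniforms, 40.0)
        for i in range(n):
            traj = h.simulate_patient(base, "TH", uniforms[i])
            out = h.score_trajectory(traj, base, "TH")
            assert res["cost"][i] == pytest.approx(out.disc_cost, rel=1e-10), i
            assert res["qaly"][i] == pytest.approx(out.disc_qaly, rel=1e-10), i
            assert res["ly"][i] == pytest.approx(out.ly, rel=1e-10), i
            assert res["months_alive"][i] == out.months_alive

    def test_matches_scalar_on_random_scenarios(self):
        for seed in (0, 1):
            pset = h.random_scenario(seed)
            start_age = pset.start_age
            cap = max_months(start_age)
            uniforms = np.random.default_rng(seed + 500).random((25, cap))
            for arm in ("NT", "ACTH"):
                res = _simulate_cohort(pset, arm, uniforms, start_age)
                for i in range(25):
                    traj = h.simulate_patient(pset, arm, uniforms[i])
                    out = h.score_trajectory(traj, pset, arm)
                    assert res["cost"][i] == pytest.approx(out.disc_cost, rel=1e-10)
                    assert res["qaly"][i] == pytest.approx(out.disc_qaly, rel=1e-10)

    def test_summary_deterministic_in_seed(self, base):
        a = h.simulate_arm(base, "TH", n=500, seed=9)
        b = h.simulate_arm(base, "TH", n=500, seed=9)
        assert a == b
        c = h.simulate_arm(base, "TH", n=500, seed=10)
        assert a.mean_cost != c.mean_cost

    def test_se_is_sd_over_sqrt_n(self, base):
        n, cap = 400, max_months(40.0)
        uniforms = np.random.default_rng(77).random((n, cap))
        res = _simulate_cohort(base, "NT", uniforms, 40.0)
        s = h.simulate_arm(base, "NT", n=n, seed=77)
        assert s.se_qaly == pytest.approx(np.std(res["qaly"], ddof=1) / np.sqrt(n))

    def test_th_relapse_fraction_small(self, base_microsim):
        assert base_microsim["TH"].frac_relapsed < 0.10

    def test_quit_split_roughly_70_30(self, base):
        """The published 70/30 high/low-toxicity quit split emerges from the
        competing quit probabilities rather than being imposed."""
        cap = max_months(40.0)
        uniforms = np.random.default_rng(4).random((40_000, cap))
        res = _simulate_cohort(base, "TH", uniforms, 40.0)
        kinds = res["quit_kind"][res["ever_quit"]]
        frac_high = np.mean(kinds == 1)
        assert 0.65 < frac_high < 0.75


class TestCohortTrace:
    def test_occupancy_rows_sum_to_one(self, base):
        tr = h.cohort_trace(base, "TH")
        sums = tr.occupancy.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-10)

    def test_dead_occupancy_nondecreasing(self, base):
        for arm in h.ARM_IDS:
            tr = h.cohort_trace(base, arm)
            dead = tr.occupancy[:, int(State.DEAD)]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_two_state_geometric_closed_form(self, base_copy):
        """Constant monthly death probability p, nothing else: expected alive
        months truncated at M is (1 - (1-p)^M) / p, exact."""
        p = 0.01
        for arm in h.ARM_IDS:
            for b in base_copy.arms[arm].mortality.by_band:
                base_copy.arms[arm].mortality.by_band[b] = p
            base_copy.arms[arm].mortality.early_override_months = None
            base_copy.arms[arm].mortality.early_override_by_band = None
            for band in base_copy.arms[arm].relapse.bands:
                band.monthly_prob = 0.0
            base_copy.arms[arm].relapse.post_quit_ceiling = 0.0
            if base_copy.arms[arm].toxicity:
                base_copy.arms[arm].toxicity.p_high_event = 0.0
                base_copy.arms[arm].toxicity.p_low_event = 0.0
                base_copy.arms[arm].toxicity.p_quit_high = 0.0
                base_copy.arms[arm].toxicity.p_quit_low = 0.0
        M = max_months(40.0)
        tr = h.cohort_trace(base_copy, "NT")
        expected_months = (1 - (1 - p) ** M) / p
        assert tr.expected_outcome.ly == pytest.approx(expected_months / 12, abs=1e-9)

    def test_trace_matches_microsim_base_case(self, base_microsim, base_trace):
        for arm in h.ARM_IDS:
            ms, tr = base_microsim[arm], base_trace[arm]
            assert abs(ms.mean_cost - tr.mean_cost) < 3 * ms.se_cost
            assert abs(ms.mean_qaly - tr.mean_qaly) < 3 * ms.se_qaly
            assert abs(ms.mean_ly - tr.mean_ly) < 3 * ms.se_ly

    def test_doubling_relapse_weakly_decreases_qaly_and_ly(self, base):
        worse = copy.deepcopy(base)
        for arm in h.ARM_IDS:
            for band in worse.arms[arm].relapse.bands:
                band.monthly_prob = min(1.0, band.monthly_prob * 2)
        for arm in h.ARM_IDS:
            a = h.trace_summary(base, arm)
            b = h.trace_summary(worse, arm)
            assert b.mean_qaly <= a.mean_qaly + 1e-9
            assert b.mean_ly <= a.mean_ly + 1e-9
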