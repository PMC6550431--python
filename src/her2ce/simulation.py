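"""Patient-level Monte-Carlo engine and its deterministic expectation oracle.

Two implementations of the same monthly process live here and are held to
agree in tests:

* :func:`simulate_patient` — a readable scalar walk through
  :func:`her2ce.transitions.transition_events`, producing an annotated
  :class:`PatientTrajectory`;
* :func:`simulate_arm` — a vectorized engine that advances all patients of
  an arm month by month from a shared matrix of uniform draws.  Because the
  matrix depends only on ``(seed, n)``, running two arms with the same seed
  pairs patient ``i``'s randomness across arms (common random numbers),
  which shrinks the variance of incremental cost/QALY estimates;
* :func:`cohort_trace` — exact forward propagation of state-occupancy
  probabilities over an expanded state space (quit cohorts are tracked per
  quit month so the post-quit relapse ramp is handled exactly).  The trace
  is the expectation of the microsimulation and serves as its oracle.

Accounting conventions: events resolve at end of month; the month in which
the patient is dead accrues the one-off death cost (discounted at that
month) and nothing else; a relapse entry month additionally accrues the full
re-treatment course cost; life-years are undiscounted while costs and QALYs
are discounted at the annual rate with ``df(m) = (1 + r)^(-(m - 1)/12)``.
State utilities are multiplied by the attained-band baseline utility (the
age-specific quality of life without treatment); the relapse-free weight is
``u_after / 0.90`` times that baseline, so the base case corresponds to a
full return to the pre-treatment baseline after therapy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .economics import discount_factor
from .parameters import MAX_AGE_YEARS, RELAPSE_FREE_UTILITY_ANCHOR, ParameterSet
from .transitions import (
    Event,
    PatientContext,
    State,
    attained_age_band,
    post_quit_ramp,
    transition_events,
)

logger = logging.getLogger(__name__)

_RESIDUAL_WARN = 1e-6
_RESIDUAL_MATERIAL = 1e-3


@dataclass
class PatientTrajectory:
    """One simulated life: monthly states plus tagged events."""

    states: list[tuple[int, State]]
    events: list[tuple[int, str]]
    retreated: bool = False
    forced_termination: bool = False


@dataclass
class Outcome:
    disc_cost: float
    disc_qaly: float
    ly: float
    months_alive: int


@dataclass
class ArmSummary:
    arm_id: str
    n: int
    mean_cost: float
    mean_qaly: float
    mean_ly: float
    se_cost: float
    se_qaly: float
    se_ly: float
    frac_relapsed: float = 0.0
    frac_quit: float = 0.0
    n_forced: int = 0


@dataclass
class CohortTrace:
    """Deterministic expectation of the microsimulation."""

    occupancy: np.ndarray  # months x 6 states, occupancy at each month
    expected_outcome: Outcome
    frac_relapsed: float
    residual_alive: float
    months: int = field(default=0)

    def __post_init__(self) -> None:
        self.months = self.occupancy.shape[0]


def max_months(start_age: float) -> int:
    """Months until the hard age cap that guarantees termination."""
    return int(math.ceil((MAX_AGE_YEARS - start_age) * 12))


# ---------------------------------------------------------------------------
# Scalar engine

def simulate_patient(
    pset: ParameterSet,
    arm_id: str,
    rng: Union[np.random.Generator, np.ndarray],
    start_age: Optional[float] = None,
) -> PatientTrajectory:
    """Simulate one patient until death (or the hard age cap).

    ``rng`` is either a numpy Generator or a pre-drawn vector of uniforms,
    one per month (the vectorized engine consumes the identical stream, so a
    shared vector reproduces a patient across engines bit for bit).
    """
    if start_age is None:
        start_age = pset.start_age
    uniforms = rng if isinstance(rng, np.ndarray) else None
    cap = max_months(start_age)
    ctx = PatientContext(arm_id=arm_id, current_state=State.ADJUVANT, month=1, start_age=start_age)
    tm = pset.arms[arm_id].treatment_months
    states: list[tuple[int, State]] = [(1, State.ADJUVANT)]
    events: list[tuple[int, str]] = []
    retreated = False
    forced = False
    while ctx.current_state != State.DEAD:
        m = ctx.month
        if m > cap:
            forced = True
            states[-1] = (m, State.DEAD)  # replace the capped month with death
            events.append((m, Event.DEATH.value))
            break
        u = uniforms[m - 1] if uniforms is not None else rng.random()
        cum = 0.0
        for event, nxt, p in transition_events(pset, ctx):
            cum += p
            if u < cum:
                break
        # update history flags
        if event in (Event.QUIT_HIGH, Event.QUIT_LOW):
            ctx.quit_pending = True
        if ctx.current_state in (State.LOW_TOX, State.HIGH_TOX) and nxt != State.DEAD:
            if ctx.quit_pending and m + 1 <= tm:
                ctx.quit = True
                ctx.quit_month = m + 1
            ctx.quit_pending = False
        if event == Event.RELAPSE:
            ctx.relapsed_before = True
            retreated = True
        if event != Event.STAY:
            events.append((m + 1, event.value))
        ctx.current_state = nxt
        ctx.month = m + 1
        states.append((m + 1, nxt))
    return PatientTrajectory(states=states, events=events, retreated=retreated, forced_termination=forced)


def score_trajectory(
    traj: PatientTrajectory,
    pset: ParameterSet,
    arm_id: str,
    start_age: Optional[float] = None,
) -> Outcome:
    """Accrue discounted cost, discounted QALYs and undiscounted life-years."""
    if start_age is None:
        start_age = pset.start_age
    r = pset.discount_rate_annual
    costs = pset.costs
    utils = pset.utilities
    treat = costs.treatment_monthly[arm_id]
    tm = pset.arms[arm_id].treatment_months
    cost = qaly = ly = 0.0
    months_alive = 0
    prev_state: Optional[State] = None
    for m, s in traj.states:
        df = discount_factor(r, m)
        if s == State.DEAD:
            cost += costs.death_once * df
            break
        band = attained_age_band(start_age, m)
        baseline = utils.baseline_by_band[band.label]
        if s == State.ADJUVANT:
            c, u = treat, utils.therapy[arm_id]
        elif s == State.LOW_TOX:
            c, u = treat + costs.low_tox, utils.low_tox
        elif s == State.HIGH_TOX:
            c, u = treat + costs.high_tox, utils.high_tox
        elif s == State.RELAPSE_FREE:
            c = costs.relapse_free_monthly[band.label]
            u = utils.relapse_free_post_therapy / RELAPSE_FREE_UTILITY_ANCHOR
        else:  # RELAPSE
            c, u = costs.relapse_free_monthly[band.label], utils.relapse
            if prev_state != State.RELAPSE:
                cost += treat * tm * df  # one-time re-treatment course
        cost += c * df
        qaly += u * baseline / 12.0 * df
        ly += 1.0 / 12.0
        months_alive += 1
        prev_state = s
    return Outcome(disc_cost=cost, disc_qaly=qaly, ly=ly, months_alive=months_alive)


# ---------------------------------------------------------------------------
# Vectorized engine

def _month_grids(pset: ParameterSet, arm_id: str, start_age: float, cap: int):
    """Per-month scalar inputs, precomputed as arrays indexed by month-1."""
    arm = pset.arms[arm_id]
    months = np.arange(1, cap + 2)
    df = (1.0 + pset.discount_rate_annual) ** (-(months - 1) / 12.0)
    bands = [attained_age_band(start_age, int(m)) for m in months]
    mort = np.array([arm.mortality.probability(b.label, int(m)) for m, b in zip(months, bands)])
    sched = np.array([arm.relapse.value_at_month(int(m)) for m in months])
    sched_nt = np.array([pset.arms["NT"].relapse.value_at_month(int(m)) for m in months])
    hm = (
        None
        if pset.effect_horizon_years is None
        else int(round(12 * pset.effect_horizon_years))
    )
    r_nq = np.where(months <= arm.treatment_months, 0.0, sched)
    if hm is not None:
        r_nq = np.where(months > hm, np.where(months <= arm.treatment_months, 0.0, sched_nt), r_nq)
    rf_cost = np.array([pset.costs.relapse_free_monthly[b.label] for b in bands])
    baseline = np.array([pset.utilities.baseline_by_band[b.label] for b in bands])
    return df, mort, sched, sched_nt, r_nq, rf_cost, baseline


def _simulate_cohort(
    pset: ParameterSet,
    arm_id: str,
    uniforms: np.ndarray,
    start_age: float,
) -> dict:
    """Advance ``n`` patients through the monthly process; per-patient outcomes."""
    n, n_months = uniforms.shape
    arm = pset.arms[arm_id]
    tm = arm.treatment_months
    cap = n_months
    df, mort, sched, sched_nt, r_nq, rf_cost, baseline = _month_grids(pset, arm_id, start_age, cap)
    costs, utils = pset.costs, pset.utilities
    treat = costs.treatment_monthly[arm_id]
    retreat = treat * tm
    u_ther = utils.therapy[arm_id]
    ceiling = arm.relapse.post_quit_ceiling
    p_dr = arm.p_death_from_relapse
    if arm.toxicity is not None:
        ph, pqh, pl, pql = (
            arm.toxicity.p_high_event,
            arm.toxicity.p_quit_high,
            arm.toxicity.p_low_event,
            arm.toxicity.p_quit_low,
        )
    else:
        ph = pqh = pl = pql = 0.0

    st = np.full(n, int(State.ADJUVANT), dtype=np.int8)
    quit_ = np.zeros(n, dtype=bool)
    qp = np.zeros(n, dtype=bool)  # quit pending (inside a toxicity month)
    qp_kind = np.zeros(n, dtype=np.int8)  # 1 = via high toxicity, 2 = via low
    quit_kind = np.zeros(n, dtype=np.int8)
    quit_month = np.zeros(n, dtype=np.int32)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    ly = np.zeros(n)
    months_alive = np.zeros(n, dtype=np.int32)
    ever_relapsed = np.zeros(n, dtype=bool)

    for m in range(1, cap + 1):
        alive = st != int(State.DEAD)
        if not alive.any():
            break
        i = m - 1
        dfm, pd = df[i], mort[i]
        bl = baseline[i]
        # --- accrual for the occupied month ---
        c_state = np.zeros(n)
        u_state = np.zeros(n)
        is_adj = st == int(State.ADJUVANT)
        is_lt = st == int(State.LOW_TOX)
        is_ht = st == int(State.HIGH_TOX)
        is_rf = st == int(State.RELAPSE_FREE)
        is_rel = st == int(State.RELAPSE)
        c_state[is_adj] = treat
        u_state[is_adj] = u_ther
        c_state[is_lt] = treat + costs.low_tox
        u_state[is_lt] = utils.low_tox
        c_state[is_ht] = treat + costs.high_tox
        u_state[is_ht] = utils.high_tox
        c_state[is_rf] = rf_cost[i]
        u_state[is_rf] = utils.relapse_free_post_therapy / RELAPSE_FREE_UTILITY_ANCHOR
        c_state[is_rel] = rf_cost[i]
        u_state[is_rel] = utils.relapse
        cost[alive] += c_state[alive] * dfm
        qaly[alive] += u_state[alive] * bl / 12.0 * dfm
        ly[alive] += 1.0 / 12.0
        months_alive[alive] += 1

        # --- transitions (single uniform per patient-month) ---
        u = uniforms[:, i]
        df_next = df[i + 1] if i + 1 < len(df) else df[-1]
        new_st = st.copy()
        new_qp = np.zeros(n, dtype=bool)
        new_qp_kind = np.zeros(n, dtype=np.int8)

        if is_adj.any():
            died = is_adj & (u < pd)
            if m < tm and arm.toxicity is not None:
                c1 = pd + ph
                c2 = c1 + pqh
                c3 = c2 + pl
                c4 = c3 + pql
                to_ht = is_adj & (u >= pd) & (u < c2)
                to_lt = is_adj & (u >= c2) & (u < c4)
                pend_h = is_adj & (u >= c1) & (u < c2)
                pend_l = is_adj & (u >= c3) & (u < c4)
                new_st[to_ht] = int(State.HIGH_TOX)
                new_st[to_lt] = int(State.LOW_TOX)
                new_qp |= pend_h | pend_l
                new_qp_kind[pend_h] = 1
                new_qp_kind[pend_l] = 2
                stay = is_adj & (u >= c4)
            else:
                stay = is_adj & (u >= pd)
            if m < tm:
                new_st[stay] = int(State.ADJUVANT)
            else:
                new_st[stay] = int(State.RELAPSE_FREE)
            new_st[died] = int(State.DEAD)
            cost[died] += costs.death_once * df_next

        is_tox = is_lt | is_ht
        if is_tox.any():
            died = is_tox & (u < pd)
            surv = is_tox & ~died
            if m + 1 <= tm:
                resume = surv & ~qp
                quitting = surv & qp
                new_st[resume] = int(State.ADJUVANT)
                new_st[quitting] = int(State.RELAPSE_FREE)
                quit_[quitting] = True
                quit_kind[quitting] = qp_kind[quitting]
                quit_month[quitting] = m + 1
            else:
                new_st[surv] = int(State.RELAPSE_FREE)  # calendar over: completed
            new_st[died] = int(State.DEAD)
            cost[died] += costs.death_once * df_next

        if is_rf.any():
            p_rel = np.full(n, r_nq[i])
            qmask = is_rf & quit_
            if qmask.any():
                if m > tm:
                    p_rel[qmask] = sched_nt[i]  # untreated schedule after the ramp
                else:
                    qm = quit_month[qmask]
                    v0 = sched[qm - 1]
                    denom = np.maximum(tm - qm, 1)
                    frac = np.clip((m - qm) / denom, 0.0, 1.0)
                    p_rel[qmask] = np.where(qm >= tm, ceiling, v0 + (ceiling - v0) * frac)
            died = is_rf & (u < pd)
            rel = is_rf & (u >= pd) & (u < pd + p_rel)
            new_st[died] = int(State.DEAD)
            new_st[rel] = int(State.RELAPSE)
            cost[died] += costs.death_once * df_next
            cost[rel] += retreat * df_next
            ever_relapsed |= rel

        if is_rel.any():
            died = is_rel & (u < min(1.0, p_dr + pd))
            new_st[died] = int(State.DEAD)
            cost[died] += costs.death_once * df_next

        st = new_st
        qp = new_qp
        qp_kind = new_qp_kind

    # hard age cap: force-terminate any survivors
    alive = st != int(State.DEAD)
    n_forced = int(alive.sum())
    if n_forced:
        cost[alive] += costs.death_once * df[-1]
        logger.info("%s: %d trajectories force-terminated at the age cap", arm_id, n_forced)

    return {
        "cost": cost,
        "qaly": qaly,
        "ly": ly,
        "months_alive": months_alive,
        "ever_relapsed": ever_relapsed,
        "ever_quit": quit_,
        "quit_kind": quit_kind,
        "n_forced": n_forced,
    }


def simulate_arm(
    pset: ParameterSet,
    arm_id: str,
    n: Optional[int] = None,
    seed: int = 0,
    start_age: Optional[float] = None,
) -> ArmSummary:
    """Monte-Carlo summary for one arm.

    Patient ``i`` consumes row ``i`` of a uniform matrix drawn from ``seed``
    alone, so every arm simulated with the same ``(n, seed)`` shares patient-
    level randomness (common random numbers across strategies).
    """
    if n is None:
        n = pset.n_patients
    if start_age is None:
        start_age = pset.start_age
    cap = max_months(start_age)
    uniforms = np.random.default_rng(seed).random((n, cap))
    res = _simulate_cohort(pset, arm_id, uniforms, start_age)

    def se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else 0.0

    return ArmSummary(
        arm_id=arm_id,
        n=n,
        mean_cost=float(res["cost"].mean()),
        mean_qaly=float(res["qaly"].mean()),
        mean_ly=float(res["ly"].mean()),
        se_cost=se(res["cost"]),
        se_qaly=se(res["qaly"]),
        se_ly=se(res["ly"]),
        frac_relapsed=float(res["ever_relapsed"].mean()),
        frac_quit=float(res["ever_quit"].mean()),
        n_forced=res["n_forced"],
    )


# ---------------------------------------------------------------------------
# Deterministic cohort trace (expectation oracle)

def cohort_trace(
    pset: ParameterSet,
    arm_id: str,
    max_months_: Optional[int] = None,
    start_age: Optional[float] = None,
) -> CohortTrace:
    """Exact state-occupancy propagation with expected outcome accrual.

    The state space is expanded so every transition probability is a
    deterministic function of (composite state, month): toxicity months are
    split by whether they end in a quit, and relapse-free quitters are
    tracked per quit month while the post-quit ramp is still rising.
    """
    if start_age is None:
        start_age = pset.start_age
    cap = max_months_ if max_months_ is not None else max_months(start_age)
    arm = pset.arms[arm_id]
    tm = arm.treatment_months
    df, mort, sched, sched_nt, r_nq, rf_cost, baseline = _month_grids(pset, arm_id, start_age, cap)
    costs, utils = pset.costs, pset.utilities
    treat = costs.treatment_monthly[arm_id]
    retreat = treat * tm
    ceiling = arm.relapse.post_quit_ceiling
    p_dr = arm.p_death_from_relapse
    if arm.toxicity is not None:
        ph, pqh, pl, pql = (
            arm.toxicity.p_high_event,
            arm.toxicity.p_quit_high,
            arm.toxicity.p_low_event,
            arm.toxicity.p_quit_low,
        )
    else:
        ph = pqh = pl = pql = 0.0

    # composite indices
    ADJ, TOXH, TOXL, TOXHQ, TOXLQ, RF, REL, DEAD = range(8)
    RFQ0 = 8  # RFQ0 + (qm - 1) = relapse-free, quit at month qm
    n_states = RFQ0 + tm
    mass = np.zeros(n_states)
    mass[ADJ] = 1.0

    occupancy = np.zeros((cap, len(State)))
    cost = qaly = ly = 0.0
    relapse_inflow_total = 0.0

    c_vec = np.zeros(n_states)
    u_vec = np.zeros(n_states)

    for m in range(1, cap + 1):
        i = m - 1
        dfm, pd, bl = df[i], mort[i], baseline[i]
        # occupancy snapshot aggregated to the six observable states
        occupancy[i, int(State.ADJUVANT)] = mass[ADJ]
        occupancy[i, int(State.HIGH_TOX)] = mass[TOXH] + mass[TOXHQ]
        occupancy[i, int(State.LOW_TOX)] = mass[TOXL] + mass[TOXLQ]
        occupancy[i, int(State.RELAPSE_FREE)] = mass[RF] + mass[RFQ0:].sum()
        occupancy[i, int(State.RELAPSE)] = mass[REL]
        occupancy[i, int(State.DEAD)] = mass[DEAD]

        # expected accrual at month m
        c_vec[:] = 0.0
        u_vec[:] = 0.0
        c_vec[ADJ], u_vec[ADJ] = treat, utils.therapy[arm_id]
        c_vec[TOXH] = c_vec[TOXHQ] = treat + costs.high_tox
        u_vec[TOXH] = u_vec[TOXHQ] = utils.high_tox
        c_vec[TOXL] = c_vec[TOXLQ] = treat + costs.low_tox
        u_vec[TOXL] = u_vec[TOXLQ] = utils.low_tox
        c_vec[RF] = c_vec[REL] = rf_cost[i]
        c_vec[RFQ0:] = rf_cost[i]
        u_vec[RF] = utils.relapse_free_post_therapy / RELAPSE_FREE_UTILITY_ANCHOR
        u_vec[RFQ0:] = utils.relapse_free_post_therapy / RELAPSE_FREE_UTILITY_ANCHOR
        u_vec[REL] = utils.relapse
        alive_mass = mass.copy()
        alive_mass[DEAD] = 0.0
        cost += float(alive_mass @ c_vec) * dfm
        qaly += float(alive_mass @ u_vec) * bl / 12.0 * dfm
        ly += float(alive_mass.sum()) / 12.0

        # transitions
        new = np.zeros(n_states)
        df_next = df[i + 1] if i + 1 < len(df) else df[-1]
        death_in = 0.0
        relapse_in = 0.0

        a = mass[ADJ]
        if a > 0:
            death_in += a * pd
            rest = a * (1 - pd)
            if m < tm and arm.toxicity is not None:
                new[TOXH] += a * ph
                new[TOXHQ] += a * pqh
                new[TOXL] += a * pl
                new[TOXLQ] += a * pql
                stay = a * (1 - pd - ph - pqh - pl - pql)
                new[ADJ] += stay
            elif m < tm:
                new[ADJ] += rest
            else:
                new[RF] += rest

        for tox_idx, quit_flag in ((TOXH, False), (TOXL, False), (TOXHQ, True), (TOXLQ, True)):
            t = mass[tox_idx]
            if t > 0:
                death_in += t * pd
                surv = t * (1 - pd)
                if m + 1 <= tm:
                    if quit_flag:
                        new[RFQ0 + m] += surv  # quit effective at month m+1
                    else:
                        new[ADJ] += surv
                else:
                    new[RF] += surv

        rfm = mass[RF]
        if rfm > 0:
            p_rel = r_nq[i]
            death_in += rfm * pd
            relapse_in += rfm * p_rel
            new[RF] += rfm * (1 - pd - p_rel)

        for qm in range(1, tm + 1):
            qmass = mass[RFQ0 + qm - 1]
            if qmass > 0:
                if m > tm:
                    p_rel = sched_nt[i]
                else:
                    p_rel = post_quit_ramp(sched[qm - 1], qm, m, tm, ceiling)
                death_in += qmass * pd
                relapse_in += qmass * p_rel
                new[RFQ0 + qm - 1] += qmass * (1 - pd - p_rel)

        relm = mass[REL]
        if relm > 0:
            p_dr_m = min(1.0, p_dr + pd)
            death_in += relm * p_dr_m
            new[REL] += relm * (1 - p_dr_m)

        new[REL] += relapse_in
        new[DEAD] = mass[DEAD] + death_in
        cost += death_in * costs.death_once * df_next
        cost += relapse_in * retreat * df_next
        relapse_inflow_total += relapse_in
        mass = new

    residual = float(mass.sum() - mass[DEAD])
    if residual > _RESIDUAL_MATERIAL:
        logger.warning("%s trace: residual alive mass %.3e at the age cap", arm_id, residual)
    elif residual > _RESIDUAL_WARN:
        logger.info("%s trace: residual alive mass %.3e at the age cap", arm_id, residual)
    cost += residual * costs.death_once * df[-1]

    return CohortTrace(
        occupancy=occupancy,
        expected_outcome=Outcome(disc_cost=cost, disc_qaly=qaly, ly=ly, months_alive=0),
        frac_relapsed=relapse_inflow_total,
        residual_alive=residual,
    )


def trace_summary(
    pset: ParameterSet,
    arm_id: str,
    start_age: Optional[float] = None,
) -> ArmSummary:
    """Cohort-trace expectations wrapped as an ArmSummary (zero SEs)."""
    tr = cohort_trace(pset, arm_id, start_age=start_age)
    o = tr.expected_outcome
    return ArmSummary(
        arm_id=arm_id,
        n=0,
        mean_cost=o.disc_cost,
        mean_qaly=o.disc_qaly,
        mean_ly=o.ly,
        se_cost=0.0,
        se_qaly=0.0,
        se_ly=0.0,
        frac_relapsed=tr.frac_relapsed,
    )
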