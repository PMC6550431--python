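"""Monthly transition kernel over the six health states.

States: adjuvant therapy (1), low toxicity (2), hospitalization due to high
toxicity (3), alive relapse-free (4), alive with relapse (5), dead (6).
A transition drawn during month ``m`` determines the state occupied in month
``m + 1``.  The kernel is time-, age-, arm- and history-dependent:

* mortality follows the attained age band (patients start at the lower bound
  of their start band and age one month per cycle); the NT arm carries an
  elevated override during the first 24 months;
* relapse is impossible while on treatment; after completion it follows the
  arm's banded schedule (years since treatment start); patients who quit
  ramp linearly from the scheduled value at the quit month up to a
  discontinuation spike of 0.0126/month at the planned treatment end, and
  follow the untreated schedule thereafter;
* when a finite effect horizon is set, relapse probabilities revert to the
  untreated (NT) schedule beyond ``12 x horizon`` months;
* toxicity states last exactly one month, after which the patient resumes
  therapy, or — if the event was a quit — leaves to relapse-free;
* from the relapse state the only exit is death, at the arm's excess
  death-from-relapse probability added to the age-specific background
  mortality.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .parameters import (
    AGE_BANDS,
    AgeBand,
    ArmParameters,
    ParameterSet,
)


class State(enum.IntEnum):
    ADJUVANT = 0
    LOW_TOX = 1
    HIGH_TOX = 2
    RELAPSE_FREE = 3
    RELAPSE = 4
    DEAD = 5


class Event(enum.Enum):
    DEATH = "death"
    TOX_HIGH = "tox_high"
    QUIT_HIGH = "quit_high"
    TOX_LOW = "tox_low"
    QUIT_LOW = "quit_low"
    RELAPSE = "relapse"
    STAY = "stay"


@dataclass
class PatientContext:
    """Everything the kernel needs to know about one patient at one month."""

    arm_id: str
    current_state: State
    month: int  # 1-based month index from simulation start
    start_age: float
    quit: bool = False
    quit_month: Optional[int] = None
    quit_pending: bool = False  # set while in a toxicity month that ends in a quit
    relapsed_before: bool = False

    def __post_init__(self) -> None:
        if self.month < 1:
            raise ValueError("month is 1-based")
        if self.quit and self.quit_month is None:
            raise ValueError("quit_month required when quit is set")


def attained_age_band(start_age: float, month: int, bands=AGE_BANDS) -> AgeBand:
    """Band containing the attained age ``start_age + (month - 1) / 12``."""
    age = start_age + (month - 1) / 12.0
    for b in bands:
        if b.contains(age):
            return b
    return bands[-1]


def background_mortality(pset: ParameterSet, arm_id: str, band: AgeBand, month: int) -> float:
    """All-cause monthly death probability outside the relapse state."""
    return pset.arms[arm_id].mortality.probability(band.label, month)


def post_quit_ramp(
    schedule_value_at_quit: float,
    quit_month: int,
    month: int,
    treatment_months: int,
    ceiling: float,
) -> float:
    """Linear rise from the scheduled value at quit to the ceiling at the
    planned treatment end.

    Applies through the planned treatment calendar; beyond it quitters
    follow the untreated relapse schedule (see :func:`relapse_probability`),
    the ceiling being a discontinuation spike rather than a lifelong hazard.
    """
    if month < quit_month:
        raise ValueError("month precedes quit_month")
    if quit_month >= treatment_months or month >= treatment_months:
        return ceiling
    frac = (month - quit_month) / (treatment_months - quit_month)
    return schedule_value_at_quit + (ceiling - schedule_value_at_quit) * frac


def _horizon_months(pset: ParameterSet) -> Optional[int]:
    h = pset.effect_horizon_years
    return None if h is None else int(round(12 * h))


def relapse_probability(pset: ParameterSet, ctx: PatientContext) -> float:
    """Monthly relapse probability for a patient in therapy or relapse-free."""
    if ctx.current_state not in (State.ADJUVANT, State.RELAPSE_FREE):
        raise ValueError(f"relapse probability undefined for state {ctx.current_state.name}")
    arm = pset.arms[ctx.arm_id]
    if not ctx.quit and ctx.month <= arm.treatment_months:
        return 0.0  # no relapse during the treatment period
    if ctx.quit:
        if ctx.month > arm.treatment_months:
            # treatment benefit lost: untreated schedule from the planned end
            return pset.arms["NT"].relapse.value_at_month(ctx.month)
        v0 = arm.relapse.value_at_month(ctx.quit_month)
        return post_quit_ramp(
            v0, ctx.quit_month, ctx.month, arm.treatment_months, arm.relapse.post_quit_ceiling
        )
    hm = _horizon_months(pset)
    if hm is not None and ctx.month > hm:
        return pset.arms["NT"].relapse.value_at_month(ctx.month)
    return arm.relapse.value_at_month(ctx.month)


def transition_events(pset: ParameterSet, ctx: PatientContext) -> list[tuple[Event, State, float]]:
    """Ordered competing-event decomposition of the month's transition.

    The order is fixed (death, high-tox, quit-high, low-tox, quit-low,
    relapse, stay) so that a single uniform draw resolves the month
    identically in the scalar and vectorized engines (common random numbers).
    """
    if ctx.current_state == State.DEAD:
        raise ValueError("no transition from the dead state")
    arm: ArmParameters = pset.arms[ctx.arm_id]
    tm = arm.treatment_months
    band = attained_age_band(ctx.start_age, ctx.month)
    m = ctx.month
    out: list[tuple[Event, State, float]] = []

    if ctx.current_state == State.ADJUVANT:
        p_death = background_mortality(pset, ctx.arm_id, band, m)
        out.append((Event.DEATH, State.DEAD, p_death))
        if m < tm and arm.toxicity is not None:
            tox = arm.toxicity
            out.append((Event.TOX_HIGH, State.HIGH_TOX, tox.p_high_event))
            out.append((Event.QUIT_HIGH, State.HIGH_TOX, tox.p_quit_high))
            out.append((Event.TOX_LOW, State.LOW_TOX, tox.p_low_event))
            out.append((Event.QUIT_LOW, State.LOW_TOX, tox.p_quit_low))
        stay_state = State.ADJUVANT if m < tm else State.RELAPSE_FREE
        residual = 1.0 - sum(p for _, _, p in out)
        if residual < 0:
            raise ValueError(f"therapy-state event probabilities exceed 1 at month {m}")
        out.append((Event.STAY, stay_state, residual))
        return out

    if ctx.current_state in (State.LOW_TOX, State.HIGH_TOX):
        p_death = background_mortality(pset, ctx.arm_id, band, m)
        out.append((Event.DEATH, State.DEAD, p_death))
        if ctx.quit_pending and m + 1 <= tm:
            nxt = State.RELAPSE_FREE  # the quit takes effect next month
        elif m + 1 <= tm:
            nxt = State.ADJUVANT
        else:
            nxt = State.RELAPSE_FREE  # calendar over: therapy complete
        out.append((Event.STAY, nxt, 1.0 - p_death))
        return out

    if ctx.current_state == State.RELAPSE_FREE:
        p_death = background_mortality(pset, ctx.arm_id, band, m)
        p_rel = relapse_probability(pset, ctx)
        if p_death + p_rel > 1.0:
            raise ValueError("relapse-free event probabilities exceed 1")
        out.append((Event.DEATH, State.DEAD, p_death))
        out.append((Event.RELAPSE, State.RELAPSE, p_rel))
        out.append((Event.STAY, State.RELAPSE_FREE, 1.0 - p_death - p_rel))
        return out

    # RELAPSE: excess cancer mortality on top of age-specific background
    p_death = min(1.0, arm.p_death_from_relapse + background_mortality(pset, ctx.arm_id, band, m))
    out.append((Event.DEATH, State.DEAD, p_death))
    out.append((Event.STAY, State.RELAPSE, 1.0 - p_death))
    return out


def transition_distribution(pset: ParameterSet, ctx: PatientContext) -> dict[State, float]:
    """Distribution of next month's state (events aggregated by destination)."""
    dist: dict[State, float] = {}
    for _, state, p in transition_events(pset, ctx):
        dist[state] = dist.get(state, 0.0) + p
    return dist
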