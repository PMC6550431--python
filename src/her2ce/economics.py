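"""Discounting, incremental cost-effectiveness ratios and dominance.

ICERs divide incremental discounted cost by incremental discounted QALYs
(or by incremental undiscounted life-years for the cost-per-LY variant).
A strategy is strictly dominated when another is both cheaper and more
effective; extended dominance removes strategies whose sequential ICER
exceeds that of the next strategy up the cost-ordered frontier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .simulation import ArmSummary

TAG_RATIO = "ratio"
TAG_DOMINANT = "dominant"
TAG_DOMINATED = "dominated"
TAG_EXTENDED_DOMINATED = "extended_dominated"
TAG_DEGENERATE = "degenerate"


def discount_factor(annual_rate: float, month: int) -> float:
    """``(1 + r) ** (-(month - 1) / 12)`` — month 1 is undiscounted."""
    if month < 1:
        raise ValueError("month is 1-based")
    if annual_rate < 0:
        raise ValueError("negative discount rate")
    return (1.0 + annual_rate) ** (-(month - 1) / 12.0)


@dataclass
class ICERResult:
    comparator: str
    reference: str
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: Optional[float]
    icer_per_ly: Optional[float]
    tag: str

    def display_icer(self) -> str:
        if self.tag == TAG_RATIO:
            return f"{self.icer_per_qaly:,.0f} / QALY"
        return self.tag


def icer(a: "ArmSummary", b: "ArmSummary") -> ICERResult:
    """Incremental comparison of ``a`` (comparator) against ``b`` (reference)."""
    if a.arm_id == b.arm_id:
        raise ValueError("comparator and reference must differ")
    dc = a.mean_cost - b.mean_cost
    dq = a.mean_qaly - b.mean_qaly
    dl = a.mean_ly - b.mean_ly
    per_qaly = per_ly = None
    if dq == 0.0 and dc == 0.0:
        tag = TAG_DEGENERATE
    elif dc <= 0.0 and dq >= 0.0:
        tag = TAG_DOMINANT  # cheaper and at least as effective
    elif dc >= 0.0 and dq <= 0.0:
        tag = TAG_DOMINATED
    else:
        tag = TAG_RATIO
        per_qaly = dc / dq
        per_ly = dc / dl if dl != 0 else None
    return ICERResult(
        comparator=a.arm_id,
        reference=b.arm_id,
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dl,
        icer_per_qaly=per_qaly,
        icer_per_ly=per_ly,
        tag=tag,
    )


@dataclass
class FrontierEntry:
    arm_id: str
    mean_cost: float
    mean_qaly: float
    tag: str  # "frontier" / dominance tag
    icer_vs_previous: Optional[float] = None  # sequential ICER along the frontier


@dataclass
class FrontierReport:
    entries: list[FrontierEntry]

    @property
    def frontier(self) -> list[str]:
        return [e.arm_id for e in self.entries if e.tag == "frontier"]

    def tag_of(self, arm_id: str) -> str:
        for e in self.entries:
            if e.arm_id == arm_id:
                return e.tag
        raise KeyError(arm_id)


def rank_strategies(summaries: Sequence["ArmSummary"]) -> FrontierReport:
    """Cost-ordered efficiency frontier with strict and extended dominance."""
    if not summaries:
        raise ValueError("need at least one strategy")
    order = sorted(summaries, key=lambda s: (s.mean_cost, -s.mean_qaly))
    tags: dict[str, str] = {}
    # strict dominance: some cheaper (or equal-cost) strategy is at least as effective
    for s in order:
        for t in order:
            if t is s:
                continue
            if t.mean_cost <= s.mean_cost and t.mean_qaly >= s.mean_qaly and (
                t.mean_cost < s.mean_cost or t.mean_qaly > s.mean_qaly
            ):
                tags[s.arm_id] = TAG_DOMINATED
                break
    remaining = [s for s in order if s.arm_id not in tags]
    # extended dominance: sequential ICERs along the frontier must increase
    changed = True
    while changed and len(remaining) > 2:
        changed = False
        for k in range(1, len(remaining) - 1):
            lo, mid, hi = remaining[k - 1], remaining[k], remaining[k + 1]
            icer_mid = (mid.mean_cost - lo.mean_cost) / (mid.mean_qaly - lo.mean_qaly)
            icer_hi = (hi.mean_cost - mid.mean_cost) / (hi.mean_qaly - mid.mean_qaly)
            if icer_mid > icer_hi:
                tags[mid.arm_id] = TAG_EXTENDED_DOMINATED
                remaining.pop(k)
                changed = True
                break
    entries = []
    prev = None
    for s in order:
        tag = tags.get(s.arm_id, "frontier")
        icer_prev = None
        if tag == "frontier" and prev is not None:
            dq = s.mean_qaly - prev.mean_qaly
            icer_prev = (s.mean_cost - prev.mean_cost) / dq if dq != 0 else None
        entries.append(
            FrontierEntry(
                arm_id=s.arm_id,
                mean_cost=s.mean_cost,
                mean_qaly=s.mean_qaly,
                tag=tag,
                icer_vs_previous=icer_prev,
            )
        )
        if tag == "frontier":
            prev = s
    return FrontierReport(entries=entries)
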