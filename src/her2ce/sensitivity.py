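"""One-way, scenario and probabilistic sensitivity analysis.

All scans compare strategies under common random numbers: the same patient-
level uniform streams (derived from one seed) are reused across arms and
across parameter settings, so differences in outcomes are attributable to
the parameters, not to sampling noise.  Each analysis can run on either the
microsimulation (``engine="microsim"``) or the deterministic cohort trace
(``engine="trace"``); the trace gives the exact expectation in milliseconds
and is the default for the deterministic scans.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .economics import ICERResult, icer
from .parameters import (
    AGE_BANDS,
    ParameterSet,
    UncertaintySpec,
    get_path,
    parameter_hash,
    set_path,
    validate,
)
from .simulation import ArmSummary, simulate_arm, trace_summary

_MAX_RESAMPLE = 100


def _run_arm(pset: ParameterSet, arm_id: str, engine: str, n: Optional[int], seed: int) -> ArmSummary:
    if engine == "trace":
        return trace_summary(pset, arm_id)
    if engine == "microsim":
        return simulate_arm(pset, arm_id, n=n, seed=seed)
    raise ValueError(f"unknown engine {engine!r}")


def _draw(spec: UncertaintySpec, base: float, rng: np.random.Generator) -> float:
    if spec.kind == "fixed":
        return base
    if spec.kind == "pct_range":
        # single multiplier; callers apply it per path so shared parameters move together
        return float(rng.triangular(1 - spec.half_width_pct, 1.0, 1 + spec.half_width_pct))
    if spec.kind == "abs_range":
        if spec.low == spec.high:
            return spec.low
        return float(rng.triangular(spec.low, base, spec.high))
    if spec.kind == "beta_sd":
        var = spec.sd**2
        k = base * (1 - base) / var - 1.0
        if k <= 0:
            raise ValueError("beta_sd variance too large for mean")
        return float(rng.beta(base * k, (1 - base) * k))
    raise ValueError(f"unknown uncertainty kind {spec.kind!r}")


def sample_parameters(
    pset: ParameterSet,
    rng: np.random.Generator,
    exclude: Sequence[str] = ("discount rate",),
) -> ParameterSet:
    """One independent draw of every uncertain parameter.

    ``pct_range`` entries draw a single triangular multiplier applied to all
    their paths; ``abs_range``/``beta_sd`` draw an absolute value.  Labels in
    ``exclude`` stay at base (by default the discount rate, which is a
    scenario axis rather than a sampled quantity).  Invalid draws are
    rejected and redrawn, up to a cap.
    """
    for _ in range(_MAX_RESAMPLE):
        out = copy.deepcopy(pset)
        for label, spec in pset.uncertainty.items():
            if label in exclude or spec.kind == "fixed":
                continue
            v = _draw(spec, get_path(pset, spec.paths[0]), rng)
            for p in spec.paths:
                if spec.kind == "pct_range":
                    set_path(out, p, get_path(pset, p) * v)
                else:
                    set_path(out, p, v)
        if not validate(out):
            return out
    raise RuntimeError("could not draw a valid parameter set")


# ---------------------------------------------------------------------------
# One-way sensitivity / tornado

@dataclass
class TornadoEntry:
    label: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _apply(pset: ParameterSet, spec: UncertaintySpec, value: float, relative: bool) -> ParameterSet:
    out = copy.deepcopy(pset)
    for p in spec.paths:
        set_path(out, p, get_path(pset, p) * value if relative else value)
    return out


def _icer_th_vs_nt(pset: ParameterSet, engine: str, n: Optional[int], seed: int) -> float:
    th = _run_arm(pset, "TH", engine, n, seed)
    nt = _run_arm(pset, "NT", engine, n, seed)
    res = icer(th, nt)
    if res.icer_per_qaly is None:
        # dominance has no finite ratio; sign encodes the direction
        return float("-inf") if res.tag == "dominant" else float("inf")
    return res.icer_per_qaly


def one_way_scan(
    pset: ParameterSet,
    label: str,
    low: Optional[float] = None,
    high: Optional[float] = None,
    n: Optional[int] = None,
    seed: int = 0,
    engine: str = "trace",
) -> TornadoEntry:
    """TH-vs-NT ICER at the low and high end of one uncertain parameter."""
    spec = pset.uncertainty[label]
    base = get_path(pset, spec.paths[0])
    b_low, b_high = spec.bounds(base)
    low = b_low if low is None else low
    high = b_high if high is None else high
    relative = spec.kind == "pct_range"
    lo_val = low / base if relative else low
    hi_val = high / base if relative else high
    icer_lo = _icer_th_vs_nt(_apply(pset, spec, lo_val, relative), engine, n, seed)
    icer_hi = _icer_th_vs_nt(_apply(pset, spec, hi_val, relative), engine, n, seed)
    return TornadoEntry(
        label=label, low_value=low, high_value=high, icer_at_low=icer_lo, icer_at_high=icer_hi
    )


def tornado(
    pset: ParameterSet,
    labels: Optional[Sequence[str]] = None,
    n: Optional[int] = None,
    seed: int = 0,
    engine: str = "trace",
) -> list[TornadoEntry]:
    """One-way scan of every non-fixed uncertain parameter, widest first."""
    if labels is None:
        labels = [k for k, s in pset.uncertainty.items() if s.kind != "fixed"]
    entries = [one_way_scan(pset, lab, n=n, seed=seed, engine=engine) for lab in labels]
    return sorted(entries, key=lambda e: (-e.width, e.label))


# ---------------------------------------------------------------------------
# Scenario scans

def horizon_scan(
    pset: ParameterSet,
    horizons: Sequence[Optional[float]],
    n: Optional[int] = None,
    seed: int = 0,
    engine: str = "microsim",
) -> list[tuple[Optional[float], ICERResult]]:
    """TH-vs-NT ICER as the treatment-effect horizon varies.

    A horizon of ``h`` years means relapse probabilities revert to the
    untreated schedule beyond month ``12 h``; patients are still followed
    for life.  ``None`` means the effect persists for the whole lifetime.
    """
    out = []
    for h in horizons:
        p = copy.deepcopy(pset)
        p.effect_horizon_years = h
        th = _run_arm(p, "TH", engine, n, seed)
        nt = _run_arm(p, "NT", engine, n, seed)
        out.append((h, icer(th, nt)))
    return out


def age_scan(
    pset: ParameterSet,
    bands: Optional[Sequence[str]] = None,
    n: Optional[int] = None,
    seed: int = 0,
    engine: str = "microsim",
) -> list[tuple[str, ICERResult]]:
    """TH-vs-NT ICER per starting age band.

    Each cohort starts at the lower bound of its band; mortality, the
    relapse-free state cost and the baseline utility then follow the
    attained age band automatically.
    """
    if bands is None:
        bands = [b.label for b in AGE_BANDS]
    out = []
    for lbl in bands:
        p = copy.deepcopy(pset)
        p.start_age_band = lbl
        th = _run_arm(p, "TH", engine, n, seed)
        nt = _run_arm(p, "NT", engine, n, seed)
        out.append((lbl, icer(th, nt)))
    return out


@dataclass
class CostScaleRow:
    multiplier: float
    th_cost: float
    comparisons: dict[str, ICERResult]  # reference arm -> TH-vs-reference


def cost_scale_scan(
    pset: ParameterSet,
    multipliers: Sequence[float],
    n: Optional[int] = None,
    seed: int = 0,
    engine: str = "microsim",
) -> list[CostScaleRow]:
    """Scale only the TH monthly treatment cost and compare TH with each
    alternative (NT, ACTH, TCH kept at base)."""
    others = {}
    for arm_id in ("NT", "ACTH", "TCH"):
        others[arm_id] = _run_arm(pset, arm_id, engine, n, seed)
    rows = []
    for mult in multipliers:
        p = copy.deepcopy(pset)
        p.costs.treatment_monthly["TH"] = pset.costs.treatment_monthly["TH"] * mult
        th = _run_arm(p, "TH", engine, n, seed)
        rows.append(
            CostScaleRow(
                multiplier=mult,
                th_cost=th.mean_cost,
                comparisons={a: icer(th, s) for a, s in others.items()},
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis

DEFAULT_WTP_GRID = tuple(float(w) for w in range(0, 210_000, 10_000))


@dataclass
class PSAResult:
    n_samples: int
    wtp: float
    draws: list[tuple[str, float, float]]  # (parameter hash, delta_cost, delta_qaly)
    p_ce_at_wtp: float
    ceac: list[tuple[float, float]] = field(default_factory=list)

    def p_ce(self, wtp: float) -> float:
        nmb = [wtp * dq - dc for _, dc, dq in self.draws]
        return float(np.mean([v > 0 for v in nmb]))


def psa(
    pset: ParameterSet,
    n_samples: int = 10_000,
    n_patients: Optional[int] = None,
    wtp: Optional[float] = None,
    seed: int = 0,
    engine: str = "microsim",
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
) -> PSAResult:
    """Probabilistic sensitivity analysis of TH versus NT.

    Per draw, every uncertain parameter is sampled once (independently,
    triangular or beta per its spec); TH and NT are then evaluated with the
    same patient-level random substream (common random numbers within the
    draw).  The probability of cost-effectiveness is the fraction of draws
    with positive incremental net monetary benefit at the WTP threshold.
    """
    if wtp is None:
        wtp = pset.wtp
    if n_patients is None:
        n_patients = pset.n_patients
    param_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    draws: list[tuple[str, float, float]] = []
    for d in range(n_samples):
        sampled = sample_parameters(pset, param_rng)
        patient_seed = int(
            np.random.SeedSequence([int(seed), 1, d]).generate_state(1)[0] % (2**31)
        )
        th = _run_arm(sampled, "TH", engine, n_patients, patient_seed)
        nt = _run_arm(sampled, "NT", engine, n_patients, patient_seed)
        draws.append(
            (parameter_hash(sampled), th.mean_cost - nt.mean_cost, th.mean_qaly - nt.mean_qaly)
        )
    dc = np.array([x[1] for x in draws])
    dq = np.array([x[2] for x in draws])
    p_ce = float(np.mean(wtp * dq - dc > 0))
    ceac = [(float(w), float(np.mean(w * dq - dc > 0))) for w in wtp_grid]
    return PSAResult(n_samples=n_samples, wtp=wtp, draws=draws, p_ce_at_wtp=p_ce, ceac=ceac)
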