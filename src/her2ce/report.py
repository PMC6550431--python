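"""Tabular report writers (CSV + JSON) with provenance metadata.

Every output embeds the package version, the run seed and the parameter-set
hash, so two runs with identical inputs are byte-comparable.  CSV cells
carry full precision; the display variants round currency to whole dollars
and QALYs/LYs to two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .economics import FrontierReport
from .parameters import ParameterSet, parameter_hash
from .simulation import ArmSummary

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_IO = 3


@dataclass
class RunConfig:
    command: str
    seed: int
    out_dir: Path
    parameter_file: Optional[Path] = None
    formats: tuple[str, ...] = ("csv", "json")
    extra: dict = field(default_factory=dict)


def metadata(pset: ParameterSet, seed: int) -> dict:
    return {
        "package": "her2ce",
        "version": __version__,
        "seed": seed,
        "parameter_hash": parameter_hash(pset),
    }


def summaries_frame(summaries: Sequence[ArmSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "arm": s.arm_id,
                "n_patients": s.n,
                "mean_cost_usd2016": s.mean_cost,
                "mean_qaly": s.mean_qaly,
                "mean_ly": s.mean_ly,
                "se_cost_usd2016": s.se_cost,
                "se_qaly": s.se_qaly,
                "se_ly": s.se_ly,
                "frac_relapsed": s.frac_relapsed,
                "frac_quit": s.frac_quit,
            }
            for s in summaries
        ]
    )


def base_case_table(
    summaries: Sequence[ArmSummary], frontier: FrontierReport
) -> pd.DataFrame:
    """Per-arm cost/QALY/LY with incrementals versus the cheapest frontier
    arm's successor comparisons, mirroring the published base-case layout."""
    ref = next(s for s in summaries if s.arm_id == frontier.frontier[0])
    rows = []
    for s in sorted(summaries, key=lambda x: x.mean_cost):
        tag = frontier.tag_of(s.arm_id)
        entry = next(e for e in frontier.entries if e.arm_id == s.arm_id)
        if s.arm_id == ref.arm_id:
            icer_disp = "-"
        elif tag != "frontier":
            icer_disp = tag
        else:
            icer_disp = f"{entry.icer_vs_previous:,.0f} / QALY"
        rows.append(
            {
                "arm": s.arm_id,
                "total_cost_usd2016": s.mean_cost,
                "qalys": s.mean_qaly,
                "lys": s.mean_ly,
                "incr_cost_vs_" + ref.arm_id: s.mean_cost - ref.mean_cost,
                "incr_qaly_vs_" + ref.arm_id: s.mean_qaly - ref.mean_qaly,
                "icer": icer_disp,
                "status": tag,
            }
        )
    return pd.DataFrame(rows)


def display_round(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            if "cost" in c or "usd" in c or "icer" in c.lower():
                out[c] = out[c].round(0)
            else:
                out[c] = out[c].round(2)
    return out


def write_report(
    tables: dict[str, pd.DataFrame],
    out_dir: Path,
    meta: dict,
    formats: Sequence[str] = ("csv", "json"),
) -> list[Path]:
    """Write each named table in the requested formats; returns paths written."""
    if not tables:
        raise ValueError("no tables to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        if df.empty:
            raise ValueError(f"table {name!r} is empty")
        if "csv" in formats:
            path = out_dir / f"{name}.csv"
            with open(path, "w") as fh:
                for k, v in meta.items():
                    fh.write(f"# {k}: {v}\n")
                df.to_csv(fh, index=False)
            written.append(path)
        if "json" in formats:
            path = out_dir / f"{name}.json"
            payload = {"metadata": meta, "rows": json.loads(df.to_json(orient="records"))}
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))
            written.append(path)
    return written
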