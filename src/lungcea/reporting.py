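"""Tabular report writers.

Machine outputs are tab-delimited full-precision text with a commented
header carrying seed, parameter digest and schema version; pretty
tables round to 2 decimals with cost in CNY millions and life-years /
QALYs in 10,000s, matching the published layout.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .cea import DOMINANT, pairwise_icer
from .engine import StrategyOutcome
from .parameters import ParameterSet
from .screening import get_strategy


def metadata_header(params: ParameterSet, seed: int | None = None, **extra) -> str:
    fields = {
        "generator": f"lungcea {__version__}",
        "schema_version": params.schema_version,
        "params_digest": params.digest(),
    }
    if seed is not None:
        fields["seed"] = seed
    fields.update(extra)
    return "\n".join(f"# {k}: {v}" for k, v in fields.items())


def write_table(df: pd.DataFrame, path: str | Path, header: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def base_case_frame(
    outcomes: dict[int, StrategyOutcome], comparator_id: int = 0
) -> pd.DataFrame:
    """One row per strategy: presentation units plus ICER and label."""
    comparator = outcomes[comparator_id]
    rows = []
    for sid in sorted(outcomes):
        o = outcomes[sid]
        if sid == comparator_id:
            icer, label = None, "comparator"
        else:
            r = pairwise_icer(o, comparator)
            icer, label = r.icer, r.label
        rows.append(
            {
                "strategy": sid,
                "description": get_strategy(sid).label,
                "cost_millions": o.cost_millions,
                "ly_10k": o.ly_10k,
                "qaly_10k": o.qaly_10k,
                "icer_vs_comparator": icer,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def pretty_base_case(df: pd.DataFrame) -> str:
    """2-decimal rendering with the dominance footnote marker."""
    out = df.copy()
    for col in ("cost_millions", "ly_10k", "qaly_10k"):
        out[col] = out[col].map(lambda x: f"{x:.2f}")
    out["icer_vs_comparator"] = [
        "NA"
        if icer is None
        else f"{icer:,.2f}" + (" [b]" if label == DOMINANT else "")
        for icer, label in zip(df["icer_vs_comparator"], df["label"])
    ]
    out = out.drop(columns=["label"])
    text = out.to_string(index=False)
    return text + "\n\n[b] Dominant (less costly, more QALYs than the comparator)."


def tornado_frame(base_icer: float | None, rows) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "rank": i + 1,
                "parameter": r.path,
                "low_value": r.low_value,
                "high_value": r.high_value,
                "icer_min": r.icer_min,
                "icer_max": r.icer_max,
                "bar_width": r.width,
            }
            for i, r in enumerate(rows)
        ]
    )
    df.attrs["base_icer"] = base_icer
    return df


def psa_frame(samples, comparator_id: int) -> pd.DataFrame:
    """Per-draw outcomes plus increments vs the comparator (scatter data)."""
    rows = []
    for s in samples:
        comparator = s.outcomes[comparator_id]
        row = {"index": s.index, "params_digest": s.params_digest}
        for sid in sorted(s.outcomes):
            o = s.outcomes[sid]
            row[f"cost_{sid}"] = o.cost * o.population
            row[f"qaly_{sid}"] = o.qalys * o.population
            if sid != comparator_id:
                row[f"dcost_{sid}"] = (o.cost - comparator.cost) * o.population
                row[f"dqaly_{sid}"] = (o.qalys - comparator.qalys) * o.population
        rows.append(row)
    return pd.DataFrame(rows)


def ceac_frame(wtp_grid, curves: dict[int, "pd.Series | list"]) -> pd.DataFrame:
    df = pd.DataFrame({"wtp": list(wtp_grid)})
    for sid, probs in curves.items():
        df[f"p_cost_effective_{sid}"] = list(probs)
    return df
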