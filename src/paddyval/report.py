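"""Report rendering: CSV and JSON views of a valuation and a comparison.

Values are carried unrounded everywhere in the engine; the 万-scaled CSV
columns are rounded to 2 decimals here, at the reporting boundary only.
The JSON rendering carries full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cultural import ScenarioComparison, ServiceValuation
from .units import rescale_money


def valuation_frame(v: ServiceValuation, comparison: ScenarioComparison | None = None) -> pd.DataFrame:
    """Tabular view: one row per service plus a total row.

    Columns: service, cices_section, value_wan (2 d.p.), share_pct; when a
    comparison is given also baseline_wan, added_wan, added_proportion_pct
    and the proportion convention.
    """
    rows = []
    for label, comp in v.components.items():
        row = {
            "service": label,
            "cices_section": comp.cices_section,
            "value_wan": round(rescale_money(comp.value, "wan"), 2),
            "share_pct": round(v.shares_pct[label], 2),
        }
        if comparison is not None:
            c = comparison.rows[label]
            row.update(
                baseline_wan=round(rescale_money(c.value_b, "wan"), 2),
                added_wan=round(rescale_money(c.added, "wan"), 2),
                added_proportion_pct=(
                    round(c.added_proportion_pct, 2) if c.added_proportion_pct is not None else None
                ),
                convention=comparison.convention,
            )
        rows.append(row)
    total_row = {
        "service": "total",
        "cices_section": "",
        "value_wan": round(rescale_money(v.total, "wan"), 2),
        "share_pct": 100.0,
    }
    if comparison is not None:
        t = comparison.total
        total_row.update(
            baseline_wan=round(rescale_money(t.value_b, "wan"), 2),
            added_wan=round(rescale_money(t.added, "wan"), 2),
            added_proportion_pct=(
                round(t.added_proportion_pct, 2) if t.added_proportion_pct is not None else None
            ),
            convention=comparison.convention,
        )
    rows.append(total_row)
    return pd.DataFrame(rows)


def valuation_json(v: ServiceValuation, comparison: ScenarioComparison | None = None) -> dict:
    """Full-precision JSON-serialisable rendering."""
    out = {
        "reference_year": v.total.reference_year,
        "components_cny": {k: c.value.amount for k, c in v.components.items()},
        "cices_sections": {k: c.cices_section for k, c in v.components.items()},
        "total_cny": v.total.amount,
        "shares_pct": dict(v.shares_pct),
        "provenance": dict(v.provenance),
    }
    if comparison is not None:
        out["comparison"] = {
            "convention": comparison.convention,
            "rows": {
                k: {
                    "value_cny": r.value_a.amount,
                    "baseline_cny": r.value_b.amount,
                    "added_cny": r.added.amount,
                    "added_proportion_pct": r.added_proportion_pct,
                }
                for k, r in comparison.rows.items()
            },
            "total": {
                "value_cny": comparison.total.value_a.amount,
                "baseline_cny": comparison.total.value_b.amount,
                "added_cny": comparison.total.added.amount,
                "added_proportion_pct": comparison.total.added_proportion_pct,
            },
        }
    return out


def write_report(
    v: ServiceValuation,
    comparison: ScenarioComparison | None,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("csv", "json"),
    stem: str = "valuation",
) -> list[Path]:
    """Write the valuation (and optional comparison) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fmt in formats:
        if fmt == "csv":
            p = out_dir / f"{stem}.csv"
            valuation_frame(v, comparison).to_csv(p, index=False)
        elif fmt == "json":
            p = out_dir / f"{stem}.json"
            p.write_text(json.dumps(valuation_json(v, comparison), indent=2))
        else:
            raise ValueError(f"unknown report format {fmt!r}; expected csv or json")
        written.append(p)
    return written
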