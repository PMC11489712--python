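"""Human-readable and tabular report rendering."""

from __future__ import annotations

import json
from typing import Optional

import pandas as pd

from .model import Key, KeyMetrics, RubricResult, record_to_dict

__all__ = ["render_report", "defects_to_lines", "rubric_to_frame", "defects_to_json"]


def defects_to_lines(defects) -> list:
    return [str(d) for d in defects]


def defects_to_json(defects, **kwargs) -> str:
    return json.dumps([record_to_dict(d) for d in defects], **kwargs)


def rubric_to_frame(results) -> pd.DataFrame:
    """One row per key: seventeen verdict columns, the suboptimal count and
    the percentage of applicable criteria."""
    rows = []
    for r in results:
        row = {"key_id": r.key_id}
        for cid in range(1, 18):
            row[f"c{cid:02d}"] = r.verdicts.get(cid, "not-applicable")
        row["n_suboptimal"] = r.n_suboptimal
        row["n_applicable"] = r.n_applicable
        row["pct_suboptimal"] = r.pct_suboptimal
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt(x, nd=4):
    if x is None:
        return "—"
    if isinstance(x, float):
        return f"{x:.{nd}g}"
    return str(x)


def render_report(
    key: Key,
    metrics: Optional[KeyMetrics] = None,
    defects=None,
    rubric: Optional[RubricResult] = None,
) -> str:
    """Render a full text report: scope header, metrics block, defect table,
    and rubric verdicts with their audit trail."""
    lines = [f"Key: {key.key_id}"]
    if key.title:
        lines.append(f"Title: {key.title}")
    sc = key.scope
    scope_bits = [b for b in (sc.group_rank, sc.extent, sc.sex, sc.caste) if b]
    if sc.is_emendation:
        scope_bits.append("emendation")
    if scope_bits:
        lines.append("Scope: " + ", ".join(scope_bits))
    lines.append(f"Style: {key.style}")

    if metrics is not None:
        lines += [
            "",
            "Metrics",
            f"  taxa: {metrics.n_taxa}   couplets: {metrics.n_couplets} "
            f"(expected {metrics.n_couplets_expected})",
            f"  mean steps to identification: {_fmt(metrics.s_actual)} "
            f"(fan minimum {_fmt(metrics.s_min)}, comb maximum {_fmt(metrics.s_max)})",
        ]
        if metrics.depth_range:
            lines.append(f"  path lengths: {metrics.depth_range[0]}–{metrics.depth_range[1]}")
        if metrics.is_max_fan is not None:
            lines.append(f"  maximally fan-shaped: {'yes' if metrics.is_max_fan else 'no'}")

    lines.append("")
    if defects:
        lines.append(f"Defects ({len(defects)})")
        lines += ["  " + str(d) for d in defects]
    else:
        lines.append("Defects: no defects detected")

    if rubric is not None:
        lines += [
            "",
            f"Rubric: {rubric.n_suboptimal} of {rubric.n_applicable} applicable "
            f"criteria suboptimal ({rubric.pct_suboptimal:.1f}%)",
        ]
        for cid in sorted(rubric.verdicts):
            lines.append(
                f"  {cid:2d}. {rubric.verdicts[cid]:<14} {rubric.evidence.get(cid, '')}"
            )
    return "\n".join(lines) + "\n"
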