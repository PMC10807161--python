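"""Round-summary and audit report rendering (JSON + Markdown).

Raw precision is preserved in the JSON payloads; display rounding (two
decimals for authority coefficients, three for W, four for weights) is
applied only when rendering Markdown.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from typing import Iterable, Mapping, Sequence

from ._rounding import round_half_even
from .delphi import (
    DEFAULT_CA_TABLE,
    DEFAULT_CS_MAP,
    FilterCriteria,
    apply_filters,
    kendalls_w,
    panel_authority,
    panel_item_stats,
    response_rate,
)
from .errors import DegenerateRatingsError
from .instrument import AuditReport
from .panel import ExpertProfile, RatingPanel

__all__ = ["config_hash", "round_summary", "summary_markdown", "audit_markdown"]


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping, embedded in reports."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def round_summary(
    panel: RatingPanel,
    profiles: Sequence[ExpertProfile] | None = None,
    criteria: FilterCriteria | None = None,
    invited: int | None = None,
    cs_map: Mapping[int, float] = DEFAULT_CS_MAP,
    ca_table: Mapping[str, Mapping[str, float]] = DEFAULT_CA_TABLE,
    config: Mapping | None = None,
) -> dict:
    """Full per-round report: descriptives, concordance, authority, filter."""
    stats = panel_item_stats(panel)
    summary: dict = {
        "round_id": panel.round_id,
        "n_experts": len(panel.experts),
        "n_items": len(panel.items),
        "item_stats": [asdict(s) for s in stats],
        "concordance": {},
    }
    for dim in panel.dimensions:
        try:
            summary["concordance"][dim] = asdict(kendalls_w(panel, dim))
        except DegenerateRatingsError as exc:
            summary["concordance"][dim] = {"error": str(exc)}
    if profiles is not None:
        summary["authority"] = panel_authority(profiles, cs_map, ca_table)
    if invited is not None:
        summary["response_rate_pct"] = response_rate(invited, len(panel.experts))
    if criteria is not None:
        result = apply_filters(stats, criteria)
        summary["filter"] = {
            "criteria": asdict(criteria),
            "retained": list(result.retained),
            "dropped": {k: dict(v) for k, v in result.dropped.items()},
        }
    summary["config_hash"] = config_hash(dict(config) if config else {})
    return summary


def summary_markdown(summary: Mapping) -> str:
    """Render a round summary as Markdown."""
    lines = [
        f"# Delphi round report: {summary['round_id']}",
        "",
        f"- experts: {summary['n_experts']}  |  items: {summary['n_items']}",
    ]
    if "response_rate_pct" in summary:
        lines.append(f"- response rate: {summary['response_rate_pct']:.2f}%")
    if "authority" in summary:
        a = summary["authority"]
        lines.append(
            "- authority: Cs {:.2f} +/- {:.2f}, Ca {:.2f} +/- {:.2f}, "
            "Cr {:.2f} +/- {:.2f}".format(
                round_half_even(a["cs_mean"], 2), round_half_even(a["cs_sd"], 2),
                round_half_even(a["ca_mean"], 2), round_half_even(a["ca_sd"], 2),
                round_half_even(a["cr_mean"], 2), round_half_even(a["cr_sd"], 2),
            )
        )
    lines += ["", "## Concordance", "", "| dimension | W | chi2 | df | p |", "|---|---|---|---|---|"]
    for dim, c in summary["concordance"].items():
        if "error" in c:
            lines.append(f"| {dim} | degenerate | - | - | - |")
        else:
            lines.append(
                f"| {dim} | {round_half_even(c['w'], 3):.3f} | "
                f"{round_half_even(c['chi_square'], 2):.2f} | {c['df']} | {c['p_value']:.3g} |"
            )
    if "filter" in summary:
        f = summary["filter"]
        lines += [
            "",
            "## Retention filter",
            "",
            f"- retained {len(f['retained'])} of "
            f"{len(f['retained']) + len(f['dropped'])} items",
        ]
        for item, reasons in f["dropped"].items():
            detail = "; ".join(f"{d}: {r}" for d, r in reasons.items())
            lines.append(f"- dropped {item}: {detail}")
    lines.append("")
    lines.append(f"_config hash: {summary['config_hash']}_")
    return "\n".join(lines)


def audit_markdown(report: AuditReport, title: str = "Instrument audit") -> str:
    """Render an instrument audit as Markdown."""
    lines = [
        f"# {title}",
        "",
        f"- leaf combined weights (normalized product rule) sum to "
        f"{report.leaf_weight_sum:.4f}",
        f"- combined-weight rows outside rounding agreement: "
        f"{', '.join(report.combined_weight_exceptions) or 'none'}",
        f"- score rows deviating from the 100 x weight rule: "
        f"{', '.join(report.score_exceptions) or 'none'}",
        f"- rows with derived (reconstructed) scores: "
        f"{', '.join(report.derived_rows) or 'none'}",
    ]
    if report.children_sum_violations:
        lines.append(
            "- children local weights not summing to 1 under: "
            + ", ".join(
                f"{k} (sum {v:.4f})" for k, v in report.children_sum_violations.items()
            )
        )
    lines += ["", "## Consistency ratios", "", "| node | printed CR | recomputed CR | status |", "|---|---|---|---|"]
    for node_id, printed, recomputed, status in report.consistency_checks:
        lines.append(f"| {node_id} | {printed:.4f} | {recomputed:.4f} | {status} |")
    lines += ["", "## Flagged rows", "", "| node | printed w | expected w | status | printed score | rule score |", "|---|---|---|---|---|---|"]
    for row in report.rows:
        if row.combined_status == "mismatch" or row.score_status == "mismatch":
            lines.append(
                f"| {row.node_id} | {row.printed_combined} | {row.expected_combined} "
                f"| {row.combined_status} | {row.printed_score} | {row.rule_score} |"
            )
    lines.append("")
    return "\n".join(lines)
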