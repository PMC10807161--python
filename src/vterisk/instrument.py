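"""The packaged VTE risk instrument: loading, auditing and patient scoring.

The instrument is a versioned YAML artifact — 3 domains, 10 subdomains and
39 indicator leaves, each with a signed integer score — shipped with the
package. ``audit_instrument`` re-derives every combined weight by the
hierarchy product rule and every score by the 100-x-weight rounding rule
and classifies each published row as ``exact``, ``within_rounding`` (off by
at most one unit in the last printed decimal) or ``mismatch``; the known
anomalies of the published table are surfaced, never silently corrected.

Patient scoring is additive over flagged indicators, with mutually
exclusive categories (the two BMI bands) resolved in favour of the
highest-magnitude member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from ._rounding import round_half_even
from .errors import IdentificationError, InstrumentError
from .hierarchy import (
    CHILD_SUM_TOL,
    HierarchyNode,
    children_sum_violations,
    combined_weights,
    derive_score,
)
from .ahp import consistency

__all__ = [
    "InstrumentSpec",
    "PatientRecord",
    "ScoreReport",
    "AuditRow",
    "AuditReport",
    "load_instrument",
    "audit_instrument",
    "score_patient",
    "score_cohort",
    "score_range",
    "read_patients_csv",
]

logger = logging.getLogger(__name__)

_PACKAGED = "cancer_vte_instrument.yaml"

_EXPECTED_COUNTS = {"domain": 3, "subdomain": 10, "indicator": 39}


@dataclass(frozen=True)
class InstrumentSpec:
    """A validated risk instrument: hierarchy tree plus scoring metadata."""

    version: str
    title: str
    tree: HierarchyNode
    exclusivity_groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    ri_table: str = "RI_52"

    @property
    def indicators(self) -> list[HierarchyNode]:
        return [n for n in self.tree.walk() if n.level == "indicator"]

    @property
    def indicator_ids(self) -> list[str]:
        return [n.node_id for n in self.indicators]

    @property
    def score_map(self) -> dict[str, int]:
        return {n.node_id: int(n.score) for n in self.indicators}

    def group_of(self, indicator_id: str) -> str | None:
        for group, members in self.exclusivity_groups.items():
            if indicator_id in members:
                return group
        return None


@dataclass(frozen=True)
class PatientRecord:
    """Binary indicator flags for one patient."""

    patient_id: str
    flags: Mapping[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class ScoreReport:
    """Additive risk total with per-indicator contributions."""

    patient_id: str
    total_score: int
    contributions: tuple[tuple[str, int], ...]
    suppressed: tuple[str, ...] = ()


@dataclass(frozen=True)
class AuditRow:
    """Audit verdict for one published row."""

    node_id: str
    level: str
    printed_combined: float | None
    expected_combined: float | None
    combined_status: str  # "exact" | "within_rounding" | "mismatch"
    printed_score: int | None = None
    rule_score: int | None = None
    score_status: str | None = None
    provenance: str | None = None
    note: str | None = None


@dataclass(frozen=True)
class AuditReport:
    """Full audit of an instrument file against its own construction rules."""

    rows: tuple[AuditRow, ...]
    children_sum_violations: Mapping[str, float]
    consistency_checks: tuple[tuple[str, float, float, str], ...]
    leaf_weight_sum: float  # of audit-corrected (normalized) leaf weights

    @property
    def combined_weight_exceptions(self) -> tuple[str, ...]:
        return tuple(r.node_id for r in self.rows if r.combined_status == "mismatch")

    @property
    def score_exceptions(self) -> tuple[str, ...]:
        return tuple(r.node_id for r in self.rows if r.score_status == "mismatch")

    @property
    def derived_rows(self) -> tuple[str, ...]:
        return tuple(r.node_id for r in self.rows if r.provenance == "derived")


# ---------------------------------------------------------------------------
# loading


def load_instrument(path: str | Path | None = None) -> InstrumentSpec:
    """Load and validate an instrument file (the packaged one by default)."""
    if path is None:
        source = resources.files("vterisk.data").joinpath(_PACKAGED)
        data = yaml.safe_load(source.read_text(encoding="utf-8"))
    else:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, Mapping) or "tree" not in data:
        raise InstrumentError("instrument file must be a mapping with a 'tree' key")
    try:
        tree = HierarchyNode.from_dict(data["tree"])
    except (KeyError, TypeError, ValueError) as exc:
        raise InstrumentError(f"malformed hierarchy: {exc}") from exc
    spec = InstrumentSpec(
        version=str(data.get("version", "unversioned")),
        title=str(data.get("title", "risk instrument")),
        tree=tree,
        exclusivity_groups={
            str(g): tuple(str(m) for m in members)
            for g, members in (data.get("exclusivity_groups") or {}).items()
        },
        ri_table=str(data.get("ri_table", "RI_52")),
    )
    _validate(spec)
    return spec


def _validate(spec: InstrumentSpec) -> None:
    counts = {lvl: 0 for lvl in _EXPECTED_COUNTS}
    seen: set[str] = set()
    for node in spec.tree.walk():
        if node.node_id in seen:
            raise InstrumentError(f"duplicate node id {node.node_id!r}")
        seen.add(node.node_id)
        if node.level in counts:
            counts[node.level] += 1
        if node.level == "indicator":
            if node.direction is None:
                raise InstrumentError(f"indicator {node.node_id!r} missing direction")
            if node.score is None or int(node.score) == 0:
                raise InstrumentError(
                    f"indicator {node.node_id!r} must carry a nonzero integer score"
                )
            if node.children:
                raise InstrumentError(f"indicator {node.node_id!r} must be a leaf")
    for level, expected in _EXPECTED_COUNTS.items():
        if counts[level] != expected:
            raise InstrumentError(
                f"expected {expected} {level}s, found {counts[level]}"
            )
    protective = [n.node_id for n in spec.indicators if n.direction == "protective"]
    if len(protective) != 2:
        raise InstrumentError(f"expected 2 protective indicators, found {protective}")
    ids = set(spec.indicator_ids)
    for group, members in spec.exclusivity_groups.items():
        if len(members) < 2:
            raise InstrumentError(f"exclusivity group {group!r} needs >= 2 members")
        unknown = sorted(set(members) - ids)
        if unknown:
            raise InstrumentError(f"exclusivity group {group!r} names unknown ids {unknown}")
    violations = children_sum_violations(spec.tree)
    if violations:
        logger.warning(
            "instrument %s: children local weights not summing to 1 at %s",
            spec.version, dict(violations),
        )


# ---------------------------------------------------------------------------
# audit

#: A printed 4-decimal value that differs from the recomputed one by at most
#: one unit in the last decimal is rounding residue, not a transcription or
#: construction error.
_ULP = 1e-4


def audit_instrument(
    spec: InstrumentSpec, ri_table: str | None = None
) -> AuditReport:
    """Recompute every combined weight and score and classify each row.

    Combined weights are re-derived by the product rule on *normalized*
    sibling weights (so a subdomain's sole indicator inherits the subdomain
    weight in full — the reading under which the 39 leaf weights sum to the
    root weight). Scores are re-derived by the 100-x-weight rule from the
    stored combined weight. CR values stored on parent nodes are re-checked
    from their lambda_max against the instrument's RI table.
    """
    ri = ri_table or spec.ri_table
    expected = combined_weights(spec.tree, normalize=True)
    violations = children_sum_violations(spec.tree)

    rows: list[AuditRow] = []
    for node in spec.tree.walk():
        if node.level == "root":
            continue
        exp = round_half_even(expected[node.node_id], 4)
        printed = node.combined_weight
        if printed is None:
            status = "mismatch"
        else:
            diff = abs(printed - exp)
            status = (
                "exact" if diff < 1e-12
                else "within_rounding" if diff <= _ULP + 1e-12
                else "mismatch"
            )
        printed_score = rule_score = None
        score_status = None
        if node.level == "indicator":
            printed_score = int(node.score)
            rule_score = derive_score(node.combined_weight, node.direction or "risk")
            score_status = "exact" if printed_score == rule_score else "mismatch"
        rows.append(
            AuditRow(
                node_id=node.node_id,
                level=node.level,
                printed_combined=printed,
                expected_combined=exp,
                combined_status=status,
                printed_score=printed_score,
                rule_score=rule_score,
                score_status=score_status,
                provenance=node.provenance,
                note=node.note,
            )
        )

    checks: list[tuple[str, float, float, str]] = []
    for node in spec.tree.walk():
        if node.lambda_max is not None and node.cr is not None and node.children:
            n = len(node.children)
            _, cr = consistency(node.lambda_max, n, ri)
            cr4 = round_half_even(cr, 4)
            diff = abs(cr4 - node.cr)
            status = (
                "exact" if diff < 1e-12
                else "within_rounding" if diff <= _ULP + 1e-12
                else "mismatch"
            )
            checks.append((node.node_id, node.cr, cr4, status))

    leaf_sum = sum(expected[n.node_id] for n in spec.indicators)
    return AuditReport(
        rows=tuple(rows),
        children_sum_violations=violations,
        consistency_checks=tuple(checks),
        leaf_weight_sum=leaf_sum,
    )


# ---------------------------------------------------------------------------
# scoring


def score_patient(
    record: PatientRecord, spec: InstrumentSpec, *, resolve_exclusivity: bool = True
) -> ScoreReport:
    """Total risk score for one patient.

    The total is the sum of printed scores over flagged indicators; within
    an exclusivity group only the highest-magnitude flagged member
    contributes (ties broken toward the later, higher-category row) and the
    rest are reported as suppressed. Unknown indicator ids in the flags are
    an error; indicators without a flag default to absent.
    """
    scores = spec.score_map
    unknown = sorted(set(record.flags) - set(scores))
    if unknown:
        raise IdentificationError(
            f"patient {record.patient_id!r}: unknown indicator ids {unknown}"
        )
    present = [i for i in spec.indicator_ids if record.flags.get(i, False)]

    suppressed: list[str] = []
    if resolve_exclusivity:
        for group, members in spec.exclusivity_groups.items():
            flagged = [i for i in present if i in members]
            if len(flagged) > 1:
                keep = max(flagged, key=lambda i: (abs(scores[i]), spec.indicator_ids.index(i)))
                suppressed.extend(i for i in flagged if i != keep)
        present = [i for i in present if i not in suppressed]

    contributions = tuple((i, scores[i]) for i in present)
    return ScoreReport(
        patient_id=record.patient_id,
        total_score=sum(s for _, s in contributions),
        contributions=contributions,
        suppressed=tuple(sorted(suppressed)),
    )


def score_cohort(
    records: Iterable[PatientRecord], spec: InstrumentSpec
) -> pd.DataFrame:
    """Score many patients; one row per patient, ordered by patient id."""
    reports = [score_patient(r, spec) for r in records]
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in reports],
            "total_score": [r.total_score for r in reports],
            "n_contributing": [len(r.contributions) for r in reports],
            "suppressed": [";".join(r.suppressed) for r in reports],
        }
    )
    return df.sort_values("patient_id", kind="stable").reset_index(drop=True)


def score_range(spec: InstrumentSpec) -> tuple[int, int]:
    """Attainable (min, max) totals.

    The minimum flags every protective indicator and nothing else; the
    maximum flags every risk indicator with exclusivity groups resolved to
    their highest-scoring member.
    """
    scores = spec.score_map
    min_total = sum(s for s in scores.values() if s < 0)
    grouped: set[str] = set()
    max_total = 0
    for members in spec.exclusivity_groups.values():
        grouped.update(members)
        best = max((scores[m] for m in members), default=0)
        if best > 0:
            max_total += best
    max_total += sum(s for i, s in scores.items() if s > 0 and i not in grouped)
    return min_total, max_total


# ---------------------------------------------------------------------------
# io


def read_patients_csv(path: str | Path, spec: InstrumentSpec) -> list[PatientRecord]:
    """Read a patients CSV: ``patient_id`` plus one 0/1 column per indicator."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise InstrumentError(f"{path}: missing patient_id column")
    unknown = sorted(set(df.columns) - {"patient_id"} - set(spec.indicator_ids))
    if unknown:
        raise IdentificationError(f"{path}: unknown indicator columns {unknown}")
    records = []
    for _, row in df.iterrows():
        flags = {
            col: bool(int(row[col]))
            for col in df.columns
            if col != "patient_id" and not pd.isna(row[col])
        }
        records.append(PatientRecord(patient_id=str(row["patient_id"]), flags=flags))
    return records
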