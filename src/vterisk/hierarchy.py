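"""Hierarchy trees: local and combined weights, and score derivation.

A risk-instrument hierarchy is a tree of domains, subdomains and indicator
leaves. Each node carries a *local* weight (its priority among siblings,
from the AHP analysis of the parent's judgment matrix) and a *combined*
weight (the product of local weights along the path from the root). An
indicator's integer risk score is 100 x combined weight rounded half-up on
the magnitude — clamped to a minimum magnitude of 1 so no retained
indicator scores 0 — and signed negative for protective indicators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping

import yaml
from decimal import ROUND_HALF_UP, Decimal

from ._rounding import round_half_even
from .errors import IdentificationError

__all__ = [
    "HierarchyNode",
    "LEVELS",
    "CHILD_SUM_TOL",
    "combined_weights",
    "combine_hierarchy",
    "children_sum_violations",
    "derive_score",
    "load_hierarchy",
    "save_hierarchy",
]

LEVELS = ("root", "domain", "subdomain", "indicator")

#: Tolerance on sibling local weights summing to 1 (published tables are
#: printed to 4 decimals, so a residue up to 5e-4 is rounding, not error).
CHILD_SUM_TOL = 5e-4


@dataclass
class HierarchyNode:
    """One node of the instrument hierarchy."""

    node_id: str
    name: str
    level: str
    local_weight: float
    combined_weight: float | None = None
    direction: str | None = None  # indicators only: "risk" | "protective"
    score: int | None = None
    provenance: str | None = None  # "printed" | "derived"
    lambda_max: float | None = None  # of the judgment matrix over children
    cr: float | None = None
    note: str | None = None
    children: list["HierarchyNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"{self.node_id}: unknown level {self.level!r}")
        if self.direction is not None and self.direction not in ("risk", "protective"):
            raise ValueError(f"{self.node_id}: unknown direction {self.direction!r}")

    # -- traversal ---------------------------------------------------------

    def walk(self) -> Iterator["HierarchyNode"]:
        """Depth-first, document order."""
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> list["HierarchyNode"]:
        return [n for n in self.walk() if not n.children]

    def find(self, node_id: str) -> "HierarchyNode":
        for n in self.walk():
            if n.node_id == node_id:
                return n
        raise IdentificationError(f"no node {node_id!r} in hierarchy")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "node_id": self.node_id,
            "name": self.name,
            "level": self.level,
            "local_weight": self.local_weight,
        }
        for key in ("combined_weight", "direction", "score", "provenance",
                    "lambda_max", "cr", "note"):
            value = getattr(self, key)
            if value is not None:
                d[key] = value
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "HierarchyNode":
        known = {k: d[k] for k in (
            "node_id", "name", "level", "local_weight", "combined_weight",
            "direction", "score", "provenance", "lambda_max", "cr", "note",
        ) if k in d}
        node = cls(**known)
        node.children = [cls.from_dict(c) for c in d.get("children", ())]
        return node


def combined_weights(root: HierarchyNode, normalize: bool = False) -> dict[str, float]:
    """Full-precision combined weight of every node by the product rule.

    ``combined(child) = combined(parent) x local(child)`` with the root at
    its own local weight (1 for a proper root). With ``normalize=True``
    each sibling group's local weights are first rescaled to sum to 1 — the
    principled reading under which leaf combined weights sum exactly to the
    root weight (a sole child then inherits its parent's weight in full).
    """
    out: dict[str, float] = {}

    def visit(node: HierarchyNode, acc: float) -> None:
        out[node.node_id] = acc
        total = sum(c.local_weight for c in node.children)
        for child in node.children:
            local = child.local_weight / total if normalize else child.local_weight
            visit(child, acc * local)

    visit(root, root.local_weight)
    return out


def combine_hierarchy(
    root: HierarchyNode, *, overwrite: bool = True, ndigits: int = 4
) -> HierarchyNode:
    """Fill ``combined_weight`` on every node by the product rule.

    Weights are stored rounded half-even to ``ndigits`` decimals (the
    published-table display convention); with ``overwrite=False`` nodes that
    already carry a combined weight keep it.
    """
    full = combined_weights(root, normalize=False)
    for node in root.walk():
        if overwrite or node.combined_weight is None:
            node.combined_weight = round_half_even(full[node.node_id], ndigits)
    return root


def children_sum_violations(
    root: HierarchyNode, tol: float = CHILD_SUM_TOL
) -> dict[str, float]:
    """Parent node ids whose children's local weights do not sum to 1."""
    out: dict[str, float] = {}
    for node in root.walk():
        if node.children:
            total = sum(c.local_weight for c in node.children)
            if abs(total - 1.0) > tol:
                out[node.node_id] = total
    return out


def derive_score(
    combined_weight: float, direction: str = "risk", *, min_magnitude: int = 1
) -> int:
    """Signed integer score from a combined weight.

    Magnitude is ``100 x combined_weight`` rounded half-up, clamped below at
    ``min_magnitude`` (default 1: every retained indicator must move the
    total); the sign is negative iff the indicator is protective.
    """
    if not 0 < combined_weight < 1:
        raise ValueError(f"combined weight must lie in (0, 1), got {combined_weight}")
    if direction not in ("risk", "protective"):
        raise ValueError(f"unknown direction {direction!r}")
    magnitude = int(
        (Decimal(str(combined_weight)) * 100).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    )
    magnitude = max(magnitude, min_magnitude)
    return -magnitude if direction == "protective" else magnitude


# ---------------------------------------------------------------------------
# io


def load_hierarchy(path: str | Path) -> HierarchyNode:
    """Read a hierarchy tree from YAML or JSON ({tree: {...}} or bare node)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if isinstance(data, Mapping) and "tree" in data:
        data = data["tree"]
    return HierarchyNode.from_dict(data)


def save_hierarchy(root: HierarchyNode, path: str | Path) -> None:
    path = Path(path)
    payload = root.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
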