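"""Expert rating panels and expert profiles.

A Delphi consultation round produces, for every expert and candidate
indicator, three Likert ratings on 1..5 — the *necessity*, *importance* and
*operability* of the indicator — together with a per-expert profile (topic
familiarity and the declared bases of judgment) used for the authority
coefficient. This module holds both containers and their CSV dialects.

The long-format ratings CSV has columns ``expert_id,item_id,dimension,rating``;
the profiles CSV has ``expert_id,familiarity,basis_theoretical,
basis_experience,basis_peer,basis_intuition``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IdentificationError, ParseError

__all__ = [
    "DIMENSIONS",
    "JUDGMENT_BASES",
    "INFLUENCE_LEVELS",
    "RatingPanel",
    "ExpertProfile",
    "read_ratings_csv",
    "read_profiles_csv",
    "write_profiles_csv",
]

logger = logging.getLogger(__name__)

#: The three Likert dimensions every item is rated on.
DIMENSIONS: tuple[str, ...] = ("necessity", "importance", "operability")

#: Declared bases of expert judgment, in the conventional order.
JUDGMENT_BASES: tuple[str, ...] = (
    "theoretical_analysis",
    "experience",
    "peer_understanding",
    "intuition",
)

INFLUENCE_LEVELS: tuple[str, ...] = ("high", "medium", "low")

_RATING_DOMAIN = frozenset({1, 2, 3, 4, 5})


@dataclass(frozen=True)
class ExpertProfile:
    """One expert's familiarity level and judgment-basis selections.

    ``familiarity_level`` is the self-rated 1 (unfamiliar) .. 5 (very
    familiar) scale; ``judgment_basis`` maps each basis in
    :data:`JUDGMENT_BASES` to an influence level in :data:`INFLUENCE_LEVELS`.
    """

    expert_id: str
    familiarity_level: int
    judgment_basis: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.familiarity_level not in range(1, 6):
            raise ValueError(
                f"familiarity_level must be in 1..5, got {self.familiarity_level!r}"
            )
        missing = [b for b in JUDGMENT_BASES if b not in self.judgment_basis]
        if missing:
            raise ValueError(f"profile {self.expert_id!r} missing bases: {missing}")
        for basis, level in self.judgment_basis.items():
            if basis not in JUDGMENT_BASES:
                raise ValueError(f"unknown judgment basis {basis!r}")
            if level not in INFLUENCE_LEVELS:
                raise ValueError(f"unknown influence level {level!r} for {basis!r}")


class RatingPanel:
    """Long-format container of one round's Likert ratings.

    Parameters
    ----------
    data
        DataFrame with columns ``expert_id``, ``item_id``, ``dimension``,
        ``rating``. Ratings must be integers in 1..5; a missing (expert,
        item, dimension) cell is simply an absent row.
    round_id
        Free-text label for the consultation round.
    """

    def __init__(self, data: pd.DataFrame, round_id: str = "round-1"):
        required = ["expert_id", "item_id", "dimension", "rating"]
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise ValueError(f"ratings table missing columns: {missing}")
        df = data.loc[:, required].copy()
        df["expert_id"] = df["expert_id"].astype(str)
        df["item_id"] = df["item_id"].astype(str)
        df["dimension"] = df["dimension"].astype(str)

        bad_dim = sorted(set(df["dimension"]) - set(DIMENSIONS))
        if bad_dim:
            raise ValueError(f"unknown dimensions {bad_dim}; expected {DIMENSIONS}")
        ratings = pd.to_numeric(df["rating"], errors="raise")
        if not np.all(np.equal(np.mod(ratings, 1), 0)):
            raise ValueError("ratings must be integers")
        df["rating"] = ratings.astype(int)
        bad = sorted(set(df["rating"]) - _RATING_DOMAIN)
        if bad:
            raise ValueError(f"ratings outside 1..5: {bad}")
        dup = df.duplicated(subset=["expert_id", "item_id", "dimension"])
        if dup.any():
            raise ValueError(
                f"duplicate (expert, item, dimension) cells: {df.loc[dup].head().to_dict('records')}"
            )
        self.data = df.reset_index(drop=True)
        self.round_id = round_id

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str, int]],
        round_id: str = "round-1",
    ) -> "RatingPanel":
        df = pd.DataFrame(records, columns=["expert_id", "item_id", "dimension", "rating"])
        return cls(df, round_id=round_id)

    @classmethod
    def from_matrix(
        cls,
        ratings: np.ndarray,
        dimension: str,
        experts: Sequence[str] | None = None,
        items: Sequence[str] | None = None,
        round_id: str = "round-1",
    ) -> "RatingPanel":
        """Build a single-dimension panel from an experts x items array."""
        ratings = np.asarray(ratings)
        m, n = ratings.shape
        experts = list(experts) if experts is not None else [f"E{i+1:02d}" for i in range(m)]
        items = list(items) if items is not None else [f"item{j+1:02d}" for j in range(n)]
        rows = [
            (experts[i], items[j], dimension, int(ratings[i, j]))
            for i in range(m)
            for j in range(n)
            if not np.isnan(float(ratings[i, j]))
        ]
        return cls.from_records(rows, round_id=round_id)

    # -- views -------------------------------------------------------------

    @property
    def experts(self) -> list[str]:
        return sorted(self.data["expert_id"].unique())

    @property
    def items(self) -> list[str]:
        return sorted(self.data["item_id"].unique())

    @property
    def dimensions(self) -> list[str]:
        return [d for d in DIMENSIONS if d in set(self.data["dimension"])]

    def ratings_for(self, item_id: str, dimension: str) -> np.ndarray:
        """All ratings for one (item, dimension), pairwise over experts."""
        self._check_labels(item_id, dimension)
        mask = (self.data["item_id"] == item_id) & (self.data["dimension"] == dimension)
        return self.data.loc[mask, "rating"].to_numpy()

    def ratings_matrix(self, dimension: str, listwise: bool = True) -> pd.DataFrame:
        """Experts x items rating matrix for one dimension.

        With ``listwise=True`` (the convention for concordance statistics)
        experts with any missing rating in the dimension are dropped and the
        removal is logged.
        """
        if dimension not in DIMENSIONS:
            raise IdentificationError(f"unknown dimension {dimension!r}")
        sub = self.data[self.data["dimension"] == dimension]
        if sub.empty:
            raise IdentificationError(f"no ratings for dimension {dimension!r}")
        mat = sub.pivot(index="expert_id", columns="item_id", values="rating")
        mat = mat.reindex(columns=sorted(mat.columns))
        if listwise:
            complete = mat.dropna(axis=0)
            dropped = sorted(set(mat.index) - set(complete.index))
            if dropped:
                logger.info(
                    "%s: listwise removal of %d incomplete expert(s) in %r: %s",
                    self.round_id, len(dropped), dimension, dropped,
                )
            mat = complete
        return mat

    def _check_labels(self, item_id: str, dimension: str) -> None:
        if dimension not in DIMENSIONS:
            raise IdentificationError(f"unknown dimension {dimension!r}")
        if item_id not in set(self.data["item_id"]):
            raise IdentificationError(f"unknown item {item_id!r}")

    def __repr__(self) -> str:
        return (
            f"RatingPanel(round_id={self.round_id!r}, experts={len(self.experts)}, "
            f"items={len(self.items)}, dimensions={self.dimensions})"
        )

    # -- io ----------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def read_ratings_csv(path: str | Path, round_id: str | None = None) -> RatingPanel:
    """Read a long-format ratings CSV into a :class:`RatingPanel`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty ratings file") from exc
    try:
        return RatingPanel(df, round_id=round_id or path.stem)
    except (ValueError, KeyError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


_PROFILE_COLS = {
    "basis_theoretical": "theoretical_analysis",
    "basis_experience": "experience",
    "basis_peer": "peer_understanding",
    "basis_intuition": "intuition",
}


def read_profiles_csv(path: str | Path) -> list[ExpertProfile]:
    """Read an expert-profiles CSV into :class:`ExpertProfile` records."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty profiles file") from exc
    required = ["expert_id", "familiarity", *_PROFILE_COLS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    profiles = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            profiles.append(
                ExpertProfile(
                    expert_id=str(row.expert_id),
                    familiarity_level=int(row.familiarity),
                    judgment_basis={
                        basis: str(getattr(row, col)).strip().lower()
                        for col, basis in _PROFILE_COLS.items()
                    },
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return profiles


def write_profiles_csv(profiles: Sequence[ExpertProfile], path: str | Path) -> None:
    rows = [
        {
            "expert_id": p.expert_id,
            "familiarity": p.familiarity_level,
            **{col: p.judgment_basis[basis] for col, basis in _PROFILE_COLS.items()},
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
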