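"""Per-round Delphi panel statistics and the indicator-retention filter.

Implements the statistics a Delphi round is judged on:

* item descriptives — mean, sample SD, coefficient of variation (CV = SD/mean)
  and the full-score ratio (fraction of experts awarding the maximum rating);
* the expert authority coefficient Cr = (Cs + Ca)/2, where Cs maps the
  self-rated familiarity level to [0, 1] and Ca sums the judgment-basis
  influence coefficients;
* Kendall's coefficient of concordance W with the tie correction,

  .. math:: W = \\frac{12 S}{m^2 (n^3 - n) - m \\sum_i T_i},

  where ``S`` is the sum of squared deviations of item rank-sums from their
  mean and ``T_i = sum(t^3 - t)`` over tie groups within expert ``i``'s
  ranking; its chi-square test uses ``chi2 = m (n - 1) W`` on ``n - 1``
  degrees of freedom;
* the round response rate ("positive coefficient");
* the retention filter: an item survives a round iff, on every dimension,
  its mean is >= 4.0, its full-score ratio exceeds 0.50 and its CV is
  below 0.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from ._rounding import round_half_even
from .errors import (
    ConfigurationError,
    DegenerateRatingsError,
    IdentificationError,
    InsufficientDataError,
)
from .panel import DIMENSIONS, INFLUENCE_LEVELS, JUDGMENT_BASES, ExpertProfile, RatingPanel

__all__ = [
    "ItemStats",
    "ConcordanceResult",
    "AuthorityResult",
    "FilterCriteria",
    "FilterResult",
    "DEFAULT_CS_MAP",
    "DEFAULT_CA_TABLE",
    "item_stats",
    "panel_item_stats",
    "kendalls_w",
    "chi_square_from_w",
    "authority",
    "authority_coefficient",
    "panel_authority",
    "response_rate",
    "apply_filters",
]

#: Familiarity level -> Cs coefficient (conventional Delphi mapping).
DEFAULT_CS_MAP: Mapping[int, float] = {5: 1.0, 4: 0.8, 3: 0.6, 2: 0.4, 1: 0.2}

#: (basis, influence level) -> Ca contribution (conventional table; sums to
#: at most 1.0 when every basis is at "high").
DEFAULT_CA_TABLE: Mapping[str, Mapping[str, float]] = {
    "theoretical_analysis": {"high": 0.3, "medium": 0.2, "low": 0.1},
    "experience": {"high": 0.5, "medium": 0.4, "low": 0.3},
    "peer_understanding": {"high": 0.1, "medium": 0.1, "low": 0.1},
    "intuition": {"high": 0.1, "medium": 0.1, "low": 0.1},
}


@dataclass(frozen=True)
class ItemStats:
    """Descriptive statistics of one item on one Likert dimension."""

    item_id: str
    dimension: str
    mean: float
    sd: float
    cv: float
    full_score_ratio: float
    n_responses: int


@dataclass(frozen=True)
class ConcordanceResult:
    """Kendall's W and its chi-square test for one dimension."""

    dimension: str
    w: float
    chi_square: float
    df: int
    p_value: float
    n_experts: int
    n_items: int


@dataclass(frozen=True)
class AuthorityResult:
    """One expert's familiarity (Cs), judgment-basis (Ca) and authority (Cr)."""

    expert_id: str
    cs: float
    ca: float
    cr: float


@dataclass(frozen=True)
class FilterCriteria:
    """Retention thresholds for the end-of-round filter.

    ``min_mean`` is inclusive (>=); ``min_full_score_ratio`` and ``max_cv``
    are strict (> and < respectively), following the usual "over 50%" /
    "CV < 0.25" phrasing. Set a threshold to ``None`` to disable it.
    ``combine_mode`` is ``all_dimensions`` (conjunctive, the default) or
    ``any_dimension``.
    """

    min_mean: float | None = 4.0
    min_full_score_ratio: float | None = 0.50
    max_cv: float | None = 0.25
    combine_mode: str = "all_dimensions"

    def __post_init__(self) -> None:
        for name in ("min_mean", "min_full_score_ratio", "max_cv"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.combine_mode not in ("all_dimensions", "any_dimension"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")

    def failure(self, s: ItemStats) -> str | None:
        """First failed criterion for ``s``, or None if all pass."""
        if self.min_mean is not None and s.mean < self.min_mean:
            return f"mean<{self.min_mean}"
        if (
            self.min_full_score_ratio is not None
            and not s.full_score_ratio > self.min_full_score_ratio
        ):
            return f"full_score_ratio<={self.min_full_score_ratio}"
        if self.max_cv is not None and not s.cv < self.max_cv:
            return f"cv>={self.max_cv}"
        return None


@dataclass(frozen=True)
class FilterResult:
    """Outcome of :func:`apply_filters`: retained ids and per-item reasons."""

    retained: tuple[str, ...]
    dropped: Mapping[str, Mapping[str, str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# item descriptives


def item_stats(
    panel: RatingPanel, item_id: str, dimension: str, *, ddof: int = 1
) -> ItemStats:
    """Mean, sample SD, CV and full-score ratio of one item/dimension.

    Missing cells are excluded pairwise. ``ddof=1`` gives the sample SD
    (the Delphi-methodology convention); pass ``ddof=0`` for the population
    SD.
    """
    ratings = panel.ratings_for(item_id, dimension)
    n = ratings.size
    if n < 2:
        raise InsufficientDataError(
            f"item {item_id!r}/{dimension!r}: need >= 2 ratings, got {n}"
        )
    mean = float(np.mean(ratings))
    sd = float(np.std(ratings, ddof=ddof))
    return ItemStats(
        item_id=item_id,
        dimension=dimension,
        mean=mean,
        sd=sd,
        cv=sd / mean,
        full_score_ratio=float(np.count_nonzero(ratings == 5)) / n,
        n_responses=int(n),
    )


def panel_item_stats(
    panel: RatingPanel, dimensions: Sequence[str] | None = None, *, ddof: int = 1
) -> list[ItemStats]:
    """Item descriptives for every item on the requested dimensions."""
    dims = list(dimensions) if dimensions is not None else panel.dimensions
    return [
        item_stats(panel, item, dim, ddof=ddof)
        for dim in dims
        for item in panel.items
    ]


# ---------------------------------------------------------------------------
# concordance


def kendalls_w(panel: RatingPanel, dimension: str) -> ConcordanceResult:
    """Kendall's W (tie-corrected) and its chi-square test for a dimension.

    Experts with incomplete ratings in the dimension are removed listwise
    (logged by :meth:`RatingPanel.ratings_matrix`). Raises
    :class:`DegenerateRatingsError` when every expert rates every item
    identically, where W is 0/0.
    """
    mat = panel.ratings_matrix(dimension, listwise=True)
    m, n = mat.shape
    if m < 2 or n < 2:
        raise InsufficientDataError(
            f"concordance needs >= 2 experts and >= 2 items after listwise "
            f"removal; got {m} x {n} for {dimension!r}"
        )
    values = mat.to_numpy(dtype=float)
    ranks = np.apply_along_axis(sps.rankdata, 1, values)  # average ranks for ties
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    ties = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    denom = m * m * (n**3 - n) - m * ties
    if denom <= 0:
        raise DegenerateRatingsError(
            f"all ratings identical in {dimension!r}: W undefined"
        )
    w = 12.0 * s / denom
    chi_square = chi_square_from_w(w, m, n)
    df = n - 1
    return ConcordanceResult(
        dimension=dimension,
        w=w,
        chi_square=chi_square,
        df=df,
        p_value=float(sps.chi2.sf(chi_square, df)),
        n_experts=m,
        n_items=n,
    )


def chi_square_from_w(w: float, m: int, n: int) -> float:
    """Chi-square statistic ``m (n - 1) W`` of the concordance test."""
    return m * (n - 1) * w


# ---------------------------------------------------------------------------
# authority


def authority_coefficient(cs: float, ca: float) -> float:
    """Authority coefficient: the exact midpoint of Cs and Ca."""
    return (cs + ca) / 2.0


def authority(
    profile: ExpertProfile,
    cs_map: Mapping[int, float] = DEFAULT_CS_MAP,
    ca_table: Mapping[str, Mapping[str, float]] = DEFAULT_CA_TABLE,
) -> AuthorityResult:
    """Cs, Ca and Cr for one expert from the configured coefficient tables."""
    for level in range(1, 6):
        if level not in cs_map:
            raise ConfigurationError(f"cs_map missing familiarity level {level}")
    for basis in JUDGMENT_BASES:
        row = ca_table.get(basis)
        if row is None:
            raise ConfigurationError(f"ca_table missing basis {basis!r}")
        for lvl in INFLUENCE_LEVELS:
            if lvl not in row:
                raise ConfigurationError(f"ca_table[{basis!r}] missing level {lvl!r}")
    cs = float(cs_map[profile.familiarity_level])
    ca = float(
        sum(ca_table[basis][profile.judgment_basis[basis]] for basis in JUDGMENT_BASES)
    )
    return AuthorityResult(
        expert_id=profile.expert_id, cs=cs, ca=ca, cr=authority_coefficient(cs, ca)
    )


def panel_authority(
    profiles: Iterable[ExpertProfile],
    cs_map: Mapping[int, float] = DEFAULT_CS_MAP,
    ca_table: Mapping[str, Mapping[str, float]] = DEFAULT_CA_TABLE,
) -> dict[str, float]:
    """Panel means and SDs of Cs, Ca, Cr (the round's Table-2-style summary)."""
    results = [authority(p, cs_map, ca_table) for p in profiles]
    if not results:
        raise InsufficientDataError("no profiles supplied")
    out: dict[str, float] = {"n_experts": len(results)}
    for name in ("cs", "ca", "cr"):
        vals = np.array([getattr(r, name) for r in results])
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return out


# ---------------------------------------------------------------------------
# response rate and filtering


def response_rate(invited: int, returned: int) -> float:
    """Round response rate as a percentage rounded to two decimals."""
    if invited <= 0:
        raise ValueError(f"invited must be positive, got {invited}")
    if not 0 < returned <= invited:
        raise ValueError(f"returned must satisfy 0 < returned <= invited ({invited})")
    return round_half_even(100.0 * returned / invited, 2)


def apply_filters(
    stats: Iterable[ItemStats], criteria: FilterCriteria = FilterCriteria()
) -> FilterResult:
    """Apply the retention filter to per-item, per-dimension descriptives.

    Under ``all_dimensions`` each item must pass every criterion on every
    one of the three dimensions and the first failed criterion per dimension
    is recorded; under ``any_dimension`` one fully passing dimension
    suffices. Retention is deterministic and items are reported in sorted
    order.
    """
    by_item: dict[str, dict[str, ItemStats]] = {}
    for s in stats:
        by_item.setdefault(s.item_id, {})[s.dimension] = s

    retained: list[str] = []
    dropped: dict[str, dict[str, str]] = {}
    for item_id in sorted(by_item):
        dims = by_item[item_id]
        if criteria.combine_mode == "all_dimensions":
            missing = [d for d in DIMENSIONS if d not in dims]
            if missing:
                raise InsufficientDataError(
                    f"item {item_id!r} lacks stats for dimensions {missing}"
                )
            reasons = {
                d: reason
                for d in DIMENSIONS
                if (reason := criteria.failure(dims[d])) is not None
            }
            if reasons:
                dropped[item_id] = reasons
            else:
                retained.append(item_id)
        else:  # any_dimension
            failures = {}
            passed = False
            for d, s in dims.items():
                reason = criteria.failure(s)
                if reason is None:
                    passed = True
                    break
                failures[d] = reason
            if passed:
                retained.append(item_id)
            else:
                dropped[item_id] = failures
    return FilterResult(retained=tuple(retained), dropped=dropped)


def relax(criteria: FilterCriteria, **changes: float | None) -> FilterCriteria:
    """Return a copy of ``criteria`` with thresholds replaced."""
    return replace(criteria, **changes)
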