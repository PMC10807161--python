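"""Seeded generators for panels, profiles and patient cohorts.

Every generator draws from a single :class:`numpy.random.Generator` seeded
explicitly, so identical seeds give identical outputs on any platform and
no global random state is touched.

The panel generator uses a consensus mixture model: each expert adopts a
common latent ordering of item quality with probability ``consensus`` and
an independent random ordering otherwise, then reports the latent quality
plus centered Gaussian noise discretized to the 1..5 Likert scale. The one
knob ``consensus`` maps monotonically (in expectation) onto Kendall's W:
0 is the null of independent rankings, 1 is perfect agreement.

Defaults mirror the consultation the package models: 23 experts rating 47
candidate indicators on three dimensions, with a familiarity split of
5 / 15 / 3 experts at levels 5 / 4 / 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import IdentificationError
from .instrument import InstrumentSpec, PatientRecord
from .panel import DIMENSIONS, INFLUENCE_LEVELS, JUDGMENT_BASES, ExpertProfile, RatingPanel

__all__ = [
    "PanelModel",
    "CohortModel",
    "DEFAULT_FAMILIARITY_DIST",
    "DEFAULT_BASIS_DIST",
    "simulate_panel",
    "simulate_profiles",
    "simulate_cohort",
]

#: Familiarity-level frequencies of the emulated 23-expert panel
#: (5 "very familiar", 15 "familiar", 3 "commonly familiar").
DEFAULT_FAMILIARITY_DIST: Mapping[int, float] = {5: 5 / 23, 4: 15 / 23, 3: 3 / 23}

#: Influence-level frequencies per judgment basis; senior panels lean on
#: theory and first-hand experience, giving Ca around 0.9.
DEFAULT_BASIS_DIST: Mapping[str, Mapping[str, float]] = {
    "theoretical_analysis": {"high": 0.7, "medium": 0.2, "low": 0.1},
    "experience": {"high": 0.8, "medium": 0.15, "low": 0.05},
    "peer_understanding": {"high": 0.3, "medium": 0.4, "low": 0.3},
    "intuition": {"high": 0.2, "medium": 0.3, "low": 0.5},
}


@dataclass(frozen=True)
class PanelModel:
    """Generator settings for one simulated consultation round.

    ``latent_quality`` defaults to an even spread over [2.8, 4.9], so at
    full consensus and no noise a majority — not all — of the items clear a
    mean-4.0 retention bar, as in a real late-round panel.
    """

    m_experts: int = 23
    n_items: int = 47
    consensus: float = 0.7
    noise_sd: float = 0.8
    latent_quality: tuple[float, ...] | None = None
    dimensions: tuple[str, ...] = DIMENSIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_experts < 2 or self.n_items < 2:
            raise ValueError("need at least 2 experts and 2 items")
        if not 0.0 <= self.consensus <= 1.0:
            raise ValueError(f"consensus must lie in [0, 1], got {self.consensus}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.latent_quality is not None and len(self.latent_quality) != self.n_items:
            raise ValueError("latent_quality must have one value per item")

    def qualities(self) -> np.ndarray:
        if self.latent_quality is not None:
            return np.asarray(self.latent_quality, dtype=float)
        return np.linspace(2.8, 4.9, self.n_items)


@dataclass(frozen=True)
class CohortModel:
    """Generator settings for a synthetic patient cohort."""

    n_patients: int = 1000
    prevalence: Mapping[str, float] = field(default_factory=dict)
    default_prevalence: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for ind, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {ind!r} must lie in [0, 1], got {p}")


def simulate_panel(model: PanelModel) -> RatingPanel:
    """Draw one round of Likert ratings under the consensus mixture model.

    For each (expert, dimension) the expert follows the common latent item
    qualities with probability ``consensus``, otherwise a random permutation
    of them; ratings are quality + N(0, noise_sd), rounded and clamped to
    1..5. At ``consensus=1, noise_sd=0`` all experts rank identically and
    Kendall's W is exactly 1.
    """
    rng = np.random.default_rng(model.seed)
    q = model.qualities()
    experts = [f"E{i + 1:02d}" for i in range(model.m_experts)]
    items = [f"item{j + 1:02d}" for j in range(model.n_items)]
    rows = []
    for expert in experts:
        for dim in model.dimensions:
            follows = rng.random() < model.consensus
            base = q if follows else rng.permutation(q)
            noisy = base + (rng.normal(0.0, model.noise_sd, size=q.size)
                            if model.noise_sd > 0 else 0.0)
            ratings = np.clip(np.rint(noisy), 1, 5).astype(int)
            rows.extend(
                (expert, item, dim, int(r)) for item, r in zip(items, ratings)
            )
    return RatingPanel.from_records(rows, round_id=f"simulated-seed{model.seed}")


def _draw_from(dist: Mapping, rng: np.random.Generator, size: int) -> list:
    keys = list(dist)
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-9):
        raise ValueError(f"distribution must sum to 1, got {probs.sum()}")
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def _quota_counts(dist: Mapping, m: int) -> dict:
    """Largest-remainder apportionment of m draws to the distribution."""
    keys = list(dist)
    exact = np.asarray([dist[k] * m for k in keys], dtype=float)
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[: m - counts.sum()]:
        counts[i] += 1
    return dict(zip(keys, counts))


def simulate_profiles(
    m: int,
    familiarity_dist: Mapping[int, float] = DEFAULT_FAMILIARITY_DIST,
    basis_dist: Mapping[str, Mapping[str, float]] = DEFAULT_BASIS_DIST,
    seed: int = 0,
    quota: bool = False,
) -> list[ExpertProfile]:
    """Draw expert profiles from familiarity and judgment-basis distributions.

    With ``quota=True`` familiarity counts follow largest-remainder quotas
    (e.g. exactly 5/15/3 at m=23 under the default split) instead of
    independent draws; judgment bases are always drawn independently.
    """
    rng = np.random.default_rng(seed)
    if quota:
        counts = _quota_counts(familiarity_dist, m)
        levels = [lvl for lvl, c in counts.items() for _ in range(c)]
        rng.shuffle(levels)
    else:
        levels = _draw_from(familiarity_dist, rng, m)
    basis_draws = {
        basis: _draw_from(basis_dist[basis], rng, m) for basis in JUDGMENT_BASES
    }
    return [
        ExpertProfile(
            expert_id=f"E{i + 1:02d}",
            familiarity_level=int(levels[i]),
            judgment_basis={basis: basis_draws[basis][i] for basis in JUDGMENT_BASES},
        )
        for i in range(m)
    ]


def simulate_cohort(model: CohortModel, spec: InstrumentSpec) -> list[PatientRecord]:
    """Draw patient indicator flags with per-indicator prevalences.

    Ungrouped indicators are independent Bernoulli draws. Members of an
    exclusivity group are sampled jointly so at most one is present: a
    single uniform draw walks the members in descending score magnitude,
    each claiming an interval of its own prevalence (capped at total mass
    1), so degenerate all-ones prevalences deterministically select the
    highest-scoring member.
    """
    ids = spec.indicator_ids
    unknown = sorted(set(model.prevalence) - set(ids))
    if unknown:
        raise IdentificationError(f"prevalence given for unknown indicators {unknown}")
    prev = {i: model.prevalence.get(i, model.default_prevalence) for i in ids}
    rng = np.random.default_rng(model.seed)
    scores = spec.score_map

    grouped: set[str] = set()
    group_order: dict[str, list[str]] = {}
    for group, members in spec.exclusivity_groups.items():
        grouped.update(members)
        group_order[group] = sorted(
            members, key=lambda i: (abs(scores[i]), ids.index(i)), reverse=True
        )

    records = []
    for k in range(model.n_patients):
        flags: dict[str, bool] = {}
        for ind in ids:
            if ind not in grouped:
                flags[ind] = bool(rng.random() < prev[ind])
        for group, members in group_order.items():
            u = rng.random()
            acc = 0.0
            chosen = None
            for member in members:
                acc = min(acc + prev[member], 1.0)
                if u < acc:
                    chosen = member
                    break
            for member in members:
                flags[member] = member == chosen
        records.append(PatientRecord(patient_id=f"P{k + 1:05d}", flags=flags))
    return records
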