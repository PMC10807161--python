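"""Delphi round statistics: descriptives, concordance, authority, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from vterisk import (
    DEFAULT_CA_TABLE,
    DEFAULT_CS_MAP,
    ExpertProfile,
    FilterCriteria,
    ItemStats,
    RatingPanel,
    apply_filters,
    authority,
    chi_square_from_w,
    item_stats,
    kendalls_w,
    panel_authority,
    panel_item_stats,
    response_rate,
)
from vterisk.errors import (
    ConfigurationError,
    DegenerateRatingsError,
    IdentificationError,
    InsufficientDataError,
)


def panel_of(ratings, dimension="necessity"):
    return RatingPanel.from_matrix(np.asarray(ratings), dimension)


def full_profile(familiarity=5, level="high"):
    return ExpertProfile(
        expert_id="E01",
        familiarity_level=familiarity,
        judgment_basis={b: level for b in DEFAULT_CA_TABLE},
    )


# ---------------------------------------------------------------------------
# item descriptives


@pytest.mark.parametrize(
    "ratings, mean, sd, cv, fsr",
    [
        ([4, 4, 4, 4], 4.0, 0.0, 0.0, 0.0),  # zero variance
        ([5, 4, 3], 4.0, 1.0, 0.25, 1 / 3),  # hand-computed sample SD
        ([5, 5, 5, 5], 5.0, 0.0, 0.0, 1.0),  # unanimous full score
    ],
)
def test_item_stats_descriptives(ratings, mean, sd, cv, fsr):
    panel = panel_of([[r] for r in ratings])
    s = item_stats(panel, "item01", "necessity")
    assert s.mean == pytest.approx(mean)
    assert s.sd == pytest.approx(sd)
    assert s.cv == pytest.approx(cv)
    assert s.full_score_ratio == pytest.approx(fsr)
    assert s.n_responses == len(ratings)


def test_item_stats_population_sd_option():
    panel = panel_of([[5], [4], [3]])
    s = item_stats(panel, "item01", "necessity", ddof=0)
    assert s.sd == pytest.approx(np.std([5, 4, 3]))


def test_item_stats_unknown_labels_and_insufficient_data():
    panel = panel_of([[4, 5], [4, 4]])
    with pytest.raises(IdentificationError):
        item_stats(panel, "nope", "necessity")
    with pytest.raises(IdentificationError):
        item_stats(panel, "item01", "beauty")
    single = RatingPanel.from_records([("E1", "i1", "necessity", 4)])
    with pytest.raises(InsufficientDataError):
        item_stats(single, "i1", "necessity")


def test_cv_is_scale_free_on_real_valued_core(rng):
    # CV = sd/mean is invariant under positive rescaling of the ratings.
    x = rng.uniform(1, 5, size=40)
    cv = np.std(x, ddof=1) / np.mean(x)
    cv_scaled = np.std(3.7 * x, ddof=1) / np.mean(3.7 * x)
    assert cv_scaled == pytest.approx(cv, rel=1e-12)


def test_rating_domain_enforced():
    with pytest.raises(ValueError):
        RatingPanel.from_records([("E1", "i1", "necessity", 6)])
    with pytest.raises(ValueError):
        RatingPanel.from_records([("E1", "i1", "necessity", 0)])


# ---------------------------------------------------------------------------
# Kendall's W


def test_w_is_one_for_identical_rankings():
    panel = panel_of([[1, 2, 4, 5]] * 3)
    res = kendalls_w(panel, "necessity")
    assert res.w == pytest.approx(1.0)
    assert res.df == 3
    assert res.chi_square == pytest.approx(chi_square_from_w(1.0, 3, 4))


def test_w_is_zero_for_exactly_reversed_rankings():
    panel = panel_of([[1, 3, 5], [5, 3, 1]])
    res = kendalls_w(panel, "necessity")
    assert res.w == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_w_matches_friedman_oracle_with_ties(rng):
    """Tie-corrected W agrees with scipy's Friedman statistic / (m (n-1))."""
    for _ in range(25):
        m = int(rng.integers(3, 9))
        n = int(rng.integers(3, 9))
        ratings = rng.integers(1, 6, size=(m, n))
        if np.all(ratings == ratings[0, 0]):
            continue
        panel = panel_of(ratings)
        try:
            res = kendalls_w(panel, "necessity")
        except DegenerateRatingsError:
            continue
        friedman = sps.friedmanchisquare(*ratings.T.tolist()).statistic
        assert res.chi_square == pytest.approx(friedman, rel=1e-10)
        assert res.w == pytest.approx(friedman / (m * (n - 1)), rel=1e-10)


def test_w_bounds_and_relabeling_invariance(rng):
    for _ in range(20):
        m, n = int(rng.integers(2, 8)), int(rng.integers(2, 8))
        ratings = rng.integers(1, 6, size=(m, n))
        panel = panel_of(ratings)
        try:
            w = kendalls_w(panel, "necessity").w
        except DegenerateRatingsError:
            continue
        assert 0.0 <= w <= 1.0 + 1e-12
        shuffled = ratings[rng.permutation(m)][:, rng.permutation(n)]
        assert kendalls_w(panel_of(shuffled), "necessity").w == pytest.approx(w)


def test_w_degenerate_panel_raises():
    panel = panel_of(np.full((3, 4), 4))
    with pytest.raises(DegenerateRatingsError):
        kendalls_w(panel, "necessity")


def test_w_listwise_removal_of_incomplete_expert():
    rows = [("E1", f"i{j}", "necessity", j + 1) for j in range(4)]
    rows += [("E2", f"i{j}", "necessity", j + 1) for j in range(4)]
    rows += [("E3", "i0", "necessity", 5)]  # incomplete expert
    res = kendalls_w(RatingPanel.from_records(rows), "necessity")
    assert res.n_experts == 2
    assert res.w == pytest.approx(1.0)


def test_untied_chi_square_identity(rng):
    """Without ties (each expert's ratings a permutation of 1..5), the
    tie-correction term vanishes and chi2 = m (n-1) W exactly."""
    ratings = np.vstack([rng.permutation([1, 2, 3, 4, 5]) for _ in range(4)])
    res = kendalls_w(panel_of(ratings), "necessity")
    assert res.chi_square == pytest.approx(4 * (5 - 1) * res.w, rel=1e-12)


# ---------------------------------------------------------------------------
# authority


def test_authority_maximal_profile_gives_cr_one():
    res = authority(full_profile(5, "high"))
    assert (res.cs, res.ca, res.cr) == (1.0, 1.0, 1.0)


def test_authority_uses_configured_tables():
    res = authority(full_profile(3, "low"))
    assert res.cs == pytest.approx(DEFAULT_CS_MAP[3])
    assert res.ca == pytest.approx(0.1 + 0.3 + 0.1 + 0.1)
    assert res.cr == pytest.approx((res.cs + res.ca) / 2)


def test_authority_missing_table_entry_is_configuration_error():
    with pytest.raises(ConfigurationError):
        authority(full_profile(), cs_map={5: 1.0})
    broken = {b: dict(v) for b, v in DEFAULT_CA_TABLE.items()}
    del broken["experience"]["low"]
    with pytest.raises(ConfigurationError):
        authority(full_profile(), ca_table=broken)


def test_panel_authority_means_are_linear(rng):
    profiles = [
        ExpertProfile(
            expert_id=f"E{i}",
            familiarity_level=int(rng.integers(1, 6)),
            judgment_basis={
                b: ["high", "medium", "low"][rng.integers(0, 3)]
                for b in DEFAULT_CA_TABLE
            },
        )
        for i in range(15)
    ]
    summary = panel_authority(profiles)
    # mean Cr is the exact midpoint of mean Cs and mean Ca
    assert summary["cr_mean"] == pytest.approx(
        (summary["cs_mean"] + summary["ca_mean"]) / 2, rel=1e-12
    )


# ---------------------------------------------------------------------------
# response rate and filter


@pytest.mark.parametrize(
    "invited, returned, expected",
    [(27, 23, 85.19), (23, 19, 82.61), (10, 10, 100.00)],
)
def test_response_rate(invited, returned, expected):
    assert response_rate(invited, returned) == pytest.approx(expected)


def test_response_rate_domain_errors():
    with pytest.raises(ValueError):
        response_rate(10, 11)
    with pytest.raises(ValueError):
        response_rate(0, 0)


def make_stats(item, mean=4.2, fsr=0.55, cv=0.20):
    return [
        ItemStats(item, dim, mean=mean, sd=cv * mean, cv=cv,
                  full_score_ratio=fsr, n_responses=20)
        for dim in ("necessity", "importance", "operability")
    ]


def test_filter_retains_passing_item_and_reports_first_failure():
    stats = make_stats("good") + [
        ItemStats("bad", "necessity", 3.9, 0.4, 0.1, 0.6, 20),
        ItemStats("bad", "importance", 4.5, 0.4, 0.09, 0.6, 20),
        ItemStats("bad", "operability", 4.5, 0.4, 0.09, 0.6, 20),
    ]
    result = apply_filters(stats, FilterCriteria())
    assert result.retained == ("good",)
    assert result.dropped["bad"] == {"necessity": "mean<4.0"}


def test_filter_boundary_inequalities_brute_force():
    """Boundary grid: mean inclusive, full-score and CV strict."""
    criteria = FilterCriteria()
    for mean in (3.99, 4.0, 4.01):
        for fsr in (0.49, 0.50, 0.51):
            for cv in (0.24, 0.25, 0.26):
                result = apply_filters(make_stats("x", mean, fsr, cv), criteria)
                expected = mean >= 4.0 and fsr > 0.50 and cv < 0.25
                assert (result.retained == ("x",)) is expected, (mean, fsr, cv)


def test_filter_missing_dimension_errors():
    stats = make_stats("x")[:2]
    with pytest.raises(InsufficientDataError):
        apply_filters(stats, FilterCriteria())


def test_filter_any_dimension_mode():
    stats = [
        ItemStats("x", "necessity", 3.0, 0.9, 0.3, 0.1, 20),
        ItemStats("x", "importance", 4.8, 0.3, 0.0625, 0.8, 20),
    ]
    result = apply_filters(stats, FilterCriteria(combine_mode="any_dimension"))
    assert result.retained == ("x",)


@given(
    mean=st.floats(3.0, 5.0),
    fsr=st.floats(0.0, 1.0),
    cv=st.floats(0.0, 0.5),
    loosen=st.floats(0.0, 0.5),
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_filter_monotone_under_relaxation(mean, fsr, cv, loosen):
    """Relaxing any threshold never drops a previously retained item."""
    stats = make_stats("x", mean, fsr, cv)
    strict = FilterCriteria()
    relaxed = FilterCriteria(
        min_mean=strict.min_mean - loosen,
        min_full_score_ratio=max(strict.min_full_score_ratio - loosen, 0.0),
        max_cv=strict.max_cv + loosen,
    )
    if apply_filters(stats, strict).retained:
        assert apply_filters(stats, relaxed).retained


def test_panel_item_stats_covers_all_items_and_dimensions(rng):
    panel = RatingPanel.from_records(
        [(f"E{i}", f"i{j}", d, int(rng.integers(1, 6)))
         for i in range(4) for j in range(3)
         for d in ("necessity", "importance", "operability")]
    )
    stats = panel_item_stats(panel)
    assert len(stats) == 9
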