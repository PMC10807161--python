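"""AHP engine: matrices, eigenvector weights, consistency, aggregation."""

import numpy as np
import pytest

from vterisk import (
    JudgmentMatrix,
    RI_TABLES,
    aggregate_matrices,
    consistency,
    evaluate_matrix,
    geometric_mean_weights,
    matrix_from_mean_ratings,
    matrix_from_weights,
    principal_weights,
    validate_matrix,
)
from vterisk.ahp import SAATY_VALUES
from vterisk.errors import ConfigurationError, ConvergenceError, MatrixError


def random_reciprocal(rng, n=3):
    """Random Saaty-scale reciprocal matrix."""
    a = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = rng.choice(SAATY_VALUES)
            a[j, i] = 1.0 / a[i, j]
    return JudgmentMatrix(labels=[f"c{k}" for k in range(n)], values=a)


# ---------------------------------------------------------------------------
# validation


def test_validate_accepts_all_ones_matrix():
    m = JudgmentMatrix(labels=["a", "b", "c"], values=np.ones((3, 3)))
    assert validate_matrix(m).valid


def test_validate_flags_reciprocity_violation_at_position():
    values = [[1, 2, 1], [0.4, 1, 1], [1, 1, 1]]
    report = validate_matrix(JudgmentMatrix(labels=list("abc"), values=values))
    assert not report.valid
    assert any("(2,1)" in v for v in report.violations)


def test_validate_flags_nonpositive_entry():
    values = [[1, -2], [-0.5, 1]]
    report = validate_matrix(JudgmentMatrix(labels=list("ab"), values=values))
    assert not report.valid
    assert any("nonpositive" in v for v in report.violations)


def test_nonsquare_matrix_rejected_at_construction():
    with pytest.raises(MatrixError):
        JudgmentMatrix(labels=["a", "b"], values=np.ones((2, 3)))


# ---------------------------------------------------------------------------
# principal weights


def test_uniform_matrix_gives_uniform_weights():
    res = principal_weights(JudgmentMatrix(labels=list("abcd"), values=np.ones((4, 4))))
    assert res.weights == pytest.approx(np.full(4, 0.25), abs=1e-12)
    assert res.lambda_max == pytest.approx(4.0, abs=1e-9)
    assert res.cr == pytest.approx(0.0, abs=1e-9)


def test_two_by_two_exact():
    res = principal_weights(
        JudgmentMatrix(labels=["a", "b"], values=[[1, 2], [0.5, 1]])
    )
    assert res.weights == pytest.approx([2 / 3, 1 / 3], abs=1e-12)
    assert res.lambda_max == pytest.approx(2.0, abs=1e-12)
    assert res.cr == 0.0  # 2x2 reciprocal matrices are always consistent


def test_consistent_matrix_recovers_target_weights():
    res = principal_weights(matrix_from_weights([0.25, 0.50, 0.25]))
    assert res.weights == pytest.approx([0.25, 0.50, 0.25], abs=1e-12)
    assert res.lambda_max == pytest.approx(3.0, abs=1e-9)


def test_eigenvector_matches_numpy_eig_oracle():
    """Power iteration vs numpy's dense eigensolver on 100 random matrices."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        m = random_reciprocal(rng, n=3)
        res = principal_weights(m)
        eigvals, eigvecs = np.linalg.eig(m.values)
        k = np.argmax(eigvals.real)
        v = np.abs(eigvecs[:, k].real)
        v /= v.sum()
        assert np.max(np.abs(res.weights - v)) <= 1e-9
        assert res.lambda_max == pytest.approx(float(eigvals[k].real), abs=1e-9)


def test_perron_positive_weights_sum_to_one(rng):
    for n in (3, 5, 7):
        m = random_reciprocal(rng, n=n)
        res = principal_weights(m)
        assert np.all(res.weights > 0)
        assert abs(res.weights.sum() - 1.0) < 1e-12
        assert res.lambda_max >= n - 1e-9


def test_geometric_mean_agrees_on_consistent_matrices(rng):
    for _ in range(10):
        w = rng.dirichlet(np.ones(4))
        m = matrix_from_weights(w)
        gm = geometric_mean_weights(m)
        ev = principal_weights(m).weights
        assert gm == pytest.approx(ev, abs=1e-10)


def test_evaluate_matrix_geometric_mean_method(rng):
    m = random_reciprocal(rng, n=4)
    res = evaluate_matrix(m, method="geometric_mean")
    assert abs(res.weights.sum() - 1.0) < 1e-12
    assert res.lambda_max >= 4 - 1e-9


def test_non_convergence_carries_last_iterate():
    m = random_reciprocal(np.random.default_rng(0), n=5)
    with pytest.raises(ConvergenceError) as err:
        principal_weights(m, max_iter=1)
    assert err.value.last_iterate is not None


def test_invalid_matrix_rejected_by_solver():
    bad = JudgmentMatrix(labels=list("ab"), values=[[1, 3], [3, 1]])
    with pytest.raises(MatrixError):
        principal_weights(bad)


# ---------------------------------------------------------------------------
# consistency


def test_consistency_published_therapeutic_matrix():
    ci, cr = consistency(3.0183, 3, "RI_52")
    assert ci == pytest.approx((3.0183 - 3) / 2, abs=1e-12)
    assert round(cr, 4) == pytest.approx(0.0176)


def test_consistency_zero_for_consistent_and_small_matrices():
    assert consistency(3.0, 3) == (0.0, 0.0)
    assert consistency(2.0, 2) == (0.0, 0.0)
    assert consistency(1.0, 1) == (0.0, 0.0)


def test_consistency_order_four_within_printed_rounding():
    _, cr = consistency(4.0610, 4, "RI_52")
    assert 0.0228 <= round(cr, 4) <= 0.0229


def test_consistency_table_variants_differ():
    _, cr52 = consistency(3.0183, 3, "RI_52")
    _, cr58 = consistency(3.0183, 3, "RI_SAATY")
    assert cr52 == pytest.approx(cr58 * 0.58 / 0.52, rel=1e-9)


def test_ri_tables_nondecreasing_with_zero_head():
    for table in RI_TABLES.values():
        assert table[1] == table[2] == 0.0
        values = [table[n] for n in sorted(table)]
        assert values == sorted(values)


def test_consistency_missing_ri_order_is_configuration_error():
    with pytest.raises(ConfigurationError):
        consistency(10.5, 10, "RI_52")
    with pytest.raises(ConfigurationError):
        consistency(3.1, 3, "NO_SUCH_TABLE")


# ---------------------------------------------------------------------------
# constructors and aggregation


def test_ratio_matrix_from_equal_weights_is_all_ones():
    m = matrix_from_weights([0.5, 0.5])
    assert m.values == pytest.approx(np.ones((2, 2)))


def test_ratio_matrix_entries_and_round_trip():
    m = matrix_from_weights([0.25, 0.50, 0.25])
    assert m.values[0, 1] == pytest.approx(0.5)
    assert m.values[0, 2] == pytest.approx(1.0)
    assert m.values[1, 2] == pytest.approx(2.0)
    assert principal_weights(m).cr == pytest.approx(0.0, abs=1e-12)


def test_ratio_matrix_rejects_nonpositive_weights():
    with pytest.raises(ValueError):
        matrix_from_weights([0.5, 0.0, 0.5])


def test_perturbed_matrix_stays_reciprocal_and_inconsistent(rng):
    m = matrix_from_weights([0.2, 0.3, 0.5], perturbation_sd=0.3, seed=11)
    assert validate_matrix(m).valid
    assert principal_weights(m).lambda_max > 3.0


def test_weight_recovery_error_vanishes_with_perturbation(rng):
    truth = np.array([0.2, 0.3, 0.5])
    errors = []
    for sd in (0.0, 0.05, 0.2):
        errs = []
        for seed in range(20):
            m = matrix_from_weights(truth, perturbation_sd=sd, seed=seed)
            errs.append(np.max(np.abs(principal_weights(m).weights - truth)))
        errors.append(np.mean(errs))
    assert errors[0] < 1e-12
    assert errors[0] < errors[1] < errors[2]


def test_aggregate_single_matrix_is_identity(rng):
    m = random_reciprocal(rng)
    agg = aggregate_matrices([m])
    assert agg.values == pytest.approx(m.values)


def test_aggregate_geometric_mean_entry():
    a = matrix_from_weights([2, 1])  # a12 = 2
    b = matrix_from_weights([8, 1])  # a12 = 8
    agg = aggregate_matrices([a, b])
    assert agg.values[0, 1] == pytest.approx(4.0)
    assert validate_matrix(agg).valid


def test_aggregate_preserves_shared_consistency(rng):
    """Aggregating matrices consistent with the same weights stays consistent."""
    w = rng.dirichlet(np.ones(4))
    mats = [matrix_from_weights(w) for _ in range(5)]
    res = principal_weights(aggregate_matrices(mats))
    assert res.weights == pytest.approx(w, abs=1e-10)
    assert res.cr == pytest.approx(0.0, abs=1e-9)


def test_aggregate_label_mismatch_errors():
    a = matrix_from_weights([1, 2], labels=["x", "y"])
    b = matrix_from_weights([1, 2], labels=["y", "x"])
    with pytest.raises(MatrixError):
        aggregate_matrices([a, b])


def test_matrix_from_mean_ratings_with_saaty_snapping():
    m = matrix_from_mean_ratings([4.8, 3.1, 2.2], snap_to_saaty=True)
    assert validate_matrix(m).valid
    off_diag = m.values[np.triu_indices(3, k=1)]
    assert all(any(np.isclose(v, s) for s in SAATY_VALUES) for v in off_diag)
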