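"""Gravity model: coefficient, pairwise values, matrix assembly, binarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthnet.errors import (
    InvalidDistanceError,
    UndefinedCoefficientError,
    ZeroEconomicDistanceError,
)
from healthnet.gravity import binarize, gravity_coefficient, gravity_matrix, gravity_value
from healthnet.types import DistanceMatrix, GravityMatrix, ProvinceRecord, ProvinceTable

REC_I = ProvinceRecord("i", P=100, H=10, G=1000, g=10, R=2)
REC_J = ProvinceRecord("j", P=200, H=20, G=2000, g=20, R=3)


def random_record(name: str, rng: np.random.Generator) -> ProvinceRecord:
    return ProvinceRecord(
        name,
        P=float(rng.uniform(10, 1e5)),
        H=float(rng.uniform(1, 1e4)),
        G=float(rng.uniform(100, 1e6)),
        g=float(rng.uniform(1, 100)),
        R=int(rng.integers(0, 200)),
    )


@pytest.mark.parametrize(
    "R_i, R_j, expected",
    [(2, 3, 0.4), (5, 5, 0.5), (7, 0, 1.0), (0, 7, 0.0)],
)
def test_gravity_coefficient(R_i, R_j, expected):
    assert gravity_coefficient(R_i, R_j) == pytest.approx(expected)


def test_gravity_coefficient_undefined_when_no_hospitals():
    with pytest.raises(UndefinedCoefficientError):
        gravity_coefficient(0, 0)


def test_gravity_value_worked_example():
    # cbrt(1e6)=100, cbrt(8e6)=200, (50/-10)^2=25, K=0.4 -> 0.4*100*200/25
    assert gravity_value(REC_I, REC_J, 50) == pytest.approx(320.0)
    assert gravity_value(REC_J, REC_I, 50) == pytest.approx(480.0)


def test_gravity_value_symmetric_when_equal_hospitals():
    a = ProvinceRecord("a", P=100, H=10, G=1000, g=10, R=4)
    b = ProvinceRecord("b", P=100, H=10, G=1000, g=20, R=4)
    assert gravity_value(a, b, 30) == pytest.approx(gravity_value(b, a, 30))


def test_gravity_value_errors():
    same_g = ProvinceRecord("k", P=1, H=1, G=1, g=10, R=1)
    with pytest.raises(ZeroEconomicDistanceError):
        gravity_value(REC_I, same_g, 50)
    # economic-distance floor substitutes an epsilon instead of raising
    assert gravity_value(REC_I, same_g, 50, economic_distance_floor=1e-6) > 0
    with pytest.raises(InvalidDistanceError):
        gravity_value(REC_I, REC_J, 0.0)
    with pytest.raises(InvalidDistanceError):
        gravity_value(REC_I, REC_J, -3.0)


def test_gravity_matrix_two_province_example():
    table = ProvinceTable((REC_I, REC_J))
    D = DistanceMatrix(("i", "j"), np.array([[0.0, 50.0], [50.0, 0.0]]))
    Y = gravity_matrix(table, D)
    np.testing.assert_allclose(Y.values, [[0.0, 320.0], [480.0, 0.0]])


@pytest.mark.parametrize("seed", range(5))
def test_gravity_matrix_reciprocity_and_distance_scaling(seed):
    """Y_ij*R_j == Y_ji*R_i elementwise, and scaling all distances by c
    scales every gravity value by 1/c^2."""
    rng = np.random.default_rng(seed)
    n = 8
    table = ProvinceTable(tuple(random_record(f"p{k}", rng) for k in range(n)))
    xy = rng.uniform(size=(n, 2))
    dvals = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
    D = DistanceMatrix(table.names, dvals)
    Y = gravity_matrix(table, D)
    R = np.array([r.R for r in table], dtype=float)
    np.testing.assert_allclose(Y.values * R[None, :], (Y.values * R[None, :]).T, rtol=1e-9)
    c = 3.7
    Y2 = gravity_matrix(table, DistanceMatrix(table.names, c * dvals))
    np.testing.assert_allclose(Y2.values, Y.values / c**2, rtol=1e-9)


def test_gravity_matrix_permutation_equivariance():
    rng = np.random.default_rng(7)
    n = 6
    table = ProvinceTable(tuple(random_record(f"p{k}", rng) for k in range(n)))
    xy = rng.uniform(size=(n, 2))
    dvals = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
    Y = gravity_matrix(table, DistanceMatrix(table.names, dvals))
    perm = rng.permutation(n)
    table_p = ProvinceTable(tuple(table.records[i] for i in perm))
    Yp = gravity_matrix(
        table_p, DistanceMatrix(table_p.names, dvals[np.ix_(perm, perm)])
    )
    np.testing.assert_allclose(Yp.values, Y.values[np.ix_(perm, perm)], rtol=1e-12)


def test_reciprocity_identity_many_random_pairs():
    """K_ij + K_ji = 1 and Y_ij*R_j = Y_ji*R_i on 1000 random pairs."""
    rng = np.random.default_rng(99)
    for _ in range(1000):
        a = random_record("a", rng)
        b = random_record("b", rng)
        if a.R + b.R == 0 or a.g == b.g:
            continue
        d = float(rng.uniform(0.1, 1000))
        assert gravity_coefficient(a.R, b.R) + gravity_coefficient(b.R, a.R) == pytest.approx(1.0)
        assert gravity_value(a, b, d) * b.R == pytest.approx(
            gravity_value(b, a, d) * a.R, rel=1e-9
        )


def test_binarize_row_mean_rule():
    values = np.array(
        [
            [0.0, 320.0, 100.0, 60.0],  # mean 160 -> [1, 0, 0]
            [10.0, 0.0, 10.0, 10.0],    # all equal -> all 1 (>= rule)
            [5.0, 1.0, 0.0, 3.0],       # mean 3 -> [1, 0, 1]
            [9.0, 2.0, 1.0, 0.0],       # mean 4 -> [1, 0, 0]
        ]
    )
    A = binarize(GravityMatrix(("a", "b", "c", "d"), values))
    expected = np.array(
        [[0, 1, 0, 0], [1, 0, 1, 1], [1, 0, 0, 1], [1, 0, 0, 0]]
    )
    np.testing.assert_array_equal(A.values, expected)


def test_binarize_two_by_two_keeps_both_arcs():
    Y = GravityMatrix(("a", "b"), np.array([[0.0, 5.0], [2.0, 0.0]]))
    np.testing.assert_array_equal(binarize(Y).values, [[0, 1], [1, 0]])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.lists(st.floats(0.01, 1e6), min_size=5, max_size=5),
        min_size=5,
        max_size=5,
    ),
    st.floats(0.1, 100.0),
    st.integers(0, 4),
)
def test_binarize_invariant_to_row_scaling(rows, c, row):
    """Multiplying one whole row of Y by a positive constant cannot change
    the binarized network (the row benchmark scales with it)."""
    values = np.array(rows)
    np.fill_diagonal(values, 0.0)
    names = tuple("abcde")
    base = binarize(GravityMatrix(names, values))
    scaled = values.copy()
    scaled[row] *= c
    np.testing.assert_array_equal(
        binarize(GravityMatrix(names, scaled)).values, base.values
    )


def test_binarize_every_active_row_keeps_an_arc():
    rng = np.random.default_rng(3)
    values = rng.uniform(0.1, 10.0, size=(9, 9))
    np.fill_diagonal(values, 0.0)
    A = binarize(GravityMatrix(tuple(f"p{i}" for i in range(9)), values))
    assert (A.values.sum(axis=1) >= 1).all()
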