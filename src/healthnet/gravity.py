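"""The modified gravity model and its binarization into a directed network.

The attraction exerted between two provinces combines three ingredients:

* an asymmetric *gravity coefficient* ``K_ij = R_i / (R_i + R_j)`` that
  splits each pair's interaction by relative tertiary-hospital endowment
  (so ``K_ij + K_ji = 1``);
* the provinces' "masses", each the cube root of the product of medical
  visits, health expenditure and GDP, ``cbrt(P*H*G)``;
* a squared composite distance ``(D_ij / (g_i - g_j))**2`` that shrinks
  attraction with geographic distance and grows it with the economic gap
  between the provinces (the sign of ``g_i - g_j`` is irrelevant because
  the term is squared).

The directed gravity value is

    Y_ij = K_ij * cbrt(P_i H_i G_i) * cbrt(P_j H_j G_j) / (D_ij / (g_i - g_j))**2

and the binary network keeps, in each row i, the arcs whose gravity value
reaches that row's off-diagonal mean (ties count as present).
"""

from __future__ import annotations

import numpy as np

from .errors import (
    InvalidDistanceError,
    UndefinedCoefficientError,
    ZeroEconomicDistanceError,
)
from .types import AdjacencyMatrix, DistanceMatrix, GravityMatrix, ProvinceRecord, ProvinceTable


def gravity_coefficient(R_i: float, R_j: float) -> float:
    """Hospital-endowment share K_ij = R_i / (R_i + R_j), in [0, 1].

    Raises
    ------
    UndefinedCoefficientError
        If both provinces lack tertiary hospitals (R_i + R_j == 0).
    """
    if R_i < 0 or R_j < 0:
        raise UndefinedCoefficientError("hospital counts must be nonnegative")
    total = R_i + R_j
    if total == 0:
        raise UndefinedCoefficientError(
            "K_ij undefined: both provinces have zero tertiary hospitals"
        )
    return R_i / total


def gravity_value(
    record_i: ProvinceRecord,
    record_j: ProvinceRecord,
    D_ij: float,
    *,
    economic_distance_floor: float | None = None,
) -> float:
    """Directed gravity value Y_ij from province i toward province j.

    Parameters
    ----------
    record_i, record_j
        Attribute records of the ordered pair.
    D_ij
        Inter-capital distance (> 0).
    economic_distance_floor
        Optional epsilon substituted for |g_i - g_j| when the two per-capita
        GDPs coincide. Off by default: identical g is an error, because the
        economic-distance denominator vanishes.
    """
    if D_ij <= 0 or not np.isfinite(D_ij):
        raise InvalidDistanceError(
            f"distance between {record_i.name!r} and {record_j.name!r} must be > 0, got {D_ij!r}"
        )
    gap = record_i.g - record_j.g
    if gap == 0:
        if economic_distance_floor is None:
            raise ZeroEconomicDistanceError(
                f"provinces {record_i.name!r} and {record_j.name!r} have identical "
                "GDP per capita; economic distance is zero"
            )
        gap = economic_distance_floor
    K = gravity_coefficient(record_i.R, record_j.R)
    return K * record_i.mass * record_j.mass / (D_ij / gap) ** 2


def gravity_matrix(
    table: ProvinceTable,
    D: DistanceMatrix,
    *,
    economic_distance_floor: float | None = None,
) -> GravityMatrix:
    """Assemble the full directed gravity matrix for a province table.

    The diagonal is zero by convention: self-gravity is undefined (zero
    geographic and economic distance) and is excluded from the row means
    used downstream.
    """
    n = len(table)
    if D.n != n:
        raise InvalidDistanceError(
            f"distance matrix is {D.n}x{D.n} but the table has {n} provinces"
        )
    values = np.zeros((n, n), dtype=float)
    for i, rec_i in enumerate(table):
        for j, rec_j in enumerate(table):
            if i == j:
                continue
            values[i, j] = gravity_value(
                rec_i,
                rec_j,
                float(D.values[i, j]),
                economic_distance_floor=economic_distance_floor,
            )
    return GravityMatrix(table.names, values)


def binarize(Y: GravityMatrix) -> AdjacencyMatrix:
    """Row-mean thresholding of gravity values into a directed 0/1 network.

    For each row i the benchmark t_i is the arithmetic mean of the N-1
    off-diagonal gravity values of that row; m_ij = 1 iff Y_ij >= t_i
    (j != i). Ties meet the benchmark. The diagonal stays 0.
    """
    values = Y.values
    n = Y.n
    off = ~np.eye(n, dtype=bool)
    # mean over the N-1 off-diagonal entries of each row
    thresholds = values.sum(axis=1) / (n - 1)
    m = (values >= thresholds[:, None]) & off
    return AdjacencyMatrix(Y.names, m.astype(int))
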