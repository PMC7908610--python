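"""Synthetic province tables and distance matrices.

The generator emulates the statistical structure of Chinese provincial
health-economy data: right-skewed (log-normal) economic size, health
expenditure and visit volumes coupled to GDP and population, and a
tertiary-hospital count whose mean grows with GDP. Two regimes:

* ``balanced`` — provinces drawn i.i.d., coordinates uniform on the unit
  square;
* ``core_periphery`` — a designated fraction of provinces (the "core",
  default 25%) get their GDP, health expenditure and hospital counts
  multiplied and their capitals clustered, mimicking the east-coast
  concentration of resources; downstream this makes core provinces the
  net attractors of the gravity network.

All draws go through one ``numpy`` Generator, so a seed fixes the output
exactly.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, DegenerateGeometryError, InvalidSizeError
from .types import DistanceMatrix, ProvinceRecord, ProvinceTable

REGIMES = ("balanced", "core_periphery")

# Magnitudes loosely matching 2017 Chinese provincial statistics:
# population in 1e4 persons, GDP in 1e8 CNY, g = G/pop in 1e4 CNY/person.
_POP_LOG_MEAN, _POP_LOG_SD = np.log(3500.0), 0.6
_GDP_LOG_MEAN, _GDP_LOG_SD = np.log(20000.0), 0.8
_HEALTH_SHARE = 0.06          # health expenditure ~ 6% of GDP
_VISITS_PER_CAPITA = 4.5      # outpatient visits per person per year
_HOSPITALS_PER_REF_GDP = 60.0  # mean tertiary hospitals at the reference GDP
_CORE_FRACTION = 0.25
_CORE_MULTIPLIER = 3.0
_CORE_CENTER = (0.75, 0.5)
_CORE_RADIUS = 0.08


def generate_provinces(
    n: int,
    regime: str = "balanced",
    seed: int = 0,
    *,
    core_fraction: float = _CORE_FRACTION,
    core_multiplier: float = _CORE_MULTIPLIER,
) -> ProvinceTable:
    """Draw a synthetic province table.

    Parameters
    ----------
    n
        Number of provinces (>= 2).
    regime
        ``"balanced"`` or ``"core_periphery"``.
    seed
        Seed for the underlying generator; identical seeds reproduce the
        table exactly.
    core_fraction, core_multiplier
        Under ``core_periphery``: share of provinces designated core and
        the factor applied to their G, H and R.

    Notes
    -----
    GDP per capita values are jittered and nudged to be pairwise
    distinct, because the gravity model divides by the economic distance
    g_i - g_j.
    """
    if n < 2:
        raise InvalidSizeError(f"need at least 2 provinces, got {n}")
    if regime not in REGIMES:
        raise ConfigurationError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    rng = np.random.default_rng(seed)

    population = rng.lognormal(_POP_LOG_MEAN, _POP_LOG_SD, size=n)
    G = rng.lognormal(_GDP_LOG_MEAN, _GDP_LOG_SD, size=n)
    H = _HEALTH_SHARE * G * rng.lognormal(0.0, 0.2, size=n)
    P = _VISITS_PER_CAPITA * population * rng.lognormal(0.0, 0.15, size=n)
    g_jitter = rng.lognormal(0.0, 0.01, size=n)
    coords = rng.uniform(0.0, 1.0, size=(n, 2))

    is_core = np.zeros(n, dtype=bool)
    if regime == "core_periphery":
        n_core = max(1, round(core_fraction * n))
        is_core[:n_core] = True
        G = np.where(is_core, core_multiplier * G, G)
        H = np.where(is_core, core_multiplier * H, H)
        angles = rng.uniform(0.0, 2 * np.pi, size=n)
        radii = _CORE_RADIUS * np.sqrt(rng.uniform(0.0, 1.0, size=n))
        core_x = _CORE_CENTER[0] + radii * np.cos(angles)
        core_y = _CORE_CENTER[1] + radii * np.sin(angles)
        coords[is_core, 0] = core_x[is_core]
        coords[is_core, 1] = core_y[is_core]

    lam = _HOSPITALS_PER_REF_GDP * G / np.exp(_GDP_LOG_MEAN)
    R = 1 + rng.poisson(lam)

    g = G / population * g_jitter
    g = _force_distinct(g)

    records = tuple(
        ProvinceRecord(
            name=f"P{i + 1:02d}" + ("c" if is_core[i] else ""),
            P=float(P[i]),
            H=float(H[i]),
            G=float(G[i]),
            g=float(g[i]),
            R=int(R[i]),
            population=float(population[i]),
            x=float(coords[i, 0]),
            y=float(coords[i, 1]),
        )
        for i in range(n)
    )
    return ProvinceTable(records)


def _force_distinct(g: np.ndarray) -> np.ndarray:
    """Nudge per-capita GDP values until pairwise distinct."""
    g = g.astype(float).copy()
    eps = abs(g).mean() * 1e-9
    while len(np.unique(g)) < len(g):
        g = g + eps * np.arange(len(g))
        eps *= 2
    return g


def core_mask(table: ProvinceTable) -> np.ndarray:
    """Boolean mask of core provinces of a generated core_periphery table."""
    return np.array([r.name.endswith("c") for r in table])


def generate_distances(
    table: ProvinceTable, seed: int = 0, *, metric: str = "planar"
) -> DistanceMatrix:
    """Pairwise capital distances for a province table.

    Uses the table's coordinates when present, otherwise draws capitals
    uniformly on the unit square with ``seed``. ``metric`` is
    ``"planar"`` (Euclidean) or ``"haversine"`` (x = longitude and
    y = latitude in degrees; great-circle km on a 6371 km sphere).
    """
    n = len(table)
    if table.has_coordinates():
        xy = np.array([[r.x, r.y] for r in table], dtype=float)
    else:
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0.0, 1.0, size=(n, 2))

    if metric == "planar":
        diff = xy[:, None, :] - xy[None, :, :]
        values = np.sqrt((diff**2).sum(axis=-1))
    elif metric == "haversine":
        lon = np.radians(xy[:, 0])
        lat = np.radians(xy[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        )
        values = 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    else:
        raise ConfigurationError(f"unknown metric {metric!r}")

    np.fill_diagonal(values, 0.0)
    off = ~np.eye(n, dtype=bool)
    zero = np.argwhere(off & (values <= 0))
    if zero.size:
        i, j = zero[0]
        raise DegenerateGeometryError(
            f"provinces {table.names[i]!r} and {table.names[j]!r} share coordinates "
            "(zero inter-capital distance)"
        )
    return DistanceMatrix(table.names, values)
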