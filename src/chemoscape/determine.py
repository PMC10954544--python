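"""Bayesian harvest-location determination on the study grid.

The likelihood of a test chemistry vector at grid cell x is the product of
independent Gaussian densities with the per-variable GP predictive means
and total variances.  Combined with a proximity-restricted uniform prior
(uniform over cells within a fixed great-circle radius of the reference
samples, zero elsewhere) via Bayes' rule, this yields a posterior over grid
cells.  The predicted harvest location is the maximum a-posteriori (MAP)
cell; the credible region is the smallest highest-posterior set of cells
whose mass reaches the nominal level.

All posterior arithmetic is done in log-space with log-sum-exp
normalization: a 20-variable density product underflows in linear space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data_model import StudyGrid

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0  # ~111.195 km per degree of arc


def great_circle_km(a, b) -> np.ndarray | float:
    """Haversine great-circle distance in km between lon/lat points.

    Accepts single points or (n, 2) arrays (broadcast against each other).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    scalar = a.ndim == 1 and b.ndim == 1
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    return float(d[0]) if scalar else d


@dataclass
class PriorMap:
    """Prior probability per grid cell (zero off-support)."""

    grid: StudyGrid
    probs: np.ndarray  # (n_cells,), sums to 1

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.probs > 0)


@dataclass
class PosteriorMap:
    """Normalized posterior over grid cells with its MAP cell."""

    grid: StudyGrid
    probs: np.ndarray  # (n_cells,), sums to 1
    map_cell: int
    log_evidence: float

    @property
    def map_lon(self) -> float:
        return float(self.grid.cell_lon[self.map_cell])

    @property
    def map_lat(self) -> float:
        return float(self.grid.cell_lat[self.map_cell])

    @property
    def map_coords(self) -> np.ndarray:
        return np.array([self.map_lon, self.map_lat])


@dataclass
class CredibleRegion:
    """Highest-posterior set of cells with mass >= the nominal level."""

    grid: StudyGrid
    cells: np.ndarray  # global cell indices, in accumulation order
    mass: float
    level: float

    @property
    def area_km2(self) -> float:
        return cell_areas_km2(self.grid, self.cells).sum()


def cell_areas_km2(grid: StudyGrid, cells: np.ndarray) -> np.ndarray:
    """Spherical-rectangle cell areas: (res * 111.195 km)^2 * cos(lat)."""
    lat = grid.cell_lat[np.asarray(cells, int)]
    side = grid.resolution * KM_PER_DEG
    return side * side * np.cos(np.radians(lat))


def log_likelihood_map(y_star: np.ndarray, ensemble, grid: StudyGrid,
                       standardized: bool = False) -> np.ndarray:
    """Gaussian log-likelihood of the sample at every masked-in cell.

    Returns an array over all grid cells with -inf at masked-out cells.
    Missing variables are skipped.
    """
    y = np.asarray(y_star, float)
    if not standardized:
        y = ensemble.transform(y)
    ok = np.isfinite(y)
    if not ok.any():
        raise ValueError("all chemistry values are missing for this sample")
    active = grid.active
    means, variances = ensemble.predict(grid.coords[active])
    mu = means[:, ok]
    var = variances[:, ok]
    ll_active = -0.5 * np.sum(
        np.log(2.0 * np.pi * var) + (y[None, ok] - mu) ** 2 / var, axis=1
    )
    ll = np.full(grid.n_cells, -np.inf)
    ll[active] = ll_active
    return ll


def build_prior(grid: StudyGrid, reference_coords: np.ndarray, radius_km: float = 300.0) -> PriorMap:
    """Uniform prior over masked cells within ``radius_km`` of the nearest
    reference sample; zero elsewhere."""
    refs = np.atleast_2d(np.asarray(reference_coords, float))
    if len(refs) == 0:
        raise ValueError("need at least one reference coordinate")
    active = grid.active
    centers = grid.coords[active]
    min_d = np.full(len(active), np.inf)
    for ref in refs:
        d = great_circle_km(centers, ref)
        np.minimum(min_d, d, out=min_d)
    support = active[min_d <= radius_km]
    if len(support) == 0:
        raise ValueError(f"no masked grid cells within {radius_km} km of the reference data")
    probs = np.zeros(grid.n_cells)
    probs[support] = 1.0 / len(support)
    return PriorMap(grid, probs)


def uniform_prior(grid: StudyGrid) -> PriorMap:
    """Uniform prior over all masked-in cells (infinite-radius limit)."""
    probs = np.zeros(grid.n_cells)
    probs[grid.active] = 1.0 / grid.n_active
    return PriorMap(grid, probs)


def posterior(log_lik: np.ndarray, prior: PriorMap) -> PosteriorMap:
    """Bayes' rule on the grid, computed with log-sum-exp.

    Cells with zero prior get exactly zero posterior.  The MAP cell is the
    highest-posterior support cell; ties break to the lowest row-major
    index.
    """
    log_lik = np.asarray(log_lik, float)
    support = prior.support
    if len(support) == 0:
        raise ValueError("prior support is empty")
    ls = log_lik[support]
    if not np.any(np.isfinite(ls)):
        raise ValueError("likelihood is zero everywhere on the prior support")
    logpost = ls + np.log(prior.probs[support])
    log_evidence = float(logsumexp(logpost))
    probs = np.zeros(len(log_lik))
    probs[support] = np.exp(logpost - log_evidence)
    map_cell = int(support[np.argmax(probs[support])])
    return PosteriorMap(prior.grid, probs, map_cell, log_evidence)


def credible_region(post: PosteriorMap, level: float = 0.95) -> CredibleRegion:
    """Smallest highest-posterior set of cells with mass >= ``level``.

    Cells are accumulated in descending posterior order (ties by ascending
    row-major index) until the level is reached.
    """
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    p = post.probs
    support = np.flatnonzero(p > 0)
    order = support[np.argsort(-p[support], kind="stable")]
    csum = np.cumsum(p[order])
    k = int(np.searchsorted(csum, level - 1e-12) + 1)
    k = min(k, len(order))
    return CredibleRegion(post.grid, order[:k], float(csum[k - 1]), level)


def uncertainty_map(ensemble, grid: StudyGrid, low_pct: float = 25.0, high_pct: float = 75.0):
    """Per-cell total log-uncertainty with low/high classification.

    The value at each masked cell is sum_j ln(sigma_j^2) (log of the product
    of the predictive variances over all panel variables).  Cells below the
    25th percentile are flagged ``low``, above the 75th ``high``, the rest
    ``mid``.  If the two percentiles coincide (no spread) every cell is
    ``mid``.
    Returns (values, labels): arrays over all cells; masked-out cells carry
    NaN / ``"outside"``.
    """
    active = grid.active
    _, variances = ensemble.predict(grid.coords[active])
    u_active = np.sum(np.log(variances), axis=1)
    values = np.full(grid.n_cells, np.nan)
    values[active] = u_active
    q_low, q_high = np.percentile(u_active, [low_pct, high_pct])
    labels = np.full(grid.n_cells, "outside", dtype=object)
    if q_high > q_low:
        lab = np.where(u_active < q_low, "low", np.where(u_active > q_high, "high", "mid"))
    else:
        lab = np.full(len(active), "mid", dtype=object)
    labels[active] = lab
    return values, labels


def region_metrics(region: CredibleRegion, truth_lonlat) -> tuple[float, bool]:
    """Efficiency (total area in km^2) and coverage flag of a region.

    ``covered`` is True iff the grid cell nearest to the true location
    belongs to the region.
    """
    if len(region.cells) == 0:
        raise ValueError("empty credible region")
    efficiency = float(region.area_km2)
    truth_cell = region.grid.cell_index(*np.asarray(truth_lonlat, float))
    covered = bool(truth_cell in set(region.cells.tolist()))
    return efficiency, covered
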