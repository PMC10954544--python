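"""Synthetic worlds: Matérn random chemistry fields, clustered field-sampling
designs, synthetic territories, and oracle experiment drivers.

The real reference data are not redistributable, so every experiment in this
package runs against synthetic worlds: per-variable Gaussian random fields
drawn from the same Matérn model class the regression assumes, sampled with
the field protocol's clustered design (trees grouped within ~50 km, clusters
spaced 100-250 km apart).  Every artifact is a pure function of its
parameters and seed.

``make_table1_fixture`` reproduces the reference collection's per-country,
per-genus sample COUNTS exactly; its coordinates and chemistry are entirely
synthetic and must never be mistaken for the real measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    ChemistryPanel,
    RegionSet,
    SampleTable,
    StudyGrid,
    build_study_grid,
    default_panel,
)
from .determine import great_circle_km, posterior, credible_region, PriorMap
from .gp_field import kernel_matrix
from .verify import territory_pvalue

MAX_SIM_CELLS = 5000  # dense-Cholesky field simulation cap

#: Reference-collection sample counts per country and genus (total 929).
TABLE1_COUNTS: dict[str, dict[str, int]] = {
    "Belarus":   {"Betula": 20, "Fagus": 0,  "Pinus": 0,  "Quercus": 10},
    "Croatia":   {"Betula": 20, "Fagus": 60, "Pinus": 30, "Quercus": 57},
    "Estonia":   {"Betula": 50, "Fagus": 0,  "Pinus": 0,  "Quercus": 10},
    "Finland":   {"Betula": 30, "Fagus": 0,  "Pinus": 36, "Quercus": 0},
    "Hungary":   {"Betula": 10, "Fagus": 16, "Pinus": 13, "Quercus": 49},
    "Latvia":    {"Betula": 56, "Fagus": 0,  "Pinus": 0,  "Quercus": 4},
    "Lithuania": {"Betula": 0,  "Fagus": 0,  "Pinus": 65, "Quercus": 34},
    "Moldova":   {"Betula": 0,  "Fagus": 0,  "Pinus": 0,  "Quercus": 51},
    "Romania":   {"Betula": 12, "Fagus": 35, "Pinus": 0,  "Quercus": 10},
    "Russia":    {"Betula": 24, "Fagus": 0,  "Pinus": 0,  "Quercus": 0},
    "Slovakia":  {"Betula": 20, "Fagus": 20, "Pinus": 0,  "Quercus": 9},
    "Ukraine":   {"Betula": 60, "Fagus": 88, "Pinus": 30, "Quercus": 0},
}

#: Study-area bounding box of the reference collection (degrees).
STUDY_BBOX = (15.0, 39.5, 46.0, 68.3)


@dataclass
class SyntheticWorld:
    """A known ground-truth world: true mean fields plus noise levels.

    ``fields`` holds the latent mean surface per masked cell and variable;
    observed chemistry is field value plus independent Gaussian noise with
    sd ``noise_sd``.
    """

    grid: StudyGrid
    panel: ChemistryPanel
    fields: np.ndarray     # (n_active, m) true mean per masked cell
    noise_sd: np.ndarray   # (m,)
    lengthscales: np.ndarray  # (m, 2) generating kernel lengthscales (deg)
    signal_var: np.ndarray    # (m,)
    nu: float
    seed: int

    @property
    def m(self) -> int:
        return self.panel.m

    def field_at_cells(self, cells: np.ndarray) -> np.ndarray:
        """True mean chemistry at global cell indices (must be masked-in)."""
        pos = np.searchsorted(self.grid.active, np.asarray(cells, int))
        if not np.array_equal(self.grid.active[pos], np.asarray(cells, int)):
            raise ValueError("cells must be masked-in grid cells")
        return self.fields[pos]

    def observe(self, cells: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw noisy chemistry observations at the given cells."""
        f = self.field_at_cells(np.asarray(cells, int))
        return f + rng.standard_normal(f.shape) * self.noise_sd[None, :]


class OracleEnsemble:
    """Predictive model equal to the generating world: means are the true
    fields, variances the true noise variances.  Used to test statistical
    guarantees free of GP fitting error.  Shares the prediction interface
    of :class:`~chemoscape.gp_field.FieldModelEnsemble`; chemistry is taken
    as-is (no standardization)."""

    def __init__(self, world: SyntheticWorld):
        self.world = world
        self.panel = world.panel
        self.standardizer = None

    @property
    def m(self) -> int:
        return self.panel.m

    def transform(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, float)

    def predict(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        coords = np.asarray(coords, float).reshape(-1, 2)
        grid = self.world.grid
        cells = grid.nearest_cells(coords)
        # snap to the nearest ACTIVE cell where the direct lookup is masked out
        active = grid.active
        pos = np.searchsorted(active, cells)
        pos = np.clip(pos, 0, len(active) - 1)
        miss = active[pos] != cells
        if miss.any():
            from scipy.spatial import cKDTree

            tree = cKDTree(grid.coords[active])
            _, nearest = tree.query(coords[miss])
            pos[miss] = nearest
        means = self.world.fields[pos]
        variances = np.broadcast_to(self.world.noise_sd**2, means.shape).copy()
        return means, variances


def simulate_fields(
    grid: StudyGrid,
    panel: ChemistryPanel | None = None,
    lengthscales=2.0,
    signal_var=1.0,
    noise_sd=0.25,
    means=0.0,
    nu: float = 2.5,
    seed: int = 0,
) -> SyntheticWorld:
    """Draw one Matérn Gaussian random field per panel variable.

    Fields are simulated over the masked cells by dense Cholesky
    factorization of the cell covariance (grids capped at 5000 masked
    cells).  Scalar parameters broadcast over variables; ``lengthscales``
    may be scalar, per-variable, or per-variable-per-axis.
    """
    panel = panel or default_panel()
    m = panel.m
    active = grid.active
    n = len(active)
    if n > MAX_SIM_CELLS:
        raise ValueError(f"{n} masked cells exceeds the dense-simulation cap of {MAX_SIM_CELLS}")
    ell = np.asarray(lengthscales, float)
    if ell.ndim == 0:
        ell = np.full((m, 2), float(ell))
    elif ell.ndim == 1 and ell.shape == (2,):
        ell = np.tile(ell, (m, 1))
    elif ell.ndim == 1:
        ell = np.repeat(ell[:, None], 2, axis=1)
    sv = np.broadcast_to(np.asarray(signal_var, float), (m,)).copy()
    ns = np.broadcast_to(np.asarray(noise_sd, float), (m,)).copy()
    mu = np.broadcast_to(np.asarray(means, float), (m,)).copy()
    if np.any(ell <= 0) or np.any(sv < 0) or np.any(ns < 0):
        raise ValueError("invalid kernel parameters")

    coords = grid.coords[active]
    rng = np.random.default_rng(seed)
    fields = np.empty((n, m))
    chol_cache: dict[tuple, np.ndarray] = {}
    for j in range(m):
        key = (ell[j, 0], ell[j, 1], sv[j])
        if sv[j] == 0:
            fields[:, j] = mu[j]
            continue
        if key not in chol_cache:
            K = kernel_matrix(coords, coords, ell[j], sv[j], nu)
            K[np.diag_indices_from(K)] += 1e-8 * max(sv[j], 1.0)
            try:
                chol_cache[key] = np.linalg.cholesky(K)
            except np.linalg.LinAlgError as exc:
                raise ValueError("cell covariance not positive definite after jitter") from exc
        fields[:, j] = mu[j] + chol_cache[key] @ rng.standard_normal(n)
    return SyntheticWorld(grid, panel, fields, ns, ell, sv, nu, seed)


def sample_reference(
    world: SyntheticWorld,
    n_clusters: int,
    trees_per_cluster: int = 3,
    cluster_diameter_km: float = 50.0,
    inter_cluster_km: tuple[float, float] = (100.0, 250.0),
    noise_sd=None,
    genus: str = "Betula",
    seed: int = 0,
    max_retries: int = 1000,
) -> SampleTable:
    """Clustered sampling design emulating the field protocol.

    Cluster centers are placed sequentially: the first uniformly at random
    on the mask, each next center at a great-circle distance to the
    previous one inside ``inter_cluster_km`` (rejection sampling with a
    bounded retry budget).  Trees sit at masked cells within half the
    cluster diameter of their center, so intra-cluster pairwise distances
    stay within the diameter.  Observed values are the field value at the
    tree's cell plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    grid = world.grid
    active = grid.active
    centers_xy = grid.coords[active]
    ns = world.noise_sd if noise_sd is None else np.broadcast_to(np.asarray(noise_sd, float), (world.m,))

    center_cells = []
    first = int(rng.integers(len(active)))
    center_cells.append(first)
    for _ in range(1, n_clusters):
        prev_xy = centers_xy[center_cells[-1]]
        for attempt in range(max_retries):
            cand = int(rng.integers(len(active)))
            d = great_circle_km(centers_xy[cand], prev_xy)
            if inter_cluster_km[0] <= d <= inter_cluster_km[1]:
                center_cells.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place cluster {len(center_cells)} within "
                f"{inter_cluster_km} km after {max_retries} retries; mask too small"
            )

    rows = []
    chem_rows = []
    radius = cluster_diameter_km / 2.0
    for ci, cc in enumerate(center_cells):
        center = centers_xy[cc]
        d_all = great_circle_km(centers_xy, center)
        nearby = np.flatnonzero(d_all <= radius)
        tree_cells = rng.choice(nearby, size=trees_per_cluster, replace=True)
        for ti, tc in enumerate(tree_cells):
            cell = int(active[tc])
            f = world.field_at_cells([cell])[0]
            y = f + rng.standard_normal(world.m) * ns
            lon, lat = centers_xy[tc]
            rows.append((f"c{ci:03d}t{ti}", genus, lon, lat, f"cluster{ci:03d}"))
            chem_rows.append(y)
    df = pd.DataFrame(rows, columns=["sample_id", "genus", "lon", "lat", "cluster"])
    chem = pd.DataFrame(np.asarray(chem_rows), columns=list(world.panel.names))
    return SampleTable(pd.concat([df, chem], axis=1), world.panel)


def synthetic_territories(grid: StudyGrid, k: int, seed: int = 0, ids=None) -> RegionSet:
    """Voronoi partition of the masked cells around k random seed centers."""
    if k < 1:
        raise ValueError("k must be >= 1")
    active = grid.active
    if k > len(active):
        raise ValueError(f"k={k} exceeds the {len(active)} masked cells")
    rng = np.random.default_rng(seed)
    center_idx = rng.choice(len(active), size=k, replace=False)
    centers = grid.coords[active[center_idx]]
    coords = grid.coords[active]
    d = np.stack([great_circle_km(coords, c) for c in centers])  # (k, n_active)
    assign = np.argmin(d, axis=0)  # ties -> lowest center index
    ids = list(ids) if ids is not None else [f"T{i:02d}" for i in range(k)]
    if len(ids) != k:
        raise ValueError("ids length must equal k")
    regions = {ids[i]: active[assign == i] for i in range(k)}
    return RegionSet(scale="synthetic", regions=regions, provenance="tiling")


def make_table1_fixture(seed: int = 0, resolution: float = 0.5) -> SampleTable:
    """Metadata-complete synthetic stand-in for the 929-sample reference table.

    Per-country, per-genus row counts equal the reference collection
    exactly.  Coordinates are drawn inside per-country synthetic (Voronoi)
    territories on the study-area bounding box, and the 23 chemistry values
    come from a seeded :class:`SyntheticWorld`.  Everything except the
    counts is synthetic.
    """
    grid = build_study_grid(STUDY_BBOX, resolution)
    countries = sorted(TABLE1_COUNTS)
    terr = synthetic_territories(grid, len(countries), seed=seed, ids=countries)
    panel = default_panel()
    world = simulate_fields(
        grid, panel, lengthscales=3.0, signal_var=1.0, noise_sd=0.25, nu=2.5, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    rows, chem_rows = [], []
    i = 0
    for country in countries:
        cells = terr.regions[country]
        for genus, count in TABLE1_COUNTS[country].items():
            if count == 0:
                continue
            chosen = rng.choice(cells, size=count, replace=True)
            obs = world.observe(chosen, rng)
            for c, y in zip(chosen, obs):
                lon = grid.cell_lon[c]
                lat = grid.cell_lat[c]
                admin1 = f"{country}:A{int(c) % 3}"
                rows.append((f"s{i:04d}", genus, lon, lat, country, admin1))
                chem_rows.append(y)
                i += 1
    df = pd.DataFrame(rows, columns=["sample_id", "genus", "lon", "lat", "country", "admin1"])
    chem = pd.DataFrame(np.asarray(chem_rows), columns=list(panel.names))
    return SampleTable(pd.concat([df, chem], axis=1), panel)


def run_type1_experiment(
    world: SyntheticWorld,
    territories: RegionSet,
    alpha: float = 0.05,
    n_reps: int = 500,
    seed: int = 0,
    ensemble=None,
) -> dict:
    """Empirical specificity of the max-p test under correct claims.

    Test samples are drawn at uniform-random masked cells with the TRUE
    territory declared.  With ``ensemble=None`` the oracle predictive model
    (true field mean, true noise variance) is used, for which the test is
    conservative by construction: the p-value at the true cell is uniform
    and the reported max-p can only exceed it.
    Returns the specificity (fraction of claims not rejected) with its
    Monte-Carlo standard error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    model = ensemble if ensemble is not None else OracleEnsemble(world)
    grid = world.grid
    active = grid.active
    cell_to_terr = {}
    for rid, cells in territories.regions.items():
        for c in np.asarray(cells).tolist():
            cell_to_terr[c] = rid
    covered_cells = np.array(sorted(cell_to_terr), dtype=int)
    if len(covered_cells) == 0:
        raise ValueError("territories cover no masked cells")
    not_rejected = 0
    for rep in range(n_reps):
        cell = int(covered_cells[rng.integers(len(covered_cells))])
        terr = cell_to_terr[cell]
        y = world.observe([cell], rng)[0]
        res = territory_pvalue(
            y, model, territories.regions[terr], grid, alpha=alpha,
            territory_id=terr, scale=territories.scale,
        )
        if not res.reject:
            not_rejected += 1
    spec = not_rejected / n_reps
    mcse = float(np.sqrt(spec * (1 - spec) / n_reps))
    return {"specificity": spec, "mcse": mcse, "n_reps": n_reps, "alpha": alpha}


def run_coverage_experiment(
    world: SyntheticWorld,
    prior: PriorMap,
    level: float = 0.95,
    n_reps: int = 1000,
    seed: int = 0,
    ensemble=None,
) -> dict:
    """Empirical coverage of the credible region under the generating model.

    Each replicate draws a true cell from the prior, observes a noisy
    chemistry vector there, computes the posterior (oracle model unless an
    ensemble is supplied), builds the level-``level`` credible region and
    records whether the true cell lies inside.  Under the oracle model
    coverage >= level is guaranteed (up to Monte-Carlo error) by the
    mass-accumulation construction.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    grid = world.grid
    support = prior.support
    p_support = prior.probs[support]
    use_oracle = ensemble is None
    if use_oracle:
        # vectorized oracle likelihood over the support cells
        fields = world.field_at_cells(support)
        noise_var = world.noise_sd**2
        log_norm = -0.5 * np.sum(np.log(2 * np.pi * noise_var))
    model = ensemble
    covered = 0
    log_prior = np.log(p_support)
    for rep in range(n_reps):
        true_cell = int(rng.choice(support, p=p_support))
        y = world.observe([true_cell], rng)[0]
        if use_oracle:
            ll = log_norm - 0.5 * np.sum((y[None, :] - fields) ** 2 / noise_var[None, :], axis=1)
            logpost = ll + log_prior
            logpost -= logpost.max()
            probs = np.exp(logpost)
            probs /= probs.sum()
            order = np.argsort(-probs, kind="stable")
            csum = np.cumsum(probs[order])
            k = int(np.searchsorted(csum, level - 1e-12) + 1)
            region_cells = set(support[order[:k]].tolist())
            covered += true_cell in region_cells
        else:
            from .determine import log_likelihood_map

            post = posterior(log_likelihood_map(y, model, grid), prior)
            region = credible_region(post, level)
            covered += true_cell in set(region.cells.tolist())
    cov = covered / n_reps
    mcse = float(np.sqrt(cov * (1 - cov) / n_reps))
    return {"coverage": cov, "mcse": mcse, "n_reps": n_reps, "level": level}
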