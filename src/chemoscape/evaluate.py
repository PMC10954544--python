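"""Experiment drivers: cross-validated determination error, verification
accuracy matrices at several spatial scales, and accuracy-matrix clustering.

These reproduce the evaluation design used to benchmark the framework:
k-fold cross-validation with per-fold standardization, per-(sample, claim)
verification tests summarized as sensitivity/specificity, and average-
linkage clustering of the accuracy matrix with the symmetrized accuracy as
the distance measure.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .data_model import RegionSet, SampleTable, StudyGrid
from .determine import build_prior, credible_region, great_circle_km, log_likelihood_map, posterior
from .gp_field import GPConfig, fit_ensemble
from .verify import territory_pvalue

log = logging.getLogger("chemoscape")

PANEL_MODES = ("sira", "tea", "sira+tea")


def load_config(path) -> dict:
    """Flat key-value experiment configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    return cfg


def _mode_panel(table: SampleTable, panel_mode: str):
    if panel_mode not in PANEL_MODES:
        raise ValueError(f"panel_mode must be one of {PANEL_MODES}")
    panel = table.panel
    if panel_mode == "sira":
        return panel.subset(panel.isotope_names)
    if panel_mode == "tea":
        return panel.subset(panel.trace_element_names)
    return panel


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Plain random (unstratified) k-fold split; deterministic given seed."""
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} samples")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def run_cv_determination(
    table: SampleTable,
    grid: StudyGrid,
    panel_mode: str = "sira+tea",
    k: int = 4,
    seed: int = 0,
    gp_config: GPConfig | None = None,
    prior_radius_km: float = 300.0,
    level: float = 0.95,
) -> dict:
    """k-fold cross-validated determination error for one panel mode.

    For each fold the standardizer and the GPs are refit on the training
    split; every held-out sample is assigned its MAP cell and the
    great-circle distance to its true location recorded.  Returns the mean
    and standard deviation of those distances over all test samples, plus
    credible-region efficiency/coverage summaries.
    """
    t0 = time.time()
    mode_panel = _mode_panel(table, panel_mode)
    sub = table.with_panel(mode_panel)
    folds = kfold_indices(len(sub), k, seed)
    distances, efficiencies, covered_flags = [], [], []
    for fi, test_idx in enumerate(folds):
        test_mask = np.zeros(len(sub), dtype=bool)
        test_mask[test_idx] = True
        train = sub.select(~test_mask)
        test = sub.select(test_mask)
        ensemble = fit_ensemble(train, gp_config)
        prior = build_prior(grid, train.coords, prior_radius_km)
        for i in range(len(test)):
            y = test.chemistry[i]
            post = posterior(log_likelihood_map(y, ensemble, grid), prior)
            truth = test.coords[i]
            distances.append(great_circle_km(post.map_coords, truth))
            region = credible_region(post, level)
            efficiencies.append(region.area_km2)
            covered_flags.append(grid.cell_index(*truth) in set(region.cells.tolist()))
        log.info("cv fold %d/%d done (mode=%s, seed=%d)", fi + 1, k, panel_mode, seed)
    distances = np.asarray(distances)
    out = {
        "mode": panel_mode,
        "k": k,
        "seed": seed,
        "n_test": len(distances),
        "mean_km": float(distances.mean()),
        "sd_km": float(distances.std(ddof=1)) if len(distances) > 1 else 0.0,
        "distances_km": distances,
        "efficiency_km2": float(np.mean(efficiencies)),
        "coverage": float(np.mean(covered_flags)),
        "wall_s": time.time() - t0,
    }
    log.info("cv determination mode=%s mean=%.1f km sd=%.1f km", panel_mode,
             out["mean_km"], out["sd_km"])
    return out


@dataclass
class AccuracyMatrix:
    """Square table over territories: entry (declared, true) is the fraction
    of correct test responses — specificity on the diagonal (correct claims
    not rejected), sensitivity off it (incorrect claims rejected)."""

    table: pd.DataFrame  # rows = declared, columns = true
    counts: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def specificity(self) -> pd.Series:
        return pd.Series(np.diag(self.table.to_numpy()), index=self.ids, name="specificity")

    def sensitivity_per_pair(self) -> pd.Series:
        """Per-true-territory sensitivity: unweighted mean over declared != true."""
        M = self.table.to_numpy(float)
        k = len(self.ids)
        out = {}
        for j, tid in enumerate(self.ids):
            off = [M[i, j] for i in range(k) if i != j and np.isfinite(M[i, j])]
            out[tid] = float(np.mean(off)) if off else np.nan
        return pd.Series(out, name="sensitivity_per_pair")

    def sensitivity_per_sample(self) -> pd.Series:
        """Per-true-territory sensitivity weighted by the number of tests."""
        M = self.table.to_numpy(float)
        C = self.counts.to_numpy(float)
        k = len(self.ids)
        out = {}
        for j, tid in enumerate(self.ids):
            num = sum(M[i, j] * C[i, j] for i in range(k) if i != j and np.isfinite(M[i, j]))
            den = sum(C[i, j] for i in range(k) if i != j and np.isfinite(M[i, j]))
            out[tid] = float(num / den) if den else np.nan
        return pd.Series(out, name="sensitivity_per_sample")


def run_verification_matrix(
    table: SampleTable,
    grid: StudyGrid,
    territories: RegionSet,
    alpha: float = 0.05,
    k: int = 4,
    seed: int = 0,
    gp_config: GPConfig | None = None,
    ensemble=None,
    claim_regions: RegionSet | None = None,
    restrict_to_sampled: RegionSet | None = None,
) -> AccuracyMatrix:
    """Accuracy matrix over all (declared, true) territory combinations.

    Every test sample is tested against every territory.  With
    ``ensemble`` given (e.g. an oracle model) a single pass is made;
    otherwise GPs are refit per cross-validation fold.  When
    ``claim_regions`` provides a finer scale (admin units or concession
    tiles), an incorrect country claim is converted to the finer unit
    containing a uniformly drawn cell of the declared country, and a
    correct claim to the unit containing the sample's true cell.  With
    ``restrict_to_sampled`` a territory is reduced to the cells of its
    sub-units that contain at least one training sample.
    """
    rng = np.random.default_rng(seed)
    ids = territories.ids
    true_terr = _assign_territories(table, grid, territories)
    correct = {(d, t): 0 for d in ids for t in ids}
    totals = {(d, t): 0 for d in ids for t in ids}

    if ensemble is not None:
        passes = [(None, np.arange(len(table)))]
    else:
        passes = [(f, idx) for f, idx in enumerate(kfold_indices(len(table), k, seed))]

    for fold, test_idx in passes:
        if ensemble is None:
            test_mask = np.zeros(len(table), dtype=bool)
            test_mask[test_idx] = True
            model = fit_ensemble(table.select(~test_mask), gp_config)
        else:
            model = ensemble
        for i in np.asarray(test_idx):
            t = true_terr[i]
            if t is None:
                continue
            y = table.chemistry[i]
            for d in ids:
                cells = _claim_cells(
                    d, t, table.coords[i], grid, territories, claim_regions,
                    restrict_to_sampled, rng,
                )
                if cells is None or len(cells) == 0:
                    continue
                res = territory_pvalue(
                    y, model, cells, grid, alpha=alpha,
                    sample_id=str(table.df["sample_id"].iloc[i]), territory_id=d,
                    scale=territories.scale,
                )
                ok = (not res.reject) if d == t else res.reject
                correct[(d, t)] += ok
                totals[(d, t)] += 1

    M = pd.DataFrame(np.nan, index=ids, columns=ids)
    C = pd.DataFrame(0, index=ids, columns=ids)
    for (d, t), n in totals.items():
        C.loc[d, t] = n
        if n:
            M.loc[d, t] = correct[(d, t)] / n
    return AccuracyMatrix(M, C)


def _assign_territories(table: SampleTable, grid: StudyGrid, territories: RegionSet):
    cell_to_terr = {}
    for rid, cells in territories.regions.items():
        for c in np.asarray(cells).tolist():
            cell_to_terr[c] = rid
    return [cell_to_terr.get(int(c)) for c in grid.nearest_cells(table.coords)]


def _claim_cells(declared, true, truth_xy, grid, territories, claim_regions,
                 restrict_to_sampled, rng):
    base = territories.regions[declared]
    if len(base) == 0:
        return None
    if restrict_to_sampled is not None:
        keep = []
        for cells in restrict_to_sampled.regions.values():
            inter = np.intersect1d(base, cells)
            if len(inter):
                keep.append(inter)
        base = np.concatenate(keep) if keep else base[:0]
        if len(base) == 0:
            return None
    if claim_regions is None:
        return base
    # finer-scale claim: the unit containing the true cell (correct claim)
    # or a randomly drawn in-country location (incorrect claim)
    if declared == true:
        anchor = grid.cell_index(*truth_xy)
    else:
        anchor = int(base[rng.integers(len(base))])
    for cells in claim_regions.regions.values():
        if anchor in cells:
            inter = np.intersect1d(cells, base)
            return inter if len(inter) else cells
    return None


def cluster_accuracy_matrix(M: pd.DataFrame | AccuracyMatrix):
    """Average-linkage clustering of territories from an accuracy matrix.

    The distance between two territories is the average of the accuracies
    in both directions, d(i, j) = (M[i,j] + M[j,i]) / 2 — mutually
    confusable territories (low sensitivity both ways) merge first.
    Returns (Z, labels): a SciPy linkage matrix (merge list with heights)
    and the territory labels in input order.
    """
    if isinstance(M, AccuracyMatrix):
        M = M.table
    if M.shape[0] != M.shape[1] or list(M.index) != list(M.columns):
        raise ValueError("accuracy matrix must be square with matching labels")
    if len(M) < 2:
        raise ValueError("need at least 2 territories to cluster")
    A = M.to_numpy(float)
    D = (A + A.T) / 2.0
    np.fill_diagonal(D, 0.0)
    if np.isnan(D).any():
        raise ValueError("accuracy matrix contains missing entries")
    Z = linkage(squareform(D, checks=False), method="average")
    return Z, list(M.index)


def linkage_to_frame(Z: np.ndarray, labels: list[str]) -> pd.DataFrame:
    """Merge list with heights as a plain table (for CSV export)."""
    rows = []
    names = {i: lab for i, lab in enumerate(labels)}
    for step, (a, b, h, n) in enumerate(Z):
        a, b = int(a), int(b)
        new = len(labels) + step
        names[new] = f"({names[a]}+{names[b]})"
        rows.append((step, names[a], names[b], float(h), int(n)))
    return pd.DataFrame(rows, columns=["step", "left", "right", "height", "size"])
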