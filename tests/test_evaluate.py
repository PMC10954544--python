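"""Experiment drivers: cross-validated determination, verification accuracy
matrices and accuracy-matrix clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import chemoscape as cs
from chemoscape.evaluate import (
    cluster_accuracy_matrix,
    kfold_indices,
    linkage_to_frame,
    load_config,
)


@pytest.fixture(scope="module")
def cv_world():
    """Small world for CV experiments: 25x25 grid, 4 variables."""
    grid = cs.build_study_grid((0.0, 4.8, 40.0, 44.8), 0.2)
    panel = cs.default_panel().subset(["d18O", "d2H", "Sr", "Rb"])
    return cs.simulate_fields(grid, panel, lengthscales=2.0, signal_var=1.0,
                              noise_sd=0.4, seed=51)


@pytest.fixture(scope="module")
def cv_samples(cv_world):
    return cs.sample_reference(cv_world, n_clusters=8, seed=52)


class TestKFold:
    def test_partition_and_determinism(self):
        folds = kfold_indices(17, 4, seed=1)
        assert sorted(np.concatenate(folds).tolist()) == list(range(17))
        again = kfold_indices(17, 4, seed=1)
        for a, b in zip(folds, again):
            np.testing.assert_array_equal(a, b)

    def test_k_equals_n_leave_one_out(self):
        folds = kfold_indices(5, 5, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_k_larger_than_n_errors(self):
        with pytest.raises(ValueError):
            kfold_indices(3, 4, seed=0)


class TestCvDetermination:
    def test_reports_mean_sd_and_is_deterministic(self, cv_world, cv_samples):
        cfg = cs.GPConfig(max_iter=60)
        out1 = cs.run_cv_determination(cv_samples, cv_world.grid, "sira+tea",
                                       k=3, seed=1, gp_config=cfg)
        out2 = cs.run_cv_determination(cv_samples, cv_world.grid, "sira+tea",
                                       k=3, seed=1, gp_config=cfg)
        assert out1["n_test"] == len(cv_samples)
        assert out1["mean_km"] == out2["mean_km"]
        assert out1["sd_km"] == pytest.approx(
            np.std(out1["distances_km"], ddof=1)
        )
        assert 0.0 <= out1["coverage"] <= 1.0

    def test_combined_panel_not_worse_than_isotopes_alone(self, cv_world):
        """Adding informative trace elements should not raise the median CV
        error across seeds (trend, not a sharp bound)."""
        cfg = cs.GPConfig(max_iter=60)
        diffs = []
        for seed in range(5):
            samples = cs.sample_reference(cv_world, n_clusters=8, seed=60 + seed)
            both = cs.run_cv_determination(samples, cv_world.grid, "sira+tea",
                                           k=3, seed=seed, gp_config=cfg)
            sira = cs.run_cv_determination(samples, cv_world.grid, "sira",
                                           k=3, seed=seed, gp_config=cfg)
            diffs.append(both["mean_km"] - sira["mean_km"])
        assert np.median(diffs) <= 0.0

    def test_unknown_mode_rejected(self, cv_world, cv_samples):
        with pytest.raises(ValueError):
            cs.run_cv_determination(cv_samples, cv_world.grid, "nope")


class TestVerificationMatrix:
    def test_oracle_matrix_shape_and_specificity(self, small_world, territories, oracle):
        rng = np.random.default_rng(70)
        cells = small_world.grid.active[rng.integers(0, small_world.grid.n_active, 60)]
        obs = small_world.observe(cells, rng)
        df = pd.DataFrame({
            "sample_id": [f"t{i}" for i in range(len(cells))],
            "genus": "Betula",
            "lon": small_world.grid.cell_lon[cells],
            "lat": small_world.grid.cell_lat[cells],
        })
        table = cs.SampleTable(
            pd.concat([df, pd.DataFrame(obs, columns=list(small_world.panel.names))], axis=1),
            small_world.panel,
        )
        acc = cs.run_verification_matrix(table, small_world.grid, territories,
                                         ensemble=oracle, seed=3)
        k = len(territories.ids)
        assert acc.table.shape == (k, k)
        vals = acc.table.to_numpy(float)
        finite = np.isfinite(vals)
        assert np.all((vals[finite] >= 0) & (vals[finite] <= 1))
        # oracle + correct claims: specificity near or above 1 - alpha
        spec = acc.specificity().dropna()
        n_diag = np.diag(acc.counts.to_numpy())[np.isfinite(np.diag(vals))]
        mcse = np.sqrt(0.05 * 0.95 / np.maximum(n_diag, 1))
        assert np.all(spec.to_numpy() >= 0.95 - 3 * mcse)
        # diagonal of the matrix equals the per-territory specificity
        np.testing.assert_array_equal(spec.to_numpy(), np.diag(vals)[np.isfinite(np.diag(vals))])

    def test_indistinguishable_territories_near_alpha_sensitivity(self, small_grid):
        """With a spatially flat world, an incorrect claim is statistically
        indistinguishable from a correct one: rejection of the wrong
        territory happens at about the alpha rate."""
        panel = cs.default_panel().subset(["d18O", "Sr"])
        flat = cs.simulate_fields(small_grid, panel, signal_var=0.0,
                                  noise_sd=0.3, seed=80)
        oracle = cs.OracleEnsemble(flat)
        terr = cs.synthetic_territories(small_grid, 2, seed=81)
        rng = np.random.default_rng(82)
        cells = small_grid.active[rng.integers(0, small_grid.n_active, 150)]
        obs = flat.observe(cells, rng)
        df = pd.DataFrame({
            "sample_id": [f"t{i}" for i in range(len(cells))],
            "genus": "Betula",
            "lon": small_grid.cell_lon[cells],
            "lat": small_grid.cell_lat[cells],
        })
        table = cs.SampleTable(
            pd.concat([df, pd.DataFrame(obs, columns=list(panel.names))], axis=1), panel
        )
        acc = cs.run_verification_matrix(table, small_grid, terr, alpha=0.05,
                                         ensemble=oracle, seed=83)
        M = acc.table.to_numpy(float)
        C = acc.counts.to_numpy(float)
        off = ~np.eye(2, dtype=bool)
        pooled = float(np.nansum(M[off] * C[off]) / C[off].sum())
        mcse = np.sqrt(0.05 * 0.95 / C[off].sum())
        assert pooled <= 0.05 + 3 * mcse

    def test_finer_claims_do_not_lower_sensitivity(self, small_world, territories, oracle):
        """Concession-scale claims (smaller areas) are at least as easy to
        reject as the enclosing territory: p(max over fewer cells) <= p."""
        grid = small_world.grid
        tiles = cs.tile_regions(grid, 1.0)
        rng = np.random.default_rng(90)
        cells = grid.active[rng.integers(0, grid.n_active, 40)]
        obs = small_world.observe(cells, rng)
        df = pd.DataFrame({
            "sample_id": [f"t{i}" for i in range(len(cells))],
            "genus": "Betula",
            "lon": grid.cell_lon[cells],
            "lat": grid.cell_lat[cells],
        })
        table = cs.SampleTable(
            pd.concat([df, pd.DataFrame(obs, columns=list(small_world.panel.names))], axis=1),
            small_world.panel,
        )
        coarse = cs.run_verification_matrix(table, grid, territories,
                                            ensemble=oracle, seed=91)
        fine = cs.run_verification_matrix(table, grid, territories,
                                          ensemble=oracle, seed=91,
                                          claim_regions=tiles)

        def pooled_sens(acc):
            M = acc.table.to_numpy(float)
            C = acc.counts.to_numpy(float)
            off = ~np.eye(len(M), dtype=bool)
            ok = off & np.isfinite(M)
            return float(np.sum(M[ok] * C[ok]) / C[ok].sum())

        assert pooled_sens(fine) >= pooled_sens(coarse) - 0.05


class TestClustering:
    def _matrix(self, d_ab, d_ac, d_bc):
        M = pd.DataFrame(
            [[0.96, d_ab, d_ac], [d_ab, 0.94, d_bc], [d_ac, d_bc, 0.95]],
            index=list("ABC"), columns=list("ABC"),
        )
        return M

    def test_hand_run_average_linkage(self):
        # d(A,B)=0.1, d(A,C)=0.5, d(B,C)=0.3: merge (A,B) at 0.1, then C at
        # the average (0.5 + 0.3) / 2 = 0.4
        Z, labels = cluster_accuracy_matrix(self._matrix(0.1, 0.5, 0.3))
        assert labels == list("ABC")
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.4)

    def test_mutual_zero_sensitivity_merges_first(self):
        Z, _ = cluster_accuracy_matrix(self._matrix(0.0, 0.8, 0.9))
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]
        assert Z[0, 2] == 0.0

    def test_asymmetric_accuracies_are_averaged(self):
        M = self._matrix(0.2, 0.6, 0.4)
        M.loc["A", "B"] = 0.4  # (0.4 + 0.2) / 2 = 0.3 becomes the distance
        Z, _ = cluster_accuracy_matrix(M)
        assert Z[0, 2] == pytest.approx(0.3)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        k = 6
        A = rng.uniform(0, 1, (k, k))
        M = pd.DataFrame(A, index=list("ABCDEF"), columns=list("ABCDEF"))
        Z, _ = cluster_accuracy_matrix(M)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_non_square_rejected(self):
        M = pd.DataFrame(np.zeros((2, 3)), index=list("AB"), columns=list("ABC"))
        with pytest.raises(ValueError, match="square"):
            cluster_accuracy_matrix(M)

    def test_linkage_frame_lists_merges(self):
        Z, labels = cluster_accuracy_matrix(self._matrix(0.1, 0.5, 0.3))
        frame = linkage_to_frame(Z, labels)
        assert list(frame.columns) == ["step", "left", "right", "height", "size"]
        assert len(frame) == 2


def test_load_config_flat_mapping(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("alpha: 0.05\nk: 4\npanel: sira+tea\n")
    cfg = load_config(path)
    assert cfg == {"alpha": 0.05, "k": 4, "panel": "sira+tea"}
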