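"""Bayesian determination: likelihood maps, priors, posterior, credible
regions, geographic metrics and calibration."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chemoscape as cs
from chemoscape.determine import (
    EARTH_RADIUS_KM,
    KM_PER_DEG,
    PosteriorMap,
    cell_areas_km2,
)
from test_verify import StubEnsemble


def _row_grid(n=3):
    return cs.build_study_grid((0, 0.5 * (n - 1), 0, 0), 0.5)


class TestGreatCircle:
    def test_zero_distance(self):
        assert cs.great_circle_km((10.0, 50.0), (10.0, 50.0)) == 0.0

    def test_antipodal_is_pi_r(self):
        assert cs.great_circle_km((0.0, 0.0), (180.0, 0.0)) == pytest.approx(
            np.pi * EARTH_RADIUS_KM, rel=1e-12
        )

    def test_one_degree_on_equator(self):
        assert cs.great_circle_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(
            111.195, abs=5e-4
        )

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-180, 180, 12), rng.uniform(-85, 85, 12)])
        for a, b, c in itertools.combinations(range(12), 3):
            dab = cs.great_circle_km(pts[a], pts[b])
            assert dab == pytest.approx(cs.great_circle_km(pts[b], pts[a]))
            assert dab <= cs.great_circle_km(pts[a], pts[c]) + cs.great_circle_km(pts[c], pts[b]) + 1e-9


class TestLikelihoodMap:
    def test_single_variable_analytic_logdensity(self):
        grid = _row_grid(1)
        ens = StubEnsemble([[0.0]], [[1.0]], grid.coords)
        ll = cs.log_likelihood_map(np.array([0.0]), ens, grid)
        assert ll[0] == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_three_cell_hand_computation(self):
        grid = _row_grid(3)
        means = [[0.0, 1.0], [2.0, -1.0], [0.5, 0.5]]
        variances = [[1.0, 4.0], [0.5, 1.0], [2.0, 2.0]]
        ens = StubEnsemble(means, variances, grid.coords)
        y = np.array([1.0, 0.0])
        ll = cs.log_likelihood_map(y, ens, grid)
        for c in range(3):
            hand = sum(
                -0.5 * np.log(2 * np.pi * v) - (y[j] - m) ** 2 / (2 * v)
                for j, (m, v) in enumerate(zip(means[c], variances[c]))
            )
            assert ll[c] == pytest.approx(hand, abs=1e-10)

    def test_duplicated_variable_doubles_its_contribution(self):
        grid = _row_grid(1)
        single = StubEnsemble([[0.0]], [[1.0]], grid.coords)
        double = StubEnsemble([[0.0, 0.0]], [[1.0, 1.0]], grid.coords)
        ll1 = cs.log_likelihood_map(np.array([1.5]), single, grid)[0]
        ll2 = cs.log_likelihood_map(np.array([1.5, 1.5]), double, grid)[0]
        assert ll2 == pytest.approx(2 * ll1)

    def test_missing_variables_skipped(self):
        grid = _row_grid(1)
        ens = StubEnsemble([[0.0, 5.0]], [[1.0, 1.0]], grid.coords)
        ll = cs.log_likelihood_map(np.array([0.0, np.nan]), ens, grid)
        assert ll[0] == pytest.approx(-0.5 * np.log(2 * np.pi))
        with pytest.raises(ValueError, match="missing"):
            cs.log_likelihood_map(np.array([np.nan, np.nan]), ens, grid)


class TestPrior:
    def test_uniform_on_disc_support(self, small_grid):
        ref = small_grid.coords[small_grid.active[450]]
        prior = cs.build_prior(small_grid, ref, radius_km=300)
        support = prior.support
        d = cs.great_circle_km(small_grid.coords[support], ref)
        assert np.all(d <= 300)
        np.testing.assert_allclose(prior.probs[support], 1.0 / len(support))
        outside = np.setdiff1d(small_grid.active, support)
        d_out = cs.great_circle_km(small_grid.coords[outside], ref)
        assert np.all(d_out > 300)

    def test_infinite_radius_covers_all_masked_cells(self, small_grid):
        prior = cs.build_prior(small_grid, small_grid.coords[:1], radius_km=np.inf)
        assert len(prior.support) == small_grid.n_active
        np.testing.assert_allclose(prior.probs[prior.support], 1.0 / small_grid.n_active)

    def test_empty_support_errors(self, small_grid):
        with pytest.raises(ValueError, match="within"):
            cs.build_prior(small_grid, np.array([[100.0, -60.0]]), radius_km=50)


class TestPosterior:
    def test_flat_likelihood_returns_prior(self, small_grid):
        prior = cs.uniform_prior(small_grid)
        ll = np.zeros(small_grid.n_cells)
        post = cs.posterior(ll, prior)
        np.testing.assert_allclose(post.probs, prior.probs, atol=1e-15)

    def test_three_cell_hand_bayes(self):
        grid = _row_grid(3)
        prior = cs.uniform_prior(grid)
        ll = np.log([2.0, 1.0, 1.0])
        post = cs.posterior(ll, prior)
        np.testing.assert_allclose(post.probs, [0.5, 0.25, 0.25], atol=1e-12)
        assert post.map_cell == 0

    def test_likelihood_scaling_invariance(self, small_grid):
        rng = np.random.default_rng(3)
        prior = cs.uniform_prior(small_grid)
        ll = rng.normal(-40, 5, small_grid.n_cells)
        a = cs.posterior(ll, prior)
        b = cs.posterior(ll + 123.456, prior)  # multiply all likelihoods by e^123
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)
        assert a.map_cell == b.map_cell

    def test_zero_prior_cells_get_zero_posterior(self, small_grid):
        ref = small_grid.coords[small_grid.active[0]]
        prior = cs.build_prior(small_grid, ref, radius_km=150)
        ll = np.zeros(small_grid.n_cells)  # flat, even off-support
        post = cs.posterior(ll, prior)
        off = np.setdiff1d(np.arange(small_grid.n_cells), prior.support)
        assert np.all(post.probs[off] == 0.0)

    def test_all_minus_inf_on_support_errors(self, small_grid):
        prior = cs.uniform_prior(small_grid)
        with pytest.raises(ValueError, match="zero everywhere"):
            cs.posterior(np.full(small_grid.n_cells, -np.inf), prior)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sums_to_one_for_random_inputs(self, seed):
        grid = cs.build_study_grid((0, 2, 0, 2), 0.5)
        rng = np.random.default_rng(seed)
        prior = cs.uniform_prior(grid)
        ll = rng.normal(-300, 50, grid.n_cells)
        post = cs.posterior(ll, prior)
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-9)


def _brute_force_smallest_region(probs, level):
    """Exhaustive search over all subsets: minimum cardinality reaching the
    level, then maximum mass among those (the highest-posterior choice)."""
    support = np.flatnonzero(probs > 0)
    best = None
    for k in range(1, len(support) + 1):
        candidates = [
            (sum(probs[list(sub)]), frozenset(sub))
            for sub in itertools.combinations(support, k)
            if sum(probs[list(sub)]) >= level - 1e-12
        ]
        if candidates:
            best = max(candidates, key=lambda t: t[0])
            break
    return best


class TestCredibleRegion:
    def test_greedy_example(self):
        grid = cs.build_study_grid((0, 1.5, 0, 0), 0.5)
        probs = np.array([0.5, 0.3, 0.15, 0.05])
        post = PosteriorMap(grid, probs, 0, 0.0)
        region = cs.credible_region(post, 0.95)
        assert region.cells.tolist() == [0, 1, 2]
        assert region.mass == pytest.approx(0.95)

    def test_level_one_returns_entire_support(self, small_grid):
        rng = np.random.default_rng(1)
        prior = cs.uniform_prior(small_grid)
        post = cs.posterior(rng.normal(0, 2, small_grid.n_cells), prior)
        region = cs.credible_region(post, 1.0)
        assert len(region.cells) == small_grid.n_active

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search_on_small_posteriors(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        grid = cs.build_study_grid((0, 0.5 * (n - 1), 0, 0), 0.5)
        probs = rng.dirichlet(np.ones(n))
        post = PosteriorMap(grid, probs, int(np.argmax(probs)), 0.0)
        region = cs.credible_region(post, 0.9)
        mass, cells = _brute_force_smallest_region(probs, 0.9)
        assert len(region.cells) == len(cells)
        assert region.mass == pytest.approx(mass, abs=1e-12)
        assert frozenset(region.cells.tolist()) == cells


class TestUncertaintyMap:
    def test_toy_hand_sum_of_logs(self):
        grid = _row_grid(2)
        variances = [[0.5, 2.0], [1.0, 4.0]]
        ens = StubEnsemble([[0.0, 0.0]] * 2, variances, grid.coords)
        values, labels = cs.uncertainty_map(ens, grid)
        assert values[0] == pytest.approx(np.log(0.5) + np.log(2.0))
        assert values[1] == pytest.approx(np.log(1.0) + np.log(4.0))

    def test_doubling_variances_shifts_by_m_log2(self, small_grid):
        m = 3
        rng = np.random.default_rng(2)
        var = rng.uniform(0.5, 2.0, (small_grid.n_cells, m))

        class VarEns(StubEnsemble):
            def __init__(self, v):
                super().__init__(np.zeros_like(v), v, small_grid.coords)

        v1, _ = cs.uncertainty_map(VarEns(var), small_grid)
        v2, _ = cs.uncertainty_map(VarEns(2 * var), small_grid)
        np.testing.assert_allclose(v2 - v1, m * np.log(2), atol=1e-10)

    def test_percentile_classification(self, small_grid):
        rng = np.random.default_rng(4)
        var = rng.uniform(0.5, 2.0, (small_grid.n_cells, 2))
        ens = StubEnsemble(np.zeros_like(var), var, small_grid.coords)
        values, labels = cs.uncertainty_map(ens, small_grid)
        active_vals = values[small_grid.active]
        q25, q75 = np.percentile(active_vals, [25, 75])
        assert np.all(active_vals[labels[small_grid.active] == "low"] < q25)
        assert np.all(active_vals[labels[small_grid.active] == "high"] > q75)

    def test_degenerate_spread_flags_everything_mid(self):
        grid = _row_grid(3)
        ens = StubEnsemble([[0.0]] * 3, [[1.0]] * 3, grid.coords)
        values, labels = cs.uncertainty_map(ens, grid)
        np.testing.assert_allclose(values[:3], 0.0)
        assert set(labels[grid.active]) == {"mid"}


class TestRegionMetrics:
    def test_single_equatorial_cell_area(self):
        grid = cs.build_study_grid((0, 1, 0, 0), 0.2)
        area = cell_areas_km2(grid, np.array([0]))[0]
        assert area == pytest.approx((0.2 * KM_PER_DEG) ** 2, rel=1e-6)
        assert area == pytest.approx(494.6, abs=0.5)

    def test_cos_latitude_halves_area_at_60N(self):
        grid = cs.build_study_grid((0, 1, 0, 60), 0.2)
        eq = cell_areas_km2(grid, np.array([grid.cell_index(0, 0)]))[0]
        north = cell_areas_km2(grid, np.array([grid.cell_index(0, 60)]))[0]
        assert north == pytest.approx(eq / 2, rel=1e-9)

    def test_truth_at_map_cell_is_covered(self, small_grid):
        rng = np.random.default_rng(9)
        prior = cs.uniform_prior(small_grid)
        post = cs.posterior(rng.normal(0, 3, small_grid.n_cells), prior)
        region = cs.credible_region(post, 0.95)
        eff, covered = cs.region_metrics(region, (post.map_lon, post.map_lat))
        assert covered
        assert eff == pytest.approx(cell_areas_km2(small_grid, region.cells).sum())


class TestCalibrationAndConsistency:
    def test_oracle_coverage_at_least_nominal(self, small_world):
        """Truth drawn from the prior, oracle likelihood: 95% region covers
        >= 95% of replicates up to 3 Monte-Carlo SEs (over-coverage expected
        from cell discreteness)."""
        prior = cs.uniform_prior(small_world.grid)
        out = cs.run_coverage_experiment(small_world, prior, level=0.95,
                                         n_reps=1000, seed=31)
        mcse = max(out["mcse"], np.sqrt(0.95 * 0.05 / 1000))
        assert out["coverage"] >= 0.95 - 3 * mcse

    def test_map_converges_to_truth_as_noise_vanishes(self, small_grid, tiny_panel):
        world = cs.simulate_fields(small_grid, tiny_panel, lengthscales=2.0,
                                   noise_sd=1e-4, seed=17)
        oracle = cs.OracleEnsemble(world)
        prior = cs.uniform_prior(small_grid)
        rng = np.random.default_rng(18)
        cells = small_grid.active[rng.integers(0, small_grid.n_active, 10)]
        obs = world.observe(cells, rng)
        for cell, y in zip(cells, obs):
            post = cs.posterior(cs.log_likelihood_map(y, oracle, small_grid), prior)
            assert post.map_cell == cell

    def test_map_error_shrinks_with_training_size(self, small_grid, tiny_panel):
        """Mean great-circle MAP error decreases (within noise) as the
        training design grows — a trend check on fitted ensembles."""
        world = cs.simulate_fields(small_grid, tiny_panel, lengthscales=2.0,
                                   noise_sd=0.3, seed=23)
        cfg = cs.GPConfig(max_iter=80)
        rng = np.random.default_rng(24)
        test_cells = small_grid.active[rng.integers(0, small_grid.n_active, 15)]
        test_obs = world.observe(test_cells, rng)
        errors = {}
        for n_clusters in (4, 16):
            train = cs.sample_reference(world, n_clusters=n_clusters, seed=25)
            ens = cs.fit_ensemble(train, cfg)
            prior = cs.uniform_prior(small_grid)
            errs = []
            for cell, y in zip(test_cells, test_obs):
                post = cs.posterior(cs.log_likelihood_map(y, ens, small_grid), prior)
                truth = small_grid.coords[cell]
                errs.append(cs.great_circle_km(post.map_coords, truth))
            errors[n_clusters] = np.mean(errs)
        assert errors[16] <= errors[4] * 1.25  # allow Monte-Carlo slack
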