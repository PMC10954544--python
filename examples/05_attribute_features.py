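"""Which chemistry variables drive the predicted harvest location?

Shapley values of the MAP longitude and latitude with respect to each
chemistry variable, with absent variables filled from the training
background.  Variables are ranked by mean absolute attribution.
"""

import numpy as np

import chemoscape as cs

grid = cs.build_study_grid((15.0, 20.8, 46.0, 51.8), 0.2)
panel = cs.default_panel().subset(["d18O", "d2H", "Sr", "Rb"])
world = cs.simulate_fields(grid, panel, lengthscales=2.0,
                           signal_var=[1.0, 1.0, 1.0, 0.0],  # Sr field is flat
                           noise_sd=0.25, nu=2.5, seed=1)
oracle = cs.OracleEnsemble(world)
prior = cs.uniform_prior(grid)
predict = cs.map_predictor(oracle, grid, prior)

rng = np.random.default_rng(6)
cells = grid.active[rng.integers(0, grid.n_active, 8)]
background = world.observe(cells, rng)
test = world.observe(grid.active[rng.integers(0, grid.n_active, 3)], rng)

attr = cs.shapley_attribution(predict, test, background,
                              feature_names=list(panel.names), seed=7)
print(attr.importance.round(3))
print("\nsum(attributions) + baseline == prediction (local accuracy):")
total = attr.values[0].sum(axis=0) + attr.baseline
print(f"  {total.round(3)} vs {attr.predictions[0].round(3)}")
# Sr's generating field is spatially flat, so it cannot move the MAP cell:
# its attribution is exactly zero on both axes.
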