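"""Verify origin claims: can this sample come from the declared territory?

The test computes, at every grid cell of the claimed territory, the
chi-squared statistic of the variance-normalized residuals, and reports the
maximum p-value over the territory.  A claim is rejected only if every
location inside it is rejected (p < alpha).
"""

import numpy as np

import chemoscape as cs
from chemoscape.data_model import DEFAULT_DROP

grid = cs.build_study_grid((15.0, 20.8, 46.0, 51.8), 0.2)
panel = cs.select_features(cs.default_panel(), DEFAULT_DROP)
world = cs.simulate_fields(grid, panel, lengthscales=2.0, signal_var=1.0,
                           noise_sd=0.25, nu=2.5, seed=1)
territories = cs.synthetic_territories(grid, 4, seed=3)
oracle = cs.OracleEnsemble(world)

rng = np.random.default_rng(4)
true_cell = int(grid.active[700])
y = world.observe([true_cell], rng)[0]
true_terr = next(t for t, cells in territories.regions.items() if true_cell in cells)

for terr in territories.ids:
    res = cs.territory_pvalue(y, oracle, territories.regions[terr], grid,
                              alpha=0.05, territory_id=terr)
    tag = "TRUE " if terr == true_terr else "false"
    print(f"claim {terr} ({tag} origin): p = {res.p_value:.4f} -> "
          f"{'reject' if res.reject else 'not rejected'} "
          f"(S = {res.s_at_argmax:.1f}, df = {res.df})")
# The true territory should survive (p >= 0.05); distant territories whose
# fields do not match the sample's chemistry are rejected.
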