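"""Build a synthetic study region: chemistry fields plus a clustered survey.

Simulates 20 Matérn random fields (one per chemistry variable) on a 30x30
grid, then emulates the field protocol: clusters of three trees within a
50 km area, consecutive clusters 100-250 km apart.
"""

import chemoscape as cs
from chemoscape.data_model import DEFAULT_DROP

grid = cs.build_study_grid((15.0, 20.8, 46.0, 51.8), 0.2)
panel = cs.select_features(cs.default_panel(), DEFAULT_DROP)
world = cs.simulate_fields(grid, panel, lengthscales=2.0, signal_var=1.0,
                           noise_sd=0.25, nu=2.5, seed=1)
samples = cs.sample_reference(world, n_clusters=12, seed=2)

print(f"grid: {grid.n_lon} x {grid.n_lat} cells at {grid.resolution} deg "
      f"({grid.n_active} active)")
print(f"panel: {panel.m} variables "
      f"({len(panel.isotope_names)} isotope ratios, "
      f"{len(panel.trace_element_names)} trace elements)")
print(f"samples: {len(samples)} trees in 12 clusters")
d = cs.great_circle_km(samples.coords, samples.coords[0])
print(f"max spread from first tree: {d.max():.0f} km")
# The world's true fields and noise level are known, so downstream examples
# can compare model output against ground truth.
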