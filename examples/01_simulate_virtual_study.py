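"""Simulate a virtual study: landscape, warming scenarios, and a species
with a known Gaussian niche.

The generator is the package's test bed: because the species' niche is
known exactly, the true current/future ranges and the true net range
change are available as ground truth for everything the pipeline later
estimates.
"""

import sdmrisk as sr

scenario = sr.default_scenario_config(seed=0)
species = sr.default_species_config(seed=100, n_presences=300)

stacks = sr.simulate_landscape(scenario)
suitability = sr.true_suitability(stacks["current"], species)
occurrences = sr.sample_presences(suitability, species)
truth = sr.ground_truth(stacks, species)

grid = scenario.grid
print(f"landscape: {grid.n_rows}x{grid.n_cols} cells of {grid.cell_size:.4f} deg")
print(f"scenarios: {sorted(stacks)}")
print(f"presence records sampled: {len(occurrences)}")
area = sr.mask_area_km2(truth.true_current_range, grid)
print(f"true current range: {truth.true_current_range.sum()} cells "
      f"({area:,.0f} km^2)")
for label, pct in truth.true_net_change_pct.items():
    print(f"true net range change under {label}: {pct:+d}%")

# The negative net change is the ground truth the pipeline must recover:
# warming pushes the species' thermal band poleward until it partly exits
# the northern edge of the study extent.
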