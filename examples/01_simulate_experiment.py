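"""Simulate a gravimetric phenotyping experiment with known ground truth.

Builds a population of three genotype families that differ in their maximum
transpiration rate and in the vapour-pressure-deficit level at which they
restrict it, and writes the four CSV inputs the pipeline reads plus a JSON
sidecar with the true cluster labels and breakpoints.
"""

from gravitr import synthetic as syn

cfg = syn.SimulationConfig(seed=7)
bundle = syn.make_population(cfg)

print(f"load-cell table : {bundle.loadcells.shape[0]} steps x "
      f"{bundle.loadcells.shape[1] - 1} sectors (grams)")
print(f"weather table   : {bundle.weather.shape[0]} steps "
      f"({cfg.n_days} days x {cfg.steps_per_day}/day)")
print(f"design table    : {len(bundle.design)} sectors, "
      f"{bundle.design['genotype_id'].nunique()} genotypes")
print("true cluster breakpoints (fraction of max VPD):",
      bundle.ground_truth["cluster_breakpoints"])

outdir = bundle.write("scratch/example_bundle")
print(f"CSV bundle written to {outdir}")
# The breakpoint fractions above are what the full analysis tries to
# recover from the weight traces alone.
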