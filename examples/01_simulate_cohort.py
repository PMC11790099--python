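"""Simulate an ICU-like cohort and build the emulated-trial population.

Generates longitudinal event tables (static, measurements, drug
administrations, outcomes) with known causal ground truth, then applies
the PICOT rules: adults, crystalloids as the follow-up anchor, albumin
within 24 h defining the treated arm, 28-day mortality outcome.
"""

import ehrtrial as et

config = et.SimConfig(n_patients=5_000, seed=42)
tables, truth = et.simulate(config)

print(f"patients simulated: {config.n_patients}")
print(f"measurement rows:   {len(tables.measurements)}")
print(f"realized treated fraction: {truth.table['treated'].mean():.3f} "
      f"(target {config.treated_fraction_target})")
print(f"true average treatment effect (risk difference): {truth.ate:+.3f}\n")

cohort, flowchart = et.build_cohort(tables, et.CohortSpec())
print(flowchart.report())
print(f"\ncohort: n={cohort.n}, treated={cohort.n_treated}, "
      f"28-day mortality={cohort.table['outcome'].mean():.3f}")

# The tables round-trip to disk; ground truth goes to a sidecar directory
# that analysis code never reads.
et.write_tables(tables, "scratch_example_data", ground_truth=truth, fmt="csv")
print("\nwrote event tables to scratch_example_data/ (ground truth in sidecar)")
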