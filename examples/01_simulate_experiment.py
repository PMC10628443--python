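"""Simulate a gravimetric drought experiment with known ground truth.

A lysimeter array weighs every potted plant every 3 minutes.  Because the
soil surface is covered, weight loss between irrigation events is
transpiration.  The simulator reproduces the whole protocol — well-watered
pre-drought, feedback deficit irrigation (each plant gets 80% of its own
previous-day transpiration), re-irrigation, and a reduced post-recovery
regime — and keeps the exact water balance as ground truth.
"""

from lysimetrics import SimulationConfig, simulate_experiment, write_experiment

config = SimulationConfig(
    n_control=2,          # well-watered replicates per cultivar
    n_drought=3,          # deficit-irrigated replicates per cultivar
    phase_lengths=(4, 8, 6, 3),
    noise_sd=0.5,         # g per weight record
    rng_seed=42,
)

exp = simulate_experiment(config)

print(f"{len(exp.plant_ids)} plants, {config.total_days} days, "
      f"{len(exp.forcing)} weight records per plant")
print("\nPhase calendar:")
for phase, (start, end) in config.phase_dates().items():
    print(f"  {phase:>14}: {start} .. {end}")

pid = next(p for p in exp.plant_ids if "-D" in p)
print(f"\nGround-truth daily transpiration for {pid} (g/day):")
print(exp.truth.daily_for(pid).head(8).to_string(index=False))

print("\nHarvest table (first rows):")
print(exp.harvest.head(4).to_string(index=False))

# Persist the run in the documented CSV/JSON layout for the other examples
paths = write_experiment(exp, "scratch_example_run")
print(f"\nWrote raw artifacts: {sorted(p.name for p in paths.values())}")
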