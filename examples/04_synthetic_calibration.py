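"""Parameter recovery on synthetic data with the Genetic Algorithm.

Generates a noise-free synthetic gradient from known truth parameters, then
calibrates the 18 model parameters against it with a small GA run and prints
the loss trajectory and the recovered direct-flow efficiency ratio k3/k4 —
one of the combinations the steady-state profile actually constrains (k11,
by contrast, reaches the observable profile only through the tiny cDl* pool
and stays unidentified).  A short demonstration run — recovery experiments
at the scale used for validation take several minutes.
"""

from dorsalgrad import (
    GAConfig,
    SpatialGrid,
    SyntheticConfig,
    evolve,
    generate_model_based,
)

config = SyntheticConfig(noise_sd=0.0, seed=0)
profile, truth = generate_model_based(config)
tp = truth["params"]

ga = GAConfig(population_size=16, generations=12, seed=0)
best, population, history = evolve(profile, ga, SpatialGrid(50))

print("generation best-cost trajectory:")
for gen, cost in enumerate(history["best_cost"]):
    if gen % 3 == 0 or gen == len(history["best_cost"]) - 1:
        print(f"  gen {gen:3d}: {cost:.5f}")
print(f"\nbest loss: {best.cost:.5f}")
print(f"k3/k4: truth {tp.k3 / tp.k4:.2f}  recovered "
      f"{best.params.k3 / best.params.k4:.2f}")
print(
    "\nElitism makes the best cost non-increasing; longer runs (population"
    "\n40+, 60+ generations) drive the loss to the noise floor and pull the"
    "\nidentifiable ratios toward the truth."
)
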