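"""Check the optimizer against an exhaustive grid search on a tiny chain.

For a 4-residue chain the conformation has just three parameters (two
bond angles, one torsion), so the global minimum can be found by brute
force.  The optimizer should match the grid minimum to within the grid's
own resolution error.

Expected output: both numbers agree to ~0.01-0.05 (the optimizer,
working in continuous space, is usually slightly LOWER than the finite
grid).
"""

import numpy as np

from abfold import ABSequence, EnergyModel, GATSConfig, gats_run

seq = ABSequence("ABAB")
model = EnergyModel(seq)

# exhaustive grid over (theta1, theta2, beta1) at 0.05 rad
grid = np.arange(-np.pi, np.pi, 0.05)
best = np.inf
for t1 in grid:
    for t2 in grid:
        e = np.array([model.energy_of_arrays(np.array([t1, t2]), np.array([b])) for b in grid])
        best = min(best, e.min())
print(f"grid-search minimum ({len(grid)**3} evaluations): {best:.4f}")

res = gats_run(seq, GATSConfig(rng_seed=1, max_evaluations=20_000, max_generations=10**6))
print(f"optimizer best ({res.evaluations} evaluations)   : {res.best_energy:.4f}")
print(f"difference: {res.best_energy - best:+.4f} (<= 0.05 expected)")
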