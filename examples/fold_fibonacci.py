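"""Fold the 13-residue Fibonacci chain with the genetic / tabu-search hybrid.

A short demonstration run with a reduced evaluation budget (3e4 instead
of the benchmark 2e5), so it finishes in a few seconds.  The printed
best energy is the lowest AB-model energy found; lower is better, and
the benchmark records for this chain range from -4.97 (simulated
annealing) to -6.95.  A short run typically lands between -3 and -5;
full-budget restarts are what the benchmark comparisons use.
"""

from abfold import GATSConfig, fibonacci_sequence, gats_run

seq = fibonacci_sequence(6)
print(f"sequence: {seq}  (n={len(seq)})")

config = GATSConfig(rng_seed=1, max_evaluations=30_000, max_generations=10**6)
result = gats_run(seq, config)

print(f"best energy   : {result.best_energy:.4f}")
print(f"evaluations   : {result.evaluations}")
print(f"generations   : {len(result.trajectory)}")
print(f"bond angles   : {[round(float(t), 3) for t in result.best_conf.theta]}")
print(f"torsion angles: {[round(float(b), 3) for b in result.best_conf.beta]}")
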