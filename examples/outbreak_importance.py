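"""Estimate per-vertex spreading importance by SIR on the raw contacts.

Simulates the SIR process directly on a small synthetic contact sequence:
for every vertex as seed (infection introduced at that vertex's first
contact) the expected outbreak size sigma_i is averaged over Monte-Carlo
runs.  The transmission probability lambda is first calibrated so the mean
outbreak reaches one fifth of its lambda=1 size, with infective duration
delta = T/5 — an intermediate regime where important and unimportant
spreaders separate cleanly.  Prints the five most and least important
vertices.
"""

import numpy as np

from temponet import (
    SIRParams,
    SyntheticConfig,
    calibrate_lambda,
    generate,
    importance_table,
)

cs = generate(SyntheticConfig(N=120, mu=0.4, T=10_000, rng_seed=3))
lam = calibrate_lambda(cs, n_runs=100, rng_seed=0)
print(f"calibrated lambda = {lam:.4f}  (delta = T/5 = {cs.T / 5:.0f})")

table = importance_table(cs, SIRParams(lam, cs.T / 5, rng_seed=0), n_runs=500)
order = np.argsort(table.mean)
print("\nmost important seeds (sigma_i = expected outbreak size):")
for v in order[::-1][:5]:
    print(f"  vertex {table.labels[v]:>4}  sigma = {table.mean[v]:7.2f} "
          f"+/- {table.se[v]:.2f}")
print("least important seeds:")
for v in order[:5]:
    print(f"  vertex {table.labels[v]:>4}  sigma = {table.mean[v]:7.2f} "
          f"+/- {table.se[v]:.2f}")
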