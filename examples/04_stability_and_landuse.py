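"""Stability across repeated runs and land-use composition of a zoning.

Runs the optimizer several times with different seeds, measures how much
of the protected area is common to every run, and tabulates the final
zoning against a toy categorical land-use map.
"""

import numpy as np

import beezone as bz

rng = np.random.default_rng(3)
grid = bz.random_instance(40, 40, rng, blocked_fraction=0.0)
q = 120
w = bz.Weights(0.34, 0.33, 0.33)

solutions = []
for seed in range(5):
    cfg = bz.IABCConfig(q=q, weights=w, sn=10, limit=50, mcn=80, rng_seed=seed)
    solutions.append(bz.run_iabc(grid, cfg).best_solution)

overlap_pct, counts = bz.run_overlap(solutions, q)
print(f"runs: {len(solutions)}, quota: {q}")
print(f"cells protected in every run: {int((counts == 5).sum())} "
      f"({overlap_pct:.1f}% of Q)")
print(f"cells protected in >= 3 runs: {int((counts >= 3).sum())}")

# toy land-use map: 3 horizontal bands (1=forest, 2=cropland, 3=urban)
landuse = np.ones((40, 40), dtype=int)
landuse[15:30, :] = 2
landuse[30:, :] = 3
table = bz.landuse_stats(solutions[0], landuse)
print()
print("land-use composition of run 0 (counts and shares):")
print(table[["category", "region_count", "protected_count",
             "protected_pct", "protected_within_pct"]].to_string(index=False))
print()
print("protected_pct: share of the protected area in each category;")
print("protected_within_pct: protected share within the category itself.")
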