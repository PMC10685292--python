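"""Bare feasibility-seeking with the AMS projection algorithm.

A random feasible toy system (200 voxel slabs over 30 beamlets, built around
a known nonnegative witness fluence) is solved by iterating AMS sweeps.  The
proximity function V (weighted mean of squared, row-normalized slab
violations) and the maximum violation in Gy both drop to zero.
"""

import numpy as np

import superplan as spn

toy = spn.make_toy_problem(n=200, m=30, density=0.1, feasible=True,
                           slack=0.5, seed=0)
C = spn.ConstraintSystem.from_bounds(toy.lower, toy.upper, matrix=toy.matrix)

# a tight stagnation tolerance lets the run settle all the way down
x, hist = spn.feasibility_solve(np.zeros(30), toy.matrix, C, max_sweeps=500,
                                tol_V=1e-8)

print(f"constructed witness satisfies all slabs: {toy.witness_feasible()}")
print(f"run status: {hist.status} after {hist.iteration[-1]} sweeps")
for i in sorted({0, 1, 5, 10, len(hist) - 1} & set(range(len(hist)))):
    print(f"  sweep {hist.iteration[i]:3d}: V = {hist.V[i]:.3e}, "
          f"max violation = {hist.max_violation[i]:.3e} Gy")
print("V = 0 means every per-voxel dose slab (and x >= 0) is satisfied; "
      "the run stops when V stagnates in relative terms.")
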