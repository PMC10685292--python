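"""Bundled planning problems: the phantom benchmark and problem containers.

`make_phantom_problem` assembles the full end-to-end benchmark: the horseshoe
phantom, its beamlet dose influence matrix, and a prescription shaped like
the classic target/core/body table (target slab around 60 Gy, upper bounds on
the organs at risk, weights 1000/100/30).  Because the analytic dose model
cannot promise that the literal textbook bounds are attainable, the bounds
are derived from an explicitly constructed nonnegative witness fluence (a
nonnegative least-squares fit pushing 60 Gy into the target), then widened to
cover it — so the packaged problem is feasible by construction and every run
against it can be judged on convergence alone.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .feasibility import VOIPrescription, prescription_to_constraints
from .phantom import (BeamConfig, DoseInfluenceMatrix, StructureSet,
                      ToyFeasibilityProblem, VoxelGrid, build_phantom,
                      generate_dose_influence)

__all__ = [
    "PlanningProblem", "default_phantom_prescription", "make_phantom_problem",
]


@dataclasses.dataclass
class PlanningProblem:
    """A dose influence matrix with per-voxel slab bounds and metadata."""

    matrix: DoseInfluenceMatrix
    lower: np.ndarray
    upper: np.ndarray
    weights: np.ndarray | None = None
    structures: StructureSet | None = None
    witness: np.ndarray | None = None
    prescription: list[VOIPrescription] | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_toy(cls, toy: ToyFeasibilityProblem) -> "PlanningProblem":
        return cls(matrix=toy.matrix, lower=toy.lower, upper=toy.upper,
                   witness=toy.witness, metadata={"seed": toy.seed})

    def constraints(self):
        from .feasibility import ConstraintSystem
        return ConstraintSystem.from_bounds(self.lower, self.upper,
                                            self.weights, self.matrix)


def default_phantom_prescription() -> list[VOIPrescription]:
    """Target slab [59, 61] Gy, core <= 20 Gy, body <= 30 Gy, weights 1000/100/30."""
    return [
        VOIPrescription("Target", 59.0, 61.0, 1000.0),
        VOIPrescription("Core", 0.0, 20.0, 100.0),
        VOIPrescription("Body", 0.0, 30.0, 30.0),
    ]


def _witness_fluence(A: DoseInfluenceMatrix, sets: dict[str, np.ndarray],
                     d_ref: float) -> np.ndarray:
    """Nonnegative least-squares fluence pushing d_ref into the target.

    Core and body rows are included with small weights so the fit also keeps
    OAR doses down; the solution is rescaled to a mean target dose of d_ref.
    """
    weights = {"Target": 1.0, "Core": 0.4, "Body": 0.15}
    goals = {"Target": d_ref, "Core": 0.0, "Body": 0.0}
    blocks, rhs = [], []
    for name, w in weights.items():
        idx = sets.get(name)
        if idx is None or idx.size == 0:
            continue
        blocks.append(w * A.csr[idx].toarray())
        rhs.append(np.full(idx.size, w * goals[name]))
    x, _ = nnls(np.vstack(blocks), np.concatenate(rhs))
    d_t = A.csr[sets["Target"]] @ x
    mean_t = float(d_t.mean())
    if mean_t <= 0:
        raise RuntimeError("witness construction failed: no dose reaches the target")
    return x * (d_ref / mean_t)


def make_phantom_problem(grid: VoxelGrid | None = None,
                         beams: BeamConfig | None = None,
                         prescription: Sequence[VOIPrescription] | None = None,
                         margin: float = 1.02) -> PlanningProblem:
    """The packaged end-to-end benchmark problem (feasible by construction).

    Builds the horseshoe phantom and its dose influence matrix, fits a
    nonnegative witness fluence, and widens each VOI's prescribed slab just
    enough to contain the witness dose (times a small ``margin``): the target
    keeps a symmetric slab around its reference dose, the organs at risk keep
    pure upper bounds.  Deterministic.
    """
    grid = grid or VoxelGrid()
    beams = beams or BeamConfig()
    pres = list(prescription or default_phantom_prescription())
    structures = build_phantom(grid)
    A = generate_dose_influence(grid, structures, beams)
    sets = structures.exclusive_partition(grid.n)
    by_name = {p.name: p for p in pres}
    target = by_name["Target"]
    d_ref = 0.5 * (target.lower + target.upper)
    x_star = _witness_fluence(A, sets, d_ref)
    d_star = A.dose(x_star)

    adjusted: list[VOIPrescription] = []
    for p in pres:
        idx = sets[p.name]
        if idx.size == 0:
            adjusted.append(p)
            continue
        d_s = d_star[idx]
        if math.isfinite(p.upper) and p.lower > 0:  # target-like slab
            half = max((p.upper - p.lower) / 2.0,
                       margin * float(np.max(np.abs(d_s - d_ref))))
            adjusted.append(VOIPrescription(p.name, d_ref - half, d_ref + half,
                                            p.weight))
        elif math.isfinite(p.upper):
            upper = max(p.upper, margin * float(d_s.max()))
            adjusted.append(VOIPrescription(p.name, p.lower, upper, p.weight))
        else:
            adjusted.append(p)

    C = prescription_to_constraints(structures, adjusted, A)
    return PlanningProblem(
        matrix=A, lower=C.lower, upper=C.upper, weights=C.weights,
        structures=structures, witness=x_star, prescription=adjusted,
        metadata={
            "grid_shape": list(grid.shape), "grid_spacing": list(grid.spacing),
            "beamlets": A.m, "prescription": [dataclasses.asdict(p) for p in adjusted],
        })
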