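"""Voxel-wise hyperslab feasibility and the weighted sequential AMS sweep.

Every voxel carries a dose slab ``lower_i <= <a_i, x> <= upper_i`` (a
hyperslab in beamlet-intensity space) plus the global nonnegativity
constraint ``x >= 0``.  The sequential relaxation method of Agmon, Motzkin
and Schoenberg (AMS) visits the active voxels in a chosen control-sequence
order and, when a slab side is violated, projects the current point onto the
violated half-space with relaxation ``lambda in (0, 2]`` scaled by a
per-voxel weight ``nu_i in (0, 1]``.  A full sweep ends with a single
projection onto the nonnegative orthant.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import time
from typing import Sequence

import numpy as np
import pandas as pd

from .history import RunHistory, stopping_met
from .phantom import DoseInfluenceMatrix, StructureSet

log = logging.getLogger(__name__)

__all__ = [
    "ConstraintSystem", "ControlSequence", "VOIPrescription",
    "prescription_to_constraints", "halfspace_step", "ams_sweep",
    "make_control_sequence", "proximity_V", "max_violation",
    "feasibility_solve",
]

CONTROL_KINDS = ("cyclic", "random", "weight_ascending", "weight_descending")


def _as_influence(A) -> DoseInfluenceMatrix:
    return A if isinstance(A, DoseInfluenceMatrix) else DoseInfluenceMatrix(A)


@dataclasses.dataclass
class ConstraintSystem:
    """Per-voxel slab bounds with projection weights and the active set.

    ``lower`` defaults to 0 (OARs get no positive lower bound), ``upper`` may
    be +inf.  The active set contains the voxels with a nontrivial finite
    slab (anything other than ``[0, inf)``) and a nonzero matrix row; only
    those are visited by the sweep and scored by the proximity measures.
    """

    lower: np.ndarray
    upper: np.ndarray
    weights: np.ndarray
    active: np.ndarray

    @classmethod
    def from_bounds(cls, lower, upper, weights=None,
                    matrix: DoseInfluenceMatrix | None = None) -> "ConstraintSystem":
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if lower.shape != upper.shape:
            raise ValueError("lower and upper bounds must have the same shape")
        if np.any(lower < 0):
            raise ValueError("lower bounds must be >= 0")
        if np.any(lower > upper):
            bad = int(np.argmax(lower > upper))
            raise ValueError(f"lower > upper at voxel {bad}")
        if weights is None:
            weights = np.ones_like(lower)
        weights = np.asarray(weights, dtype=float)
        if np.any((weights <= 0) | (weights > 1)):
            raise ValueError("projection weights must lie in (0, 1]")
        nontrivial = (lower > 0) | np.isfinite(upper)
        if matrix is not None:
            zero = matrix.zero_rows
            n_dropped = int(np.count_nonzero(nontrivial & zero))
            if n_dropped:
                log.warning("%d constrained voxels have all-zero dose rows; "
                            "excluded from the active set", n_dropped)
            nontrivial &= ~zero
        return cls(lower, upper, weights, np.flatnonzero(nontrivial))

    @property
    def n(self) -> int:
        return self.lower.size

    @property
    def n_active(self) -> int:
        return self.active.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "voxel_index": np.arange(self.n),
            "lower": self.lower,
            "upper": self.upper,
            "weight": self.weights,
        })


@dataclasses.dataclass(frozen=True)
class VOIPrescription:
    """Per-VOI dose bounds (Gy) and relative projection weight."""

    name: str
    lower: float = 0.0
    upper: float = math.inf
    weight: float = 1.0

    def __post_init__(self):
        if self.lower < 0 or self.lower > self.upper:
            raise ValueError(
                f"prescription for {self.name!r}: need 0 <= lower <= upper, "
                f"got [{self.lower}, {self.upper}]")
        if self.weight <= 0:
            raise ValueError(f"prescription weight for {self.name!r} must be > 0")


def prescription_to_constraints(structures: StructureSet,
                                prescription: Sequence[VOIPrescription],
                                matrix: DoseInfluenceMatrix | None = None,
                                ) -> ConstraintSystem:
    """Expand per-VOI bounds to per-voxel slabs on the exclusive partition.

    Each voxel receives the bounds of its highest-priority containing
    structure.  Projection weights are the VOI's relative weight rescaled
    into (0, 1] by the maximum prescription weight.  Voxels owned by no
    prescribed structure stay at the trivial slab ``[0, inf)`` and are
    excluded from the active set.
    """
    by_name = {p.name: p for p in prescription}
    for name in by_name:
        if name not in structures:
            raise ValueError(f"prescription references unknown structure {name!r}")
    n = matrix.n if matrix is not None else max(
        (int(s.indices[-1]) + 1 for s in structures if len(s)), default=0)
    sets = structures.exclusive_partition(n)
    lower = np.zeros(n)
    upper = np.full(n, math.inf)
    weights = np.ones(n)
    w_max = max(p.weight for p in by_name.values())
    unassigned = 0
    for name, p in by_name.items():
        idx = sets[name]
        lower[idx] = p.lower
        upper[idx] = p.upper
        weights[idx] = p.weight / w_max
    for name, s in ((s.name, s) for s in structures if s.name not in by_name):
        unassigned += sets[name].size
    if unassigned:
        log.info("%d voxels belong to structures without a prescription; "
                 "they carry the trivial slab [0, inf)", unassigned)
    return ConstraintSystem.from_bounds(lower, upper, weights, matrix)


def halfspace_step(x: np.ndarray, a: np.ndarray, bound: float, side: str,
                   step_weight: float) -> np.ndarray:
    """Relaxed projection of ``x`` onto one half-space of a voxel slab.

    For the upper side with ``<a, x> > bound``:
    ``x' = x - step_weight * (<a, x> - bound) / ||a||^2 * a``; the lower side
    is symmetric.  ``step_weight`` is the product ``lambda * nu_i``; with
    step weight 1 the violated constraint's residual is closed exactly.
    Non-violated constraints leave ``x`` unchanged.
    """
    if side not in ("lower", "upper"):
        raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")
    x = np.asarray(x, dtype=float).copy()
    a = np.asarray(a, dtype=float)
    sq = float(a @ a)
    if sq == 0.0:
        log.warning("halfspace_step: zero row skipped")
        return x
    dot = float(a @ x)
    if side == "upper" and dot > bound:
        x -= step_weight * (dot - bound) / sq * a
    elif side == "lower" and dot < bound:
        x += step_weight * (bound - dot) / sq * a
    return x


@dataclasses.dataclass
class ControlSequence:
    """Visit order of the active voxels within each sweep.

    ``cyclic``: ascending voxel index; ``random``: seeded shuffle, redrawn
    each sweep; ``weight_ascending``/``weight_descending``: stable sort by
    the per-voxel weights.
    """

    kind: str = "cyclic"
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in CONTROL_KINDS:
            raise ValueError(f"unknown control sequence {self.kind!r}; known: {CONTROL_KINDS}")
        self._rng = np.random.default_rng(self.seed)

    def draw(self, C: ConstraintSystem) -> np.ndarray:
        return make_control_sequence(self.kind, C, self._rng)


def make_control_sequence(kind: str, C: ConstraintSystem,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """One sweep's permutation of the active voxel set."""
    if kind not in CONTROL_KINDS:
        raise ValueError(f"unknown control sequence {kind!r}; known: {CONTROL_KINDS}")
    act = np.sort(C.active)
    if kind == "cyclic":
        return act
    if kind == "random":
        rng = rng if rng is not None else np.random.default_rng()
        return rng.permutation(act)
    w = C.weights[act]
    order = np.argsort(w if kind == "weight_ascending" else -w, kind="stable")
    return act[order]


def _sequence_for(sequence, seed=None) -> ControlSequence:
    if isinstance(sequence, ControlSequence):
        return sequence
    return ControlSequence(kind=sequence, seed=seed)


def ams_sweep(x: np.ndarray, A, C: ConstraintSystem, lam: float = 1.0,
              order: np.ndarray | None = None,
              weight_scale: float = 1.0) -> np.ndarray:
    """One complete AMS sweep: sequential slab projections + orthant clamp.

    Visits every active voxel once in ``order`` (default cyclic); at each
    voxel the upper-bound half-space step is applied first, then the
    lower-bound step, with effective weight ``lam * weight_scale * nu_i``.
    After the full pass, ``x`` is clamped to the nonnegative orthant.  Pure
    function of its inputs (the input vector is not modified).
    """
    if not (0.0 < lam <= 2.0):
        raise ValueError(f"relaxation parameter must lie in (0, 2], got {lam}")
    if not (0.0 < weight_scale <= 1.0):
        raise ValueError(f"weight scale must lie in (0, 1], got {weight_scale}")
    A = _as_influence(A)
    xp = np.array(x, dtype=float, copy=True)
    if xp.shape != (A.m,):
        raise ValueError(f"x has shape {xp.shape}, expected ({A.m},)")
    if not np.all(np.isfinite(xp)):
        raise ValueError("x must be finite")
    if order is None:
        order = np.sort(C.active)
    indptr, indices, data = A.csr.indptr, A.csr.indices, A.csr.data
    rsq = A.row_sq_norms
    lower, upper = C.lower, C.upper
    w_eff = lam * weight_scale * C.weights
    for i in order:
        s0, s1 = indptr[i], indptr[i + 1]
        cols = indices[s0:s1]
        vals = data[s0:s1]
        xs = xp[cols]
        dot = vals @ xs
        changed = False
        u = upper[i]
        if dot > u:
            xs = xs - (w_eff[i] * (dot - u) / rsq[i]) * vals
            dot = vals @ xs
            changed = True
        lo = lower[i]
        if dot < lo:
            xs = xs + (w_eff[i] * (lo - dot) / rsq[i]) * vals
            changed = True
        if changed:
            xp[cols] = xs
    np.maximum(xp, 0.0, out=xp)
    return xp


def _active_residuals(x, A: DoseInfluenceMatrix, C: ConstraintSystem):
    act = C.active
    d = (A.csr @ np.asarray(x, dtype=float))[act]
    below = np.maximum(C.lower[act] - d, 0.0)
    above = np.maximum(d - C.upper[act], 0.0)
    return act, below, above


def proximity_V(x, A, C: ConstraintSystem) -> float:
    """Weighted mean of squared, row-normalized slab violations.

    ``V = (1/n_active) * sum_i [ (l_i - <a_i,x>)_+^2 + (<a_i,x> - u_i)_+^2 ]
    / ||a_i||^2`` over the active voxels; zero exactly on the feasible set.
    """
    A = _as_influence(A)
    if C.n_active == 0:
        raise ValueError("proximity_V requires a nonempty active set")
    act, below, above = _active_residuals(x, A, C)
    return float(np.sum((below ** 2 + above ** 2) / A.row_sq_norms[act]) / act.size)


def max_violation(x, A, C: ConstraintSystem) -> float:
    """Infinity norm of the slab violations (Gy); 0 for a feasible point."""
    A = _as_influence(A)
    if C.n_active == 0:
        return 0.0
    _, below, above = _active_residuals(x, A, C)
    return float(max(below.max(initial=0.0), above.max(initial=0.0)))


def feasibility_solve(x0, A, C: ConstraintSystem, lam: float = 1.0,
                      sequence="cyclic", max_sweeps: int = 500,
                      max_time: float = 3000.0, tol_V: float = 1e-3,
                      consecutive: int = 3, seed: int | None = None,
                      ) -> tuple[np.ndarray, RunHistory]:
    """Bare feasibility-seeking: iterate AMS sweeps with weight scale 1.

    Stops on proximity stagnation (relative change of V below ``tol_V`` for
    ``consecutive`` consecutive sweeps; disable with a negative tolerance),
    on ``max_sweeps``, or on ``max_time`` seconds.  The history records V and
    the maximum violation per sweep (f is NaN: no objective is involved).
    """
    A = _as_influence(A)
    x = np.array(x0, dtype=float, copy=True)
    if np.any(x < 0):
        raise ValueError("x0 must be nonnegative")
    seq = _sequence_for(sequence, seed)
    hist = RunHistory()
    t0 = time.perf_counter()
    hist.append(0, math.nan, proximity_V(x, A, C), max_violation(x, A, C),
                0, 0, 0.0)
    hist.status = "max_iterations"
    for sweep in range(1, max_sweeps + 1):
        order = seq.draw(C)
        x = ams_sweep(x, A, C, lam, order, weight_scale=1.0)
        elapsed = time.perf_counter() - t0
        hist.append(sweep, math.nan, proximity_V(x, A, C),
                    max_violation(x, A, C), 0, 0, elapsed)
        if stopping_met(hist, tol_f=-1.0, tol_V=tol_V, consecutive=consecutive):
            hist.status = "stopped_criterion"
            break
        if elapsed > max_time:
            hist.status = "max_time"
            break
    return x, hist
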