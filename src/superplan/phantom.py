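"""Synthetic planning problems: voxel phantom, beamlet dose model, toy systems.

This module generates everything needed to exercise the planning algorithms
without clinical data:

* a voxelized phantom with a C-shaped (horseshoe) target wrapping a central
  core organ-at-risk inside an elliptical body contour — the classic
  commissioning geometry used for IMRT benchmarks;
* a physically plausible multi-field beamlet dose influence matrix
  (exponential depth attenuation times a lateral Gaussian kernel along each
  beamlet ray);
* small random hyperslab feasibility problems with a known nonnegative
  witness (or a provably infeasible pair of duplicated rows), used as oracles
  for the projection algorithms.

All generators are pure functions of their parameters and seed.
Voxel linear indices are 0-based, x-fastest: ``i = ix + nx*(iy + ny*iz)``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "VoxelGrid", "Structure", "StructureSet", "BeamConfig",
    "DoseInfluenceMatrix", "ToyFeasibilityProblem", "PhantomGeometryError",
    "build_phantom", "generate_dose_influence", "make_toy_problem",
]


class PhantomGeometryError(ValueError):
    """Requested phantom geometry does not fit inside the voxel grid."""


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid with physical spacing in mm.

    The grid is centered on the origin; voxel ``(ix, iy, iz)`` has its center
    at ``((ix + 0.5 - nx/2)*sx, ...)`` mm.  Linear indices are x-fastest.
    """

    shape: tuple[int, int, int] = (64, 64, 1)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(v) < 1 for v in self.shape):
            raise ValueError(f"grid shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(v <= 0 for v in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))

    @property
    def n(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def linear_index(self, ix, iy, iz):
        nx, ny, _ = self.shape
        return ix + nx * (iy + ny * iz)

    def unravel(self, idx):
        idx = np.asarray(idx)
        nx, ny, _ = self.shape
        return idx % nx, (idx // nx) % ny, idx // (nx * ny)

    def coords(self) -> np.ndarray:
        """(n, 3) array of voxel-center coordinates in mm, grid-centered."""
        nx, ny, nz = self.shape
        sx, sy, sz = self.spacing
        idx = np.arange(self.n)
        ix, iy, iz = self.unravel(idx)
        return np.column_stack([
            (ix + 0.5 - nx / 2.0) * sx,
            (iy + 0.5 - ny / 2.0) * sy,
            (iz + 0.5 - nz / 2.0) * sz,
        ])


@dataclasses.dataclass(frozen=True)
class Structure:
    """A named voxel-index set with a priority rank (smaller = higher)."""

    name: str
    indices: np.ndarray
    priority: int

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=np.intp))
        object.__setattr__(self, "indices", idx)
        if idx.size and idx[0] < 0:
            raise ValueError(f"structure {self.name!r} has negative voxel indices")

    def __len__(self) -> int:
        return int(self.indices.size)


class StructureSet:
    """Ordered collection of structures with unique names and priorities."""

    def __init__(self, structures: Sequence[Structure]):
        self.structures = list(structures)
        names = [s.name for s in self.structures]
        prios = [s.priority for s in self.structures]
        if len(set(names)) != len(names):
            raise ValueError("structure names must be unique")
        if len(set(prios)) != len(prios):
            raise ValueError("structure priority ranks must be unique")
        self._by_name = {s.name: s for s in self.structures}

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    def __getitem__(self, name: str) -> Structure:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.structures)

    def __len__(self) -> int:
        return len(self.structures)

    def validate_against(self, n: int) -> None:
        for s in self.structures:
            if s.indices.size and s.indices[-1] >= n:
                raise ValueError(
                    f"structure {s.name!r} contains voxel index {int(s.indices[-1])} >= n={n}")

    def exclusive_partition(self, n: int) -> dict[str, np.ndarray]:
        """Assign every voxel to its highest-priority containing structure.

        Returns name -> sorted voxel indices; the sets are pairwise disjoint.
        Voxels contained in no structure are absent from all sets.
        """
        self.validate_against(n)
        owner = np.full(n, -1, dtype=np.intp)
        # paint from lowest to highest priority so higher priority overwrites
        for rank, s in sorted(enumerate(self.structures),
                              key=lambda t: -self.structures[t[0]].priority):
            owner[s.indices] = rank
        return {s.name: np.flatnonzero(owner == rank)
                for rank, s in enumerate(self.structures)}


@dataclasses.dataclass(frozen=True)
class BeamConfig:
    """Multi-field beamlet geometry and the analytic dose kernel parameters.

    The kernel deposits, along each beamlet ray, ``scale * exp(-mu * depth) *
    exp(-lateral^2 / (2 sigma^2))`` inside the body contour, where depth is
    measured from the body entry point of the beamlet.  Entries below
    ``cutoff_rel`` times the beamlet maximum are dropped to control sparsity.
    """

    gantry_angles_deg: tuple[float, ...] = (0.0, 72.0, 144.0, 216.0, 288.0)
    beamlet_width_mm: float = 2.5
    mu_per_mm: float = 0.005
    lateral_sigma_mm: float = 3.0
    scale_gy: float = 1.0
    cutoff_rel: float = 1e-4

    def __post_init__(self):
        for a in self.gantry_angles_deg:
            if not (0.0 <= a < 360.0):
                raise ValueError(f"gantry angles must lie in [0, 360), got {a}")
        if self.beamlet_width_mm <= 0 or self.mu_per_mm < 0 \
                or self.lateral_sigma_mm <= 0 or self.scale_gy <= 0:
            raise ValueError("beamlet width, sigma and scale must be positive; mu >= 0")


class DoseInfluenceMatrix:
    """Sparse nonnegative n x m map from beamlet intensities to voxel doses.

    Caches per-row squared Euclidean norms (needed by every projection step)
    and flags all-zero rows.
    """

    def __init__(self, matrix):
        A = sp.csr_matrix(matrix, dtype=float)
        if A.nnz and A.data.min() < 0:
            raise ValueError("dose influence entries must be nonnegative")
        A.sum_duplicates()
        self.csr = A
        self.row_sq_norms = np.asarray(A.multiply(A).sum(axis=1)).ravel()
        self.zero_rows = self.row_sq_norms == 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.csr.shape

    @property
    def n(self) -> int:
        return self.csr.shape[0]

    @property
    def m(self) -> int:
        return self.csr.shape[1]

    def dose(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.m,):
            raise ValueError(f"intensity vector has shape {x.shape}, expected ({self.m},)")
        return self.csr @ x


def build_phantom(grid: VoxelGrid, *,
                  target_inner_mm: float = 15.0,
                  target_outer_mm: float = 35.0,
                  target_gap_deg: float = 90.0,
                  core_radius_mm: float = 10.0,
                  body_semiaxes_mm: tuple[float, float] = (65.0, 55.0)) -> StructureSet:
    """Build the horseshoe phantom masks: C-shaped Target, central Core, Body.

    The target is an annulus sector (inner/outer radius, with an angular gap
    of ``target_gap_deg`` opening toward +x); the core is a central disc of
    radius ``core_radius_mm`` (strictly inside the annulus); the body is an
    axis-aligned ellipse enclosing both.  All shapes are extruded through
    every z slice.  Priorities: Target 0 (highest), Core 1, Body 2.
    """
    ri, ro = float(target_inner_mm), float(target_outer_mm)
    rc = float(core_radius_mm)
    ba, bb = (float(v) for v in body_semiaxes_mm)
    if min(ri, ro, rc, ba, bb) < 0:
        raise PhantomGeometryError("phantom radii must be nonnegative")
    if ri > ro:
        raise PhantomGeometryError(f"target inner radius {ri} exceeds outer radius {ro}")
    if rc > 0 and rc >= ri:
        raise PhantomGeometryError(
            f"core radius {rc} must be strictly smaller than target inner radius {ri}")
    nx, ny, _ = grid.shape
    half_x = nx * grid.spacing[0] / 2.0
    half_y = ny * grid.spacing[1] / 2.0
    if ro > max(half_x, half_y) or ba > half_x or bb > half_y:
        raise PhantomGeometryError(
            f"geometry (target outer {ro} mm, body {ba}x{bb} mm) exceeds grid "
            f"half-extent {half_x}x{half_y} mm")

    xy = grid.coords()[:, :2]
    r = np.hypot(xy[:, 0], xy[:, 1])
    ang = np.degrees(np.arctan2(xy[:, 1], xy[:, 0]))

    target = (r >= ri) & (r <= ro) & (np.abs(ang) >= target_gap_deg / 2.0)
    core = r < rc
    if ba > 0 and bb > 0:
        body = (xy[:, 0] / ba) ** 2 + (xy[:, 1] / bb) ** 2 <= 1.0
    else:
        body = (xy[:, 0] == 0.0) & (xy[:, 1] == 0.0)

    return StructureSet([
        Structure("Target", np.flatnonzero(target), priority=0),
        Structure("Core", np.flatnonzero(core), priority=1),
        Structure("Body", np.flatnonzero(body), priority=2),
    ])


def generate_dose_influence(grid: VoxelGrid, structures: StructureSet,
                            beams: BeamConfig = BeamConfig()) -> DoseInfluenceMatrix:
    """Compute the beamlet dose influence matrix for the phantom.

    For each gantry angle, beamlets are laid out laterally across the
    projected extent of the Target (plus one beamlet-width margin on each
    side), spaced by the beamlet width.  Each beamlet deposits dose only in
    Body voxels, with exponential attenuation along depth (measured from the
    beamlet's body entry) and a Gaussian lateral profile.  Deterministic for
    fixed inputs.
    """
    structures.validate_against(grid.n)
    body_idx = structures["Body"].indices if "Body" in structures \
        else np.unique(np.concatenate([s.indices for s in structures]))
    if body_idx.size == 0:
        raise ValueError("Body structure is empty; no medium to deposit dose in")
    aperture_idx = structures["Target"].indices if "Target" in structures and \
        len(structures["Target"]) else body_idx

    xy = grid.coords()[:, :2]
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    col = 0
    w = beams.beamlet_width_mm
    sig = beams.lateral_sigma_mm
    support = max(3.0 * sig, w)
    for theta_deg in beams.gantry_angles_deg:
        th = math.radians(theta_deg)
        u = np.array([math.sin(th), -math.cos(th)])   # beam direction
        v = np.array([math.cos(th), math.sin(th)])    # lateral axis
        t_body = xy[body_idx] @ u
        l_body = xy[body_idx] @ v
        l_ap = xy[aperture_idx] @ v
        lo, hi = float(l_ap.min()) - w, float(l_ap.max()) + w
        offsets = np.arange(lo, hi + 1e-9, w)
        for o in offsets:
            lat = l_body - o
            sel = np.abs(lat) <= support
            if not np.any(sel):
                continue
            depth = t_body[sel] - t_body[sel].min()
            dose = beams.scale_gy * np.exp(-beams.mu_per_mm * depth) \
                * np.exp(-lat[sel] ** 2 / (2.0 * sig ** 2))
            keep = dose >= beams.cutoff_rel * dose.max()
            if not np.any(keep):
                continue
            rows.append(body_idx[sel][keep])
            cols.append(np.full(int(keep.sum()), col, dtype=np.intp))
            vals.append(dose[keep])
            col += 1
    if col == 0:
        raise ValueError("beam configuration produced zero beamlets")
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(grid.n, col))
    dropped = sum(len(r) for r in rows)
    log.debug("dose influence: %d beamlets, %d nonzeros (cutoff %.1e relative)",
              col, dropped, beams.cutoff_rel)
    return DoseInfluenceMatrix(A)


@dataclasses.dataclass
class ToyFeasibilityProblem:
    """Random hyperslab system, feasible (with witness) or provably infeasible."""

    matrix: DoseInfluenceMatrix
    lower: np.ndarray
    upper: np.ndarray
    witness: np.ndarray | None
    seed: int

    def witness_feasible(self, atol: float = 1e-9) -> bool:
        if self.witness is None:
            return False
        d = self.matrix.dose(self.witness)
        return bool(np.all(self.witness >= 0)
                    and np.all(d >= self.lower - atol)
                    and np.all(d <= self.upper + atol))


def make_toy_problem(n: int = 200, m: int = 30, density: float = 0.1,
                     feasible: bool = True, slack: float = 0.5,
                     seed: int = 0) -> ToyFeasibilityProblem:
    """Draw a random nonnegative sparse system with per-voxel slab bounds.

    Feasible construction: draw nonnegative sparse A (every row gets at least
    one nonzero) and a strictly positive witness ``x*``; bounds are
    ``[<a_i, x*> - slack (clipped at 0), <a_i, x*> + slack]``.

    Infeasible construction: additionally duplicate one row onto another and
    give the pair disjoint slabs, which is unsatisfiable regardless of x
    (the same linear functional cannot lie in two disjoint intervals).
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    if not (0 < density <= 1):
        raise ValueError(f"density must lie in (0, 1], got {density}")
    if feasible and slack <= 0:
        raise ValueError("slack must be positive for a feasible construction")
    slack = float(abs(slack)) if slack else 0.5
    rng = np.random.default_rng(seed)

    rows, cols, vals = [], [], []
    for i in range(n):
        nnz = max(1, int(rng.binomial(m, density)))
        c = rng.choice(m, size=nnz, replace=False)
        rows.append(np.full(nnz, i, dtype=np.intp))
        cols.append(c.astype(np.intp))
        vals.append(rng.uniform(0.5, 1.5, size=nnz))
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, m)).tocsr()

    x_star = rng.uniform(0.5, 1.5, size=m)
    t = A @ x_star
    lower = np.clip(t - slack, 0.0, None)
    upper = t + slack

    if feasible:
        return ToyFeasibilityProblem(DoseInfluenceMatrix(A), lower, upper,
                                     x_star, seed)

    # force infeasibility: rows i2 := row i1, with disjoint slabs around t[i1]
    if n < 2:
        raise ValueError("infeasible construction needs n >= 2")
    i1, i2 = rng.choice(n, size=2, replace=False)
    A = A.tolil()
    A.rows[i2] = list(A.rows[i1])
    A.data[i2] = list(A.data[i1])
    A = A.tocsr()
    gap = max(0.5, min(1.0, t[i1] / 2.0))
    lower[i1], upper[i1] = t[i1] + gap, t[i1] + gap + slack
    lower[i2], upper[i2] = max(t[i1] - gap - slack, 0.0), max(t[i1] - gap, 0.0)
    if upper[i2] >= lower[i1]:  # degenerate tiny t; push the slabs apart
        lower[i1] = upper[i2] + gap
        upper[i1] = lower[i1] + slack
    return ToyFeasibilityProblem(DoseInfluenceMatrix(A), lower, upper, None, seed)
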