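"""Per-structure dose objectives with analytic gradients, and their weighted sum.

The objective vocabulary is the standard fluence-optimization set: squared
deviation from a reference dose, one-sided squared overdose/underdose
penalties, mean dose, and dose-volume-histogram (DVH) penalties that act only
on the voxels between the reference dose and the dose at the prescribed
volume fraction.  All objectives are normalized by the structure size so
values are comparable across structures and runs.

Values are functions of the dose restricted to a structure; the composite
chains them to beamlet-intensity space through the dose influence matrix
(``d = Ax``), computing the dose once per evaluation.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .phantom import DoseInfluenceMatrix, StructureSet

__all__ = [
    "KINDS", "canonical_kind", "ObjectiveSpec", "CompositeObjective",
    "objective_value", "objective_gradient", "inverse_dvh_quantile",
    "dvh_objective",
]

KINDS = ("sq_deviation", "sq_overdose", "sq_underdose", "mean_dose",
         "max_dvh", "min_dvh")

_ALIASES = {
    "sqdev": "sq_deviation", "f_sqdev": "sq_deviation",
    "sqdev+": "sq_overdose", "f_sqdev+": "sq_overdose",
    "sqdev-": "sq_underdose", "f_sqdev-": "sq_underdose",
    "mean": "mean_dose", "f_mean": "mean_dose",
    "maxdvh": "max_dvh", "f_maxdvh": "max_dvh",
    "mindvh": "min_dvh", "f_mindvh": "min_dvh",
}

_DVH_KINDS = ("max_dvh", "min_dvh")


def canonical_kind(kind: str) -> str:
    k = kind.strip().lower()
    k = _ALIASES.get(k, k)
    if k not in KINDS:
        raise ValueError(f"unknown objective kind {kind!r}; known: {KINDS}")
    return k


def _check_doses(doses) -> np.ndarray:
    d = np.asarray(doses, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("doses must be a nonempty 1-D array (empty structure?)")
    return d


def inverse_dvh_quantile(doses, volume: float) -> float:
    """Dose received by the hottest ``volume`` fraction of the structure.

    Nearest-rank convention on the descending sort: the returned value is the
    element at 1-based rank ``max(1, round(volume * |S|))`` (round half up).
    Ties in dose are handled by sort stability.
    """
    d = _check_doses(doses)
    if not (0.0 < volume < 1.0):
        raise ValueError(f"volume fraction must lie in (0, 1), got {volume}")
    rank = max(1, int(math.floor(volume * d.size + 0.5)))
    return float(np.sort(d, kind="stable")[::-1][rank - 1])


def _dvh_mask(d: np.ndarray, d_ref: float, volume: float, kind: str) -> np.ndarray:
    d_v = inverse_dvh_quantile(d, volume)
    if kind == "max_dvh":
        return (d > d_ref) & (d <= d_v)
    return (d >= d_v) & (d < d_ref)


def dvh_objective(kind: str, doses, d_ref: float, volume: float):
    """Value and per-voxel gradient of a DVH penalty.

    ``max_dvh`` penalizes ``(1/|S|) * sum (d_i - d_ref)^2`` over voxels with
    ``d_ref < d_i <= d_V`` (hot voxels that could be cooled without changing
    the DVH at the prescribed volume); ``min_dvh`` is the mirror case over
    ``d_V <= d_i < d_ref``.  The quantile ``d_V`` is treated as constant
    during differentiation, so the gradient is nonzero only on the penalized
    set (the conventional subgradient-style choice).
    """
    kind = canonical_kind(kind)
    if kind not in _DVH_KINDS:
        raise ValueError(f"{kind!r} is not a DVH objective")
    d = _check_doses(doses)
    mask = _dvh_mask(d, d_ref, volume, kind)
    dev = np.where(mask, d - d_ref, 0.0)
    value = float(dev @ dev) / d.size
    grad = 2.0 * dev / d.size
    return value, grad


def objective_value(kind: str, doses, d_ref: float | None = None,
                    volume: float | None = None) -> float:
    """Scalar objective value on the dose restricted to one structure."""
    kind = canonical_kind(kind)
    d = _check_doses(doses)
    if kind == "mean_dose":
        return float(d.mean())
    if kind in _DVH_KINDS:
        return dvh_objective(kind, d, d_ref, volume)[0]
    dev = d - d_ref
    if kind == "sq_overdose":
        dev = np.maximum(dev, 0.0)
    elif kind == "sq_underdose":
        dev = np.minimum(dev, 0.0)
    return float(dev @ dev) / d.size


def objective_gradient(kind: str, doses, d_ref: float | None = None,
                       volume: float | None = None) -> np.ndarray:
    """Per-voxel dose gradient of :func:`objective_value` (same length as S)."""
    kind = canonical_kind(kind)
    d = _check_doses(doses)
    if kind == "mean_dose":
        return np.full(d.size, 1.0 / d.size)
    if kind in _DVH_KINDS:
        return dvh_objective(kind, d, d_ref, volume)[1]
    dev = d - d_ref
    if kind == "sq_overdose":
        dev = np.maximum(dev, 0.0)
    elif kind == "sq_underdose":
        dev = np.minimum(dev, 0.0)
    return 2.0 * dev / d.size


@dataclasses.dataclass(frozen=True)
class ObjectiveSpec:
    """One weighted objective term attached to a named structure."""

    kind: str
    structure: str
    weight: float
    d_ref: float | None = None
    volume: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "kind", canonical_kind(self.kind))
        if self.weight < 0:
            raise ValueError(f"objective weight must be >= 0, got {self.weight}")
        if self.kind != "mean_dose":
            if self.d_ref is None or self.d_ref < 0:
                raise ValueError(f"{self.kind} requires a reference dose >= 0 Gy")
        if self.kind in _DVH_KINDS:
            if self.volume is None or not (0.0 < self.volume < 1.0):
                raise ValueError(f"{self.kind} requires a volume fraction in (0, 1)")


class CompositeObjective:
    """Weighted sum of per-structure objectives, chained through ``d = Ax``.

    Structures are resolved to their exclusive (priority-based) voxel
    partition once at construction.  ``value_and_gradient`` performs a single
    sparse dose computation and a single transposed product for the chain
    rule ``g = A[S]^T (df/dd)``.
    """

    def __init__(self, specs: Sequence[ObjectiveSpec], structures: StructureSet,
                 matrix: DoseInfluenceMatrix):
        self.specs = list(specs)
        self.matrix = matrix
        self.structures = structures
        self._sets = structures.exclusive_partition(matrix.n)
        for spec in self.specs:
            if spec.structure not in self._sets:
                raise ValueError(f"objective references unknown structure {spec.structure!r}")
            if self._sets[spec.structure].size == 0:
                raise ValueError(f"objective on empty structure {spec.structure!r}")

    @property
    def total_weight(self) -> float:
        return float(sum(s.weight for s in self.specs))

    def value_from_dose(self, d: np.ndarray) -> float:
        return float(sum(
            spec.weight * objective_value(spec.kind, d[self._sets[spec.structure]],
                                          spec.d_ref, spec.volume)
            for spec in self.specs))

    def value(self, x: np.ndarray) -> float:
        return self.value_from_dose(self.matrix.dose(x))

    def value_and_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.matrix.dose(x)
        f = 0.0
        gd = np.zeros(self.matrix.n)
        for spec in self.specs:
            if spec.weight == 0.0:
                continue
            idx = self._sets[spec.structure]
            f += spec.weight * objective_value(spec.kind, d[idx], spec.d_ref, spec.volume)
            gd[idx] += spec.weight * objective_gradient(spec.kind, d[idx],
                                                        spec.d_ref, spec.volume)
        g = self.matrix.csr.T @ gd
        return float(f), np.asarray(g).ravel()
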