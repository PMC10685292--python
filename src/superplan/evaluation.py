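"""Plan-quality analytics: dose, cumulative DVHs, statistics, run comparison."""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .objectives import inverse_dvh_quantile
from .phantom import DoseInfluenceMatrix, StructureSet
from .superiorize import PlanResult

__all__ = [
    "DVHCurve", "DoseStats", "compute_dose", "compute_dvh",
    "dose_statistics", "compare_runs", "plot_dvh", "plot_history",
]


def compute_dose(A, x) -> np.ndarray:
    """Voxel doses ``d = A x`` (exact sparse product)."""
    A = A if isinstance(A, DoseInfluenceMatrix) else DoseInfluenceMatrix(A)
    return A.dose(x)


@dataclasses.dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram for one structure.

    ``volume_fraction[j]`` is the fraction of structure voxels receiving at
    least ``dose_gy[j]`` (the ">=" convention at bin edges), so the curve is
    non-increasing and equals 1 at dose 0 for nonnegative doses.
    """

    structure: str
    dose_gy: np.ndarray
    volume_fraction: np.ndarray


def _default_grid(d: np.ndarray, bins: int = 200) -> np.ndarray:
    top = 1.1 * float(d.max()) if d.size and d.max() > 0 else 1.0
    return np.linspace(0.0, top, bins)


def compute_dvh(d: np.ndarray, structure_indices, dose_grid=None,
                name: str = "") -> DVHCurve:
    """Cumulative DVH of ``d`` restricted to a structure's voxels."""
    idx = np.asarray(structure_indices, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("cannot compute a DVH for an empty structure")
    ds = np.sort(np.asarray(d, dtype=float)[idx])
    grid = _default_grid(ds) if dose_grid is None else np.asarray(dose_grid, float)
    vol = 1.0 - np.searchsorted(ds, grid, side="left") / ds.size
    return DVHCurve(name, grid, vol)


@dataclasses.dataclass(frozen=True)
class DoseStats:
    """Summary dose metrics for one structure.

    ``d_at[x]`` is the dose to the hottest x-fraction (nearest-rank
    quantile); ``v_at[t]`` the volume fraction receiving at least t Gy.
    """

    structure: str
    mean: float
    min: float
    max: float
    d_at: dict[float, float]
    v_at: dict[float, float]


def dose_statistics(d: np.ndarray, structure_indices,
                    d_fractions: Sequence[float] = (0.02, 0.5, 0.95, 0.98),
                    v_thresholds: Sequence[float] = (),
                    name: str = "") -> DoseStats:
    idx = np.asarray(structure_indices, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("cannot compute dose statistics for an empty structure")
    ds = np.asarray(d, dtype=float)[idx]
    return DoseStats(
        structure=name,
        mean=float(ds.mean()),
        min=float(ds.min()),
        max=float(ds.max()),
        d_at={float(v): inverse_dvh_quantile(ds, v) for v in d_fractions},
        v_at={float(t): float(np.mean(ds >= t)) for t in v_thresholds},
    )


def compare_runs(results: Mapping[str, PlanResult] | Sequence[PlanResult],
                 structures: StructureSet,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Side-by-side report of several runs on the same problem.

    Returns ``(table, trajectories)``: one table row per (run, structure)
    with dose statistics plus the run's final f/V/max-violation, and a
    long-format trajectory frame (run, iteration, f, V, max_violation,
    elapsed_s).  Raises if the runs do not share the problem dimensions.
    """
    if not isinstance(results, Mapping):
        results = {f"run{i}": r for i, r in enumerate(results)}
    if not results:
        raise ValueError("no runs to compare")
    dims = {(r.x.size, r.dose.size) for r in results.values()}
    if len(dims) > 1:
        raise ValueError(f"runs come from inconsistent problems: dims {sorted(dims)}")
    n = next(iter(results.values())).dose.size
    sets = structures.exclusive_partition(n)
    rows = []
    traj = []
    for label, res in results.items():
        h = res.history
        for sname, idx in sets.items():
            if idx.size == 0:
                continue
            st = dose_statistics(res.dose, idx, name=sname)
            rows.append({
                "run": label, "structure": sname,
                "mean_gy": st.mean, "min_gy": st.min, "max_gy": st.max,
                "d95_gy": st.d_at[0.95], "d02_gy": st.d_at[0.02],
                "final_f": h.f[-1], "final_V": h.V[-1],
                "final_max_violation_gy": h.max_violation[-1],
                "status": h.status, "iterations": h.iteration[-1],
            })
        traj.append(pd.DataFrame({
            "run": label, "iteration": h.iteration, "f": h.f, "V": h.V,
            "max_violation": h.max_violation, "elapsed_s": h.elapsed,
        }))
    return pd.DataFrame(rows), pd.concat(traj, ignore_index=True)


def _figure():
    # build figures without pyplot so headless use never needs a display
    from matplotlib.figure import Figure
    return Figure(figsize=(6.0, 4.0))


def plot_dvh(curves: Sequence[DVHCurve]):
    """DVH plot (volume fraction vs dose); returns a matplotlib Figure."""
    fig = _figure()
    ax = fig.add_subplot(111)
    for c in curves:
        ax.plot(c.dose_gy, 100.0 * c.volume_fraction, label=c.structure or None)
    ax.set_xlabel("dose [Gy]")
    ax.set_ylabel("volume [%]")
    ax.set_ylim(0, 105)
    ax.legend()
    return fig


def plot_history(histories: Mapping[str, "object"]):
    """Objective value and max violation per iteration; returns a Figure."""
    fig = _figure()
    ax1 = fig.add_subplot(211)
    ax2 = fig.add_subplot(212, sharex=ax1)
    for label, h in histories.items():
        ax1.plot(h.iteration, h.f, label=label)
        ax2.semilogy(h.iteration, np.maximum(h.max_violation, 1e-16), label=label)
    ax1.set_ylabel("objective f")
    ax2.set_ylabel("max violation [Gy]")
    ax2.set_xlabel("iteration")
    ax1.legend()
    return fig
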