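"""Per-iteration run records and the two-part relative-change stopping rule.

A :class:`RunHistory` stores one record per full iteration (for the
superiorized algorithm: perturbation phase + feasibility sweep; for bare
feasibility-seeking: one sweep).  The stopping rule terminates a run when both
the objective value ``f`` and the constraint proximity ``V`` have stagnated in
relative terms for a number of consecutive iterations.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["RunHistory", "stopping_met"]


@dataclasses.dataclass
class RunHistory:
    """Trajectory of a feasibility-seeking or superiorization run.

    Record 0 describes the starting point (iteration 0); each subsequent
    record is appended after a full iteration.  ``f`` is NaN for runs without
    an objective.  ``status`` is one of ``running``, ``stopped_criterion``,
    ``max_iterations``, ``max_time``.
    """

    iteration: list[int] = dataclasses.field(default_factory=list)
    f: list[float] = dataclasses.field(default_factory=list)
    V: list[float] = dataclasses.field(default_factory=list)
    max_violation: list[float] = dataclasses.field(default_factory=list)
    s: list[int] = dataclasses.field(default_factory=list)
    k: list[int] = dataclasses.field(default_factory=list)
    elapsed: list[float] = dataclasses.field(default_factory=list)
    status: str = "running"

    def append(self, iteration: int, f: float, V: float, max_violation: float,
               s: int, k: int, elapsed: float) -> None:
        if self.elapsed and elapsed < self.elapsed[-1]:
            elapsed = self.elapsed[-1]
        self.iteration.append(int(iteration))
        self.f.append(float(f))
        self.V.append(float(V))
        self.max_violation.append(float(max_violation))
        self.s.append(int(s))
        self.k.append(int(k))
        self.elapsed.append(float(elapsed))

    def __len__(self) -> int:
        return len(self.iteration)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sweep": self.iteration,
            "f": self.f,
            "V": self.V,
            "max_violation": self.max_violation,
            "s": self.s,
            "k": self.k,
            "elapsed_s": self.elapsed,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "RunHistory":
        df = pd.read_csv(path, float_precision="round_trip")
        h = cls()
        h.iteration = [int(v) for v in df["sweep"]]
        h.f = [float(v) for v in df["f"]]
        h.V = [float(v) for v in df["V"]]
        h.max_violation = [float(v) for v in df["max_violation"]]
        h.s = [int(v) for v in df["s"]] if "s" in df else [0] * len(df)
        h.k = [int(v) for v in df["k"]] if "k" in df else [0] * len(df)
        h.elapsed = [float(v) for v in df["elapsed_s"]]
        return h


def _rel_change_ok(curr: float, prev: float, tol: float) -> bool:
    """Relative-change test ``|x_{k+1} - x_k| / max(1, x_k) < tol``.

    A negative tolerance disables the test (always satisfied).  NaN values
    never satisfy a non-negative tolerance.
    """
    if tol < 0:
        return True
    if math.isnan(curr) or math.isnan(prev):
        return False
    return abs(curr - prev) / max(1.0, prev) < tol


def stopping_met(history, tol_f: float = 1e-4, tol_V: float = 1e-3,
                 consecutive: int = 3) -> bool:
    """Whether the two-part relative-stagnation stopping rule is satisfied.

    Both the relative change of the objective ``f`` and of the proximity
    ``V`` (each measured as ``|x_{k+1}-x_k| / max(1, x_k)``) must fall below
    their tolerances for ``consecutive`` successive iteration pairs.  Either
    part can be disabled by passing a negative tolerance.

    ``history`` may be a :class:`RunHistory` or any object with ``f`` and
    ``V`` sequences.  Returns False when fewer than ``consecutive + 1``
    records exist.
    """
    if tol_f < 0 and tol_V < 0:
        return False  # both parts disabled = early stopping turned off entirely
    f: Sequence[float] = np.asarray(history.f, dtype=float)
    V: Sequence[float] = np.asarray(history.V, dtype=float)
    n = len(f)
    if n < consecutive + 1:
        return False
    for j in range(n - consecutive, n):
        if not _rel_change_ok(f[j], f[j - 1], tol_f):
            return False
        if not _rel_change_ok(V[j], V[j - 1], tol_V):
            return False
    return True
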