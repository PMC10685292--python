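"""Superiorized version of the AMS feasibility-seeking algorithm.

Superiorization interlaces objective-reduction perturbations into a
perturbation-resilient feasibility-seeking iteration.  Each full iteration
consists of (i) a perturbation phase: up to ``N`` accepted steps of length
``beta = alpha**s`` along the negative normalized objective gradient, where
the exponent ``s`` only ever grows so the step sizes form a summable
geometric series; followed by (ii) one AMS sweep whose projection weights
decay as ``eta**k``.  The run stops when both the objective value and the
constraint proximity stagnate in relative terms for several consecutive
iterations, or on iteration/time limits.

The result is a feasible (or proximal, if the constraints are infeasible)
intensity vector with a reduced — not necessarily minimal — objective value.
"""

from __future__ import annotations

import dataclasses
import math
import time

import numpy as np

from .feasibility import (CONTROL_KINDS, ConstraintSystem, _as_influence,
                          _sequence_for, ams_sweep, max_violation,
                          proximity_V)
from .history import RunHistory, stopping_met
from .objectives import CompositeObjective

__all__ = [
    "SuperiorizationConfig", "PlanResult", "descent_direction",
    "perturbation_phase", "decay_weights", "stopping_met", "superiorize",
    "RunHistory",
]


@dataclasses.dataclass
class SuperiorizationConfig:
    """All tunables of the superiorized run.

    alpha: step-size kernel in (0, 1); beta = alpha**s.
    n_perturbations: accepted perturbation steps per iteration (N).
    lam: AMS relaxation parameter in (0, 2].
    eta: projection-weight decay kernel in (0, 1]; 1 keeps weights constant.
    warm_start_increment: added to s after the run's very first proposal.
    tol_f / tol_V: relative-stagnation tolerances (negative disables).
    consecutive: iterations the stagnation must persist.
    control: control-sequence kind; seed drives the random kind.
    """

    alpha: float = 0.99
    n_perturbations: int = 5
    lam: float = 1.0
    eta: float = 1.0
    warm_start_increment: int = 25
    max_iterations: int = 500
    max_time: float = 3000.0
    tol_f: float = 1e-4
    tol_V: float = 1e-3
    consecutive: int = 3
    control: str = "cyclic"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"kernel alpha must lie in (0, 1), got {self.alpha}")
        if self.n_perturbations < 0:
            raise ValueError("n_perturbations must be >= 0")
        if not (0.0 < self.lam <= 2.0):
            raise ValueError(f"relaxation lam must lie in (0, 2], got {self.lam}")
        if not (0.0 < self.eta <= 1.0):
            raise ValueError(f"weight-decay kernel eta must lie in (0, 1], got {self.eta}")
        if self.warm_start_increment < 1:
            raise ValueError("warm_start_increment must be >= 1")
        if self.max_iterations < 1 or self.max_time <= 0:
            raise ValueError("max_iterations and max_time must be positive")
        if self.consecutive < 1:
            raise ValueError("consecutive must be >= 1")
        if self.control not in CONTROL_KINDS:
            raise ValueError(f"unknown control sequence {self.control!r}")


@dataclasses.dataclass
class PlanResult:
    """Final intensities, their dose, the trajectory, and the config used."""

    x: np.ndarray
    dose: np.ndarray
    history: RunHistory
    config: SuperiorizationConfig


def descent_direction(g: np.ndarray) -> np.ndarray:
    """Unit vector along the negative gradient; zero vector at stationarity."""
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("gradient must be finite")
    nrm = float(np.linalg.norm(g))
    if nrm == 0.0:
        return np.zeros_like(g)
    return -g / nrm


def decay_weights(nu: np.ndarray, eta: float, k: int) -> np.ndarray:
    """Projection weights after k feasibility sweeps: ``eta**k * nu``."""
    if not (0.0 < eta <= 1.0):
        raise ValueError(f"eta must lie in (0, 1], got {eta}")
    if k < 0:
        raise ValueError("k must be >= 0")
    return (eta ** k) * np.asarray(nu, dtype=float)


def perturbation_phase(x: np.ndarray, objective: CompositeObjective,
                       alpha: float, s_in: int, N: int,
                       s_increment_first: int = 1,
                       max_proposals: int = 10_000,
                       ) -> tuple[np.ndarray, int, int, float]:
    """Run N objective-reduction perturbations from ``x``.

    Each perturbation records the phase-start value ``f_start = f(x)`` and
    proposes ``z = x + beta * v`` with ``beta = alpha**s`` and ``v`` the
    normalized negative gradient at ``x``; after every proposal ``s`` grows
    (by ``s_increment_first`` on the run's very first proposal, by 1
    afterwards), so the step sizes shrink geometrically until a proposal with
    ``f(z) <= f_start`` is accepted.  A zero gradient skips the perturbation.

    Returns ``(x', s_out, objective evaluation count, sum of proposed betas)``.
    ``s`` never decreases and every accepted point satisfies
    ``f(x') <= f_start`` exactly.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if s_in < 0:
        raise ValueError("s_in must be >= 0")
    x = np.array(x, dtype=float, copy=True)
    s = int(s_in)
    inc = int(s_increment_first)
    evals = 0
    beta_sum = 0.0
    for _ in range(N):
        f_start, g = objective.value_and_gradient(x)
        evals += 1
        v = descent_direction(g)
        if not v.any():
            continue
        for _ in range(max_proposals):
            beta = alpha ** s
            s += inc
            inc = 1
            beta_sum += beta
            z = x + beta * v
            fz = objective.value(z)
            evals += 1
            if fz <= f_start:
                x = z
                break
        else:  # pragma: no cover - geometric series underflow guard
            break
    return x, s, evals, beta_sum


def superiorize(x0, A, C: ConstraintSystem,
                objective: CompositeObjective | None,
                config: SuperiorizationConfig = SuperiorizationConfig(),
                ) -> PlanResult:
    """Run the superiorized AMS algorithm from ``x0`` (default: zeros).

    Iteration k = 0, 1, ...: perturbation phase (N accepted objective
    reductions), then one AMS sweep with weight scale ``eta**k``, then k is
    incremented.  One history record is appended per full iteration.  With
    ``N = 0``, a missing objective, or all-zero objective weights, the
    iterate sequence coincides bitwise with bare feasibility-seeking under
    the same control sequence.
    """
    A = _as_influence(A)
    if x0 is None:
        x = np.zeros(A.m)
    else:
        x = np.array(x0, dtype=float, copy=True)
    if x.shape != (A.m,):
        raise ValueError(f"x0 has shape {x.shape}, expected ({A.m},)")
    if np.any(x < 0):
        raise ValueError("x0 must be nonnegative")
    if C.lower.size != A.n:
        raise ValueError("constraint system size does not match the matrix")
    if objective is not None and objective.matrix.m != A.m:
        raise ValueError("objective is chained through a matrix of different width")

    cfg = config
    seq = _sequence_for(cfg.control, cfg.seed)
    perturb = objective is not None and cfg.n_perturbations > 0
    hist = RunHistory()
    t0 = time.perf_counter()

    def f_of(xv):
        return objective.value(xv) if objective is not None else math.nan

    hist.append(0, f_of(x), proximity_V(x, A, C), max_violation(x, A, C),
                0, 0, 0.0)
    hist.status = "max_iterations"
    s = 0
    k = 0
    first_proposal_pending = True
    beta_total = 0.0
    beta_bound = 1.0 / (1.0 - cfg.alpha)  # sum_{j >= s0=0} alpha**j
    for it in range(1, cfg.max_iterations + 1):
        if perturb:
            inc = cfg.warm_start_increment if first_proposal_pending else 1
            x, s_new, _, bsum = perturbation_phase(
                x, objective, cfg.alpha, s, cfg.n_perturbations,
                s_increment_first=inc)
            if s_new != s:
                first_proposal_pending = False
            s = s_new
            beta_total += bsum
            # step-size discipline: the beta series stays summable
            assert beta_total <= beta_bound * (1.0 + 1e-12)
        order = seq.draw(C)
        x = ams_sweep(x, A, C, cfg.lam, order, weight_scale=cfg.eta ** k)
        k += 1
        elapsed = time.perf_counter() - t0
        hist.append(it, f_of(x), proximity_V(x, A, C),
                    max_violation(x, A, C), s, k, elapsed)
        if stopping_met(hist, cfg.tol_f, cfg.tol_V, cfg.consecutive):
            hist.status = "stopped_criterion"
            break
        if elapsed > cfg.max_time:
            hist.status = "max_time"
            break
    return PlanResult(x=x, dose=A.dose(x), history=hist, config=cfg)
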