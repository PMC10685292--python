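"""End-to-end runners behind the CLI: build problem, solve, evaluate, compare.

Everything here is a plain function so scripted use (examples, acceptance
script, tests) and the CLI share one code path.  Runs are deterministic given
(config, seed); every artifact directory receives the resolved config for
provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PlanSpecConfig
from .evaluation import compare_runs, compute_dvh, dose_statistics
from .feasibility import (VOIPrescription, feasibility_solve,
                          prescription_to_constraints)
from .io import read_problem, write_problem
from .objectives import CompositeObjective, ObjectiveSpec
from .phantom import BeamConfig, VoxelGrid, make_toy_problem
from .problems import PlanningProblem, make_phantom_problem
from .superiorize import PlanResult, SuperiorizationConfig, superiorize

log = logging.getLogger(__name__)

__all__ = ["build_problem", "run_plan", "evaluate_result", "compare_results",
           "load_result"]


def build_problem(cfg: PlanSpecConfig) -> PlanningProblem:
    src = cfg.problem
    if src.type == "phantom":
        grid = VoxelGrid(shape=(src.nx, src.ny, src.nz),
                         spacing=(src.spacing_mm,) * 3)
        pres = [VOIPrescription(p.voi, p.lower, p.upper, p.weight)
                for p in cfg.prescription] or None
        if src.witness_bounds:
            return make_phantom_problem(grid, prescription=pres)
        from .phantom import build_phantom, generate_dose_influence
        structures = build_phantom(grid)
        A = generate_dose_influence(grid, structures, BeamConfig())
        C = prescription_to_constraints(structures, pres or [], A)
        return PlanningProblem(matrix=A, lower=C.lower, upper=C.upper,
                               weights=C.weights, structures=structures)
    if src.type == "toy":
        toy = make_toy_problem(src.n, src.m, src.density, src.feasible,
                               src.slack, cfg.seed)
        return PlanningProblem.from_toy(toy)
    return read_problem(src.path)


def _composite(cfg: PlanSpecConfig, problem: PlanningProblem):
    if not cfg.objectives:
        return None
    if problem.structures is None:
        raise ValueError("objectives need structures, but the problem has none")
    specs = [ObjectiveSpec(o.kind, o.voi, o.weight, o.d_ref, o.volume)
             for o in cfg.objectives]
    return CompositeObjective(specs, problem.structures, problem.matrix)


def run_plan(cfg: PlanSpecConfig, out_dir=None) -> tuple[PlanResult, Path]:
    """Build the problem, solve per the solver block, write all artifacts."""
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    problem = build_problem(cfg)
    # re-derive constraints from the prescription when one is supplied for a
    # loaded/phantom problem with structures; otherwise use the stored bounds
    if cfg.prescription and problem.structures is not None \
            and cfg.problem.type == "load":
        pres = [VOIPrescription(p.voi, p.lower, p.upper, p.weight)
                for p in cfg.prescription]
        C = prescription_to_constraints(problem.structures, pres, problem.matrix)
    else:
        C = problem.constraints()
    objective = _composite(cfg, problem)

    s = cfg.solver
    if s.mode == "feasibility":
        x, hist = feasibility_solve(
            np.zeros(problem.matrix.m), problem.matrix, C, lam=s.lam,
            sequence=s.control, max_sweeps=s.max_iterations,
            max_time=s.max_time, tol_V=s.tol_V, consecutive=s.consecutive,
            seed=cfg.seed)
        result = PlanResult(x=x, dose=problem.matrix.dose(x), history=hist,
                            config=SuperiorizationConfig(
                                lam=s.lam, n_perturbations=0,
                                max_iterations=s.max_iterations,
                                max_time=s.max_time, tol_V=s.tol_V,
                                consecutive=s.consecutive, control=s.control,
                                seed=cfg.seed))
    else:
        sup_cfg = SuperiorizationConfig(
            alpha=s.alpha, n_perturbations=s.n_perturbations, lam=s.lam,
            eta=s.eta, warm_start_increment=s.warm_start_increment,
            max_iterations=s.max_iterations, max_time=s.max_time,
            tol_f=s.tol_f, tol_V=s.tol_V, consecutive=s.consecutive,
            control=s.control, seed=cfg.seed)
        result = superiorize(None, problem.matrix, C, objective, sup_cfg)

    for it, f, V, mv in zip(result.history.iteration, result.history.f,
                            result.history.V, result.history.max_violation):
        log.info("iteration %4d  f=%-12.6g V=%-12.6g max_violation=%.6g",
                 it, f, V, mv)

    write_problem(out / "problem", problem)
    pd.DataFrame({"beamlet": np.arange(result.x.size), "intensity": result.x}
                 ).to_csv(out / "x.csv", index=False, float_format="%.17g")
    pd.DataFrame({"voxel_index": np.arange(result.dose.size),
                  "dose_gy": result.dose}
                 ).to_csv(out / "dose.csv", index=False, float_format="%.17g")
    result.history.to_csv(out / "history.csv")
    summary = {
        "mode": s.mode,
        "status": result.history.status,
        "iterations": result.history.iteration[-1],
        "final_f": result.history.f[-1],
        "final_V": result.history.V[-1],
        "final_max_violation_gy": result.history.max_violation[-1],
        "elapsed_s": result.history.elapsed[-1],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    cfg.echo(out / "resolved_config.yaml")
    return result, out


def load_result(result_dir) -> tuple[PlanningProblem, PlanResult]:
    """Reload a run directory written by :func:`run_plan`."""
    from .history import RunHistory
    out = Path(result_dir)
    problem = read_problem(out / "problem")
    x = pd.read_csv(out / "x.csv")["intensity"].to_numpy()
    hist = RunHistory.from_csv(out / "history.csv")
    summary = json.loads((out / "summary.json").read_text())
    hist.status = summary.get("status", hist.status)
    dose = problem.matrix.dose(x)
    return problem, PlanResult(x=x, dose=dose, history=hist,
                               config=SuperiorizationConfig())


def evaluate_result(result_dir, out_dir=None) -> Path:
    """Write DVH and dose-statistics CSVs for a finished run."""
    out = Path(out_dir if out_dir is not None else result_dir)
    problem, result = load_result(result_dir)
    if problem.structures is None:
        raise ValueError("cannot evaluate: problem has no structures")
    sets = problem.structures.exclusive_partition(problem.matrix.n)
    dvh_rows, stat_rows = [], []
    for name, idx in sets.items():
        if idx.size == 0:
            continue
        curve = compute_dvh(result.dose, idx, name=name)
        dvh_rows.append(pd.DataFrame({
            "structure": name, "dose_gy": curve.dose_gy,
            "volume_fraction": curve.volume_fraction}))
        st = dose_statistics(result.dose, idx, name=name)
        stat_rows.append({"structure": name, "mean_gy": st.mean,
                          "min_gy": st.min, "max_gy": st.max,
                          "d95_gy": st.d_at[0.95], "d02_gy": st.d_at[0.02]})
    out.mkdir(parents=True, exist_ok=True)
    pd.concat(dvh_rows, ignore_index=True).to_csv(out / "dvh.csv", index=False)
    pd.DataFrame(stat_rows).to_csv(out / "stats.csv", index=False)
    return out


def compare_results(result_dirs, out_path) -> pd.DataFrame:
    """Aggregate several run directories into one comparison report CSV."""
    problems, results = {}, {}
    for d in result_dirs:
        label = Path(d).name
        problems[label], results[label] = load_result(d)
    first = next(iter(problems.values()))
    if first.structures is None:
        raise ValueError("cannot compare: problems have no structures")
    table, traj = compare_runs(results, first.structures)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, index=False)
    traj.to_csv(out_path.with_name(out_path.stem + "_trajectories.csv"),
                index=False)
    return table
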