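"""On-disk problem format: MatrixMarket matrix, CSV masks/bounds, JSON metadata.

A problem directory contains::

    matrix.mtx     MatrixMarket coordinate format (1-based indices on disk)
    bounds.csv     voxel_index,lower,upper,weight   (0-based voxel indices)
    masks.csv      voxel_index,structure            (optional)
    structures.json  name -> priority               (optional)
    metadata.json  grid shape/spacing, seed, beam config, witness, ...

Values are serialized with 17 significant digits so float64 entries
round-trip exactly.  Voxel indices are 0-based x-fastest everywhere except
inside the MatrixMarket file, whose format mandates 1-based indices.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .phantom import DoseInfluenceMatrix, Structure, StructureSet
from .problems import PlanningProblem

__all__ = ["write_problem", "read_problem", "ProblemFormatError"]


class ProblemFormatError(ValueError):
    """A problem directory or one of its files is malformed."""


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_problem(path, problem: PlanningProblem) -> Path:
    """Serialize a planning problem into a directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", problem.matrix.csr.tocoo(),
                     precision=17)
    n = problem.matrix.n
    weights = problem.weights if problem.weights is not None else np.ones(n)
    pd.DataFrame({
        "voxel_index": np.arange(n),
        "lower": problem.lower,
        "upper": problem.upper,
        "weight": weights,
    }).to_csv(path / "bounds.csv", index=False, float_format="%.17g")
    if problem.structures is not None:
        rows = [pd.DataFrame({"voxel_index": s.indices, "structure": s.name})
                for s in problem.structures]
        masks = (pd.concat(rows, ignore_index=True) if rows else
                 pd.DataFrame(columns=["voxel_index", "structure"]))
        masks.to_csv(path / "masks.csv", index=False)
        with open(path / "structures.json", "w") as fh:
            json.dump({s.name: s.priority for s in problem.structures}, fh,
                      indent=1)
    meta = dict(problem.metadata)
    if problem.witness is not None:
        meta["witness"] = problem.witness
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, default=_jsonify, indent=1)
    return path


def read_problem(path) -> PlanningProblem:
    """Load a problem directory written by :func:`write_problem`."""
    path = Path(path)
    mtx_path = path / "matrix.mtx"
    if not mtx_path.exists():
        raise ProblemFormatError(f"missing {mtx_path}")
    try:
        A = sp.csr_matrix(scipy.io.mmread(mtx_path))
    except ValueError as exc:
        raise ProblemFormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    matrix = DoseInfluenceMatrix(A)

    bounds = pd.read_csv(path / "bounds.csv", float_precision="round_trip")
    expected = {"voxel_index", "lower", "upper", "weight"}
    if not expected.issubset(bounds.columns):
        raise ProblemFormatError(
            f"bounds.csv needs columns {sorted(expected)}, got {list(bounds.columns)}")
    idx = bounds["voxel_index"].to_numpy()
    if idx.min(initial=0) < 0 or idx.max(initial=-1) >= matrix.n:
        raise ProblemFormatError("bounds.csv voxel index out of range")
    n = matrix.n
    lower = np.zeros(n)
    upper = np.full(n, math.inf)
    weights = np.ones(n)
    lower[idx] = bounds["lower"].to_numpy()
    upper[idx] = bounds["upper"].to_numpy()
    weights[idx] = bounds["weight"].to_numpy()

    structures = None
    masks_path = path / "masks.csv"
    if masks_path.exists():
        masks = pd.read_csv(masks_path)
        if not {"voxel_index", "structure"}.issubset(masks.columns):
            raise ProblemFormatError("masks.csv needs columns voxel_index,structure")
        if len(masks) and (masks["voxel_index"].min() < 0
                           or masks["voxel_index"].max() >= n):
            raise ProblemFormatError("masks.csv voxel index out of range")
        prios_path = path / "structures.json"
        prios = json.loads(prios_path.read_text()) if prios_path.exists() else {}
        structs = []
        for rank, (name, grp) in enumerate(masks.groupby("structure", sort=False)):
            structs.append(Structure(str(name), grp["voxel_index"].to_numpy(),
                                     priority=int(prios.get(str(name), rank))))
        for name, prio in prios.items():  # structures that happen to be empty
            if not any(s.name == name for s in structs):
                structs.append(Structure(name, np.array([], dtype=np.intp),
                                         priority=int(prio)))
        structures = StructureSet(structs)

    meta_path = path / "metadata.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    witness = metadata.pop("witness", None)
    if witness is not None:
        witness = np.asarray(witness, dtype=float)
    return PlanningProblem(matrix=matrix, lower=lower, upper=upper,
                           weights=weights, structures=structures,
                           witness=witness, metadata=metadata)
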