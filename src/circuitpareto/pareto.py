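"""Pareto-front extraction over clouds of |sensitivity| pairs.

Each parameter point on a grid (and each stable branch at that point)
contributes one point to a two-dimensional objective cloud of absolute
sensitivities.  The Pareto front is the minimization-sense non-dominated
subset; a circuit exhibits a trade-off for an objective pair when that
front is a genuine curve rather than a single collapsed point.
"""
from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .circuits import CircuitModel, ParameterGrid
from .sensitivity import (SensitivityError, grid_sensitivities,
                          sensitivity_analytic, sensitivity_column,
                          sensitivity_fd)
from .steady_state import SolverPolicy, exclude_zero_states, find_steady_states

__all__ = [
    "ObjectivePair",
    "ParetoResult",
    "pareto_front",
    "moo_pair",
    "classify_tradeoff",
    "tradeoff_census",
    "objective_universe",
]

log = logging.getLogger(__name__)

# Trade-off classification: the front must be spread, in every objective,
# by more than REL_TOL of the cloud's extent (plus a small absolute floor)
# to count as a genuine trade-off curve.
REL_TOL = 1e-3
ABS_FLOOR = 1e-6


@dataclass(frozen=True)
class ObjectivePair:
    """Two distinct |sensitivity| objectives, each (species, parameter)."""

    first: tuple[str, str]
    second: tuple[str, str]

    def __post_init__(self):
        if self.first == self.second:
            raise ValueError("objective pair must use two distinct "
                             "sensitivities")

    def validate(self, model: CircuitModel,
                 params: tuple[str, ...] | None = None) -> None:
        params = tuple(params or model.swept)
        for sp, p in (self.first, self.second):
            if sp not in model.species:
                raise ValueError(f"species {sp!r} not in {model.species}")
            if p not in params:
                raise ValueError(f"parameter {p!r} not among swept {params}")

    @property
    def labels(self) -> tuple[str, str]:
        return (sensitivity_column(*self.first),
                sensitivity_column(*self.second))

    def __str__(self) -> str:
        return f"|{self.labels[0]}| vs |{self.labels[1]}|"


SNAP_DIGITS = 12


def _snap(values: np.ndarray, digits: int = SNAP_DIGITS) -> np.ndarray:
    """Round to ``digits`` significant digits.

    Dominance comparisons are made on snapped values so that ties are
    resolved by the quantity itself rather than by the ~1e-15 relative
    rounding noise of the Jacobian solve; two objectives closer than the
    snap resolution are treated as equal.
    """
    arr = np.asarray(values, dtype=float)
    fmt = f"%.{digits - 1}e"
    out = np.fromiter((float(fmt % v) for v in arr.ravel()),
                      dtype=float, count=arr.size)
    return out.reshape(arr.shape)


def pareto_front(cloud) -> np.ndarray:
    """Indices of the non-dominated points of a 2-d objective cloud.

    Minimization sense.  Coordinates are compared at SNAP_DIGITS
    significant digits; duplicated coordinates are collapsed to the first
    occurrence, so an exactly repeated front point is retained once.  The
    result is ordered by the first objective ascending.
    """
    pts = np.asarray(cloud, dtype=float)
    if pts.size == 0:
        return np.array([], dtype=int)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("cloud must have shape (n, 2)")
    if not np.all(np.isfinite(pts)) or np.any(pts < 0):
        raise ValueError("objectives must be finite and nonnegative")
    snapped = _snap(pts)
    _, first_idx = np.unique(snapped, axis=0, return_index=True)
    keep: list[int] = []
    best_f2 = np.inf
    order = first_idx[np.lexsort((snapped[first_idx, 1],
                                  snapped[first_idx, 0]))]
    for idx in order:
        if snapped[idx, 1] < best_f2:
            keep.append(int(idx))
            best_f2 = snapped[idx, 1]
    return np.asarray(keep, dtype=int)


@dataclass
class ParetoResult:
    """Objective cloud, non-dominated subset and trade-off label for one
    objective pair."""

    pair: ObjectivePair
    objectives: np.ndarray          # (n, 2) absolute sensitivities
    table: pd.DataFrame             # provenance: parameters, branch, signed S
    front_indices: np.ndarray
    tradeoff: str = "none"          # "none" | "tradeoff"

    @property
    def front_points(self) -> np.ndarray:
        return self.objectives[self.front_indices]

    @property
    def front_parameters(self) -> pd.DataFrame:
        return self.table.iloc[self.front_indices]

    def to_dict(self) -> dict:
        keep = [c for c in self.table.columns if not c.startswith("S_")]
        return {
            "pair": [list(self.pair.first), list(self.pair.second)],
            "objective_labels": list(self.pair.labels),
            "classification": self.tradeoff,
            "n_cloud": int(len(self.objectives)),
            "front": [
                {
                    "objectives": [float(a) for a in self.objectives[i]],
                    "parameters": {c: float(self.table.iloc[i][c])
                                   for c in keep},
                    "branch_id": int(self.table.iloc[i].get("branch_id", 0)),
                }
                for i in self.front_indices
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def classify_tradeoff(result: ParetoResult, rel_tol: float = REL_TOL,
                      abs_floor: float = ABS_FLOOR) -> str:
    """Label a Pareto result "none" or "tradeoff".

    A pair of objectives is free of trade-offs when its utopia point --
    the per-objective minima over the whole cloud -- is (approximately)
    attained by a single sampled point: both objectives can then be
    minimized simultaneously and the front collapses to that point at the
    scale of the cloud.  Conversely, when every point that approaches one
    objective's minimum stays bounded away from the other's, improving
    one sensitivity necessarily sacrifices the other: a trade-off.

    "Approximately" means within rel_tol of the cloud's extent per
    objective, plus a small absolute floor.  A single-point front is
    always "none".
    """
    if len(result.front_indices) <= 1:
        return "none"
    pts = result.objectives
    utopia = pts.min(axis=0)
    extent = pts.max(axis=0) - utopia
    tol = rel_tol * extent + abs_floor
    attained = np.any(np.all(pts <= utopia + tol, axis=1))
    return "none" if attained else "tradeoff"


def _filter_artifacts(model: CircuitModel, result: ParetoResult,
                      policy: SolverPolicy, fd_tol: float = 1e-4,
                      max_rounds: int = 5) -> ParetoResult:
    """Re-verify front members; drop numerical artifacts and re-form the
    front.

    Each front member is re-solved at a tighter tolerance and its analytic
    sensitivities are cross-checked against the finite-difference oracle.
    Sampling artifacts (spurious front points from an unconverged root)
    fail one of the checks and are removed from the cloud.
    """
    tight = policy.tighter()
    mask = np.ones(len(result.objectives), dtype=bool)
    front = result.front_indices
    for _ in range(max_rounds):
        bad: list[int] = []
        for i in front:
            row = result.table.iloc[i]
            theta = {p: float(row[p]) for p in model.params if p in row}
            ref = np.array([float(row[s]) for s in model.species])
            try:
                states = exclude_zero_states(
                    find_steady_states(model, theta, tight),
                    tight.zero_threshold)
                cand = [s for s in states if s.stable and not s.marginal]
                if not cand:
                    raise SensitivityError("no stable root on re-solve")
                dists = [np.linalg.norm(s.state - ref) for s in cand]
                ss = cand[int(np.argmin(dists))]
                if min(dists) / (1 + np.linalg.norm(ref)) > 1e-6:
                    raise SensitivityError("root moved on tighter re-solve")
                ana = sensitivity_analytic(model, theta, ss)
                fd = sensitivity_fd(model, theta, ss, policy=policy)
                scale = np.maximum(np.abs(ana.S), 1.0)
                if np.max(np.abs(ana.S - fd.S) / scale) > fd_tol:
                    raise SensitivityError("analytic/FD mismatch")
            except SensitivityError as err:
                log.warning("%s: dropping front member %d as numerical "
                            "artifact (%s)", model.name, i, err)
                bad.append(i)
        if not bad:
            break
        mask[bad] = False
        sub = np.flatnonzero(mask)
        front = sub[pareto_front(result.objectives[sub])]
    result.front_indices = np.asarray(front, dtype=int)
    return result


def moo_pair(model: CircuitModel, grid: ParameterGrid, pair: ObjectivePair,
             policy: SolverPolicy | None = None,
             table: pd.DataFrame | None = None,
             filter_artifacts: bool = True,
             rel_tol: float = REL_TOL,
             abs_floor: float = ABS_FLOOR) -> ParetoResult:
    """Solve one MOO problem: minimize a pair of |sensitivities| over a grid.

    Pipeline: sample the grid, find stable nonzero steady states, evaluate
    analytic sensitivities per branch, take absolute values, extract the
    non-dominated subset, verify front members, classify the trade-off.
    A precomputed sensitivity ``table`` may be passed to share the solve
    across several objective pairs.
    """
    policy = policy or SolverPolicy()
    pair.validate(model)
    if table is None:
        table = grid_sensitivities(model, grid, policy)
    if table.empty:
        raise SteadyStateSolveError(model, grid)
    c1, c2 = pair.labels
    objectives = np.abs(table[[c1, c2]].to_numpy(dtype=float))
    result = ParetoResult(pair=pair, objectives=objectives, table=table,
                          front_indices=pareto_front(objectives))
    if filter_artifacts:
        result = _filter_artifacts(model, result, policy)
    result.tradeoff = classify_tradeoff(result, rel_tol, abs_floor)
    return result


class SteadyStateSolveError(RuntimeError):
    def __init__(self, model: CircuitModel, grid: ParameterGrid):
        super().__init__(
            f"{model.name}: no parameter point on the grid "
            f"{dict(grid.axes)} produced a stable nonzero steady state")


def objective_universe(model: CircuitModel,
                       params: tuple[str, ...] | None = None,
                       ) -> list[tuple[str, str]]:
    """All (species, parameter) sensitivity objectives for a circuit."""
    params = tuple(params or model.swept)
    return [(sp, p) for sp in model.species for p in params]


def _objective_classes(table: pd.DataFrame,
                       objectives: list[tuple[str, str]],
                       rel_tol: float = 1e-9) -> dict[tuple[str, str],
                                                      tuple[str, str]]:
    """Map each objective to the representative of its equivalence class.

    Some motifs make two sensitivity functions identical everywhere (in
    the positive-negative loop and the toggle, a species' sensitivity to
    its own production rate equals the partner's to the partner's rate).
    Pairs built from duplicated objectives restate the same trade-off, so
    the census counts distinct trade-offs at the class level.
    """
    reps: dict[tuple[str, str], tuple[str, str]] = {}
    cols = {o: np.abs(table[sensitivity_column(*o)].to_numpy(dtype=float))
            for o in objectives}
    for o in objectives:
        for r in reps.values():
            if r == o:
                continue
            denom = np.maximum(np.maximum(cols[o], np.abs(cols[r])), 1e-30)
            if np.max(np.abs(cols[o] - cols[r]) / denom) < rel_tol:
                reps[o] = reps[r]
                break
        else:
            reps[o] = o
    return reps


def tradeoff_census(model: CircuitModel, grid: ParameterGrid,
                    policy: SolverPolicy | None = None,
                    params: tuple[str, ...] | None = None,
                    table: pd.DataFrame | None = None,
                    filter_artifacts: bool = True,
                    rel_tol: float = REL_TOL,
                    abs_floor: float = ABS_FLOOR) -> pd.DataFrame:
    """Classify every unordered pair of sensitivity objectives.

    Returns one row per pair with the classification, front size, and
    the equivalence-class representatives of both objectives;
    ``distinct`` marks the first occurrence of each class-level pair.
    ``df.attrs["n_tradeoffs"]`` counts distinct trade-offs and
    ``df.attrs["n_tradeoff_rows"]`` the raw row count.  The steady states
    and sensitivities are computed once and shared by all pairs.
    """
    policy = policy or SolverPolicy()
    params = tuple(params or model.swept)
    if table is None:
        table = grid_sensitivities(model, grid, policy, params=params)
    objectives = objective_universe(model, params)
    reps = _objective_classes(table, objectives)
    rows = []
    seen_class_pairs: set[frozenset] = set()
    for a, b in itertools.combinations(objectives, 2):
        pair = ObjectivePair(a, b)
        res = moo_pair(model, grid, pair, policy=policy, table=table,
                       filter_artifacts=filter_artifacts,
                       rel_tol=rel_tol, abs_floor=abs_floor)
        class_pair = frozenset((reps[a], reps[b]))
        distinct = len(class_pair) == 2 and class_pair not in seen_class_pairs
        seen_class_pairs.add(class_pair)
        rows.append({
            "species_1": a[0], "param_1": a[1],
            "species_2": b[0], "param_2": b[1],
            "class_1": sensitivity_column(*reps[a]),
            "class_2": sensitivity_column(*reps[b]),
            "distinct": distinct,
            "classification": res.tradeoff,
            "front_size": int(len(res.front_indices)),
            "n_cloud": int(len(res.objectives)),
        })
    df = pd.DataFrame(rows)
    tradeoff = df["classification"] == "tradeoff"
    df.attrs["circuit"] = model.name
    df.attrs["n_tradeoffs"] = int((tradeoff & df["distinct"]).sum())
    df.attrs["n_tradeoff_rows"] = int(tradeoff.sum())
    return df
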