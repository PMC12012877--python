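"""Named study pipelines: promoter-leakiness sweeps and the
upstream/downstream circuit comparison.

A promoter-leakiness sweep repeats one MOO problem on leaky variants of a
circuit at increasing basal production L; increasing leakiness raises the
steady-state level while leaving the absolute derivatives to the swept
parameters essentially unchanged, so the relative sensitivities shrink and
any trade-off collapses toward the origin.

The downstream comparison contrasts a constitutively expressed upstream
gene against a positively autoregulated one, both driving the same
downstream gene, over the same grid and objective pair.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circuits import (CircuitModel, ParameterGrid, default_grid,
                       leaky_variant, make_circuit)
from .pareto import (ObjectivePair, ParetoResult, moo_pair,
                     tradeoff_census)
from .sensitivity import grid_sensitivities, sensitivity_column
from .steady_state import (SolverPolicy, Trajectory, find_steady_states,
                           simulate)

__all__ = [
    "StudyConfig",
    "LeakinessSweep",
    "DownstreamComparison",
    "default_pair",
    "leakiness_sweep",
    "leakiness_census",
    "downstream_comparison",
    "write_steady_state_csv",
    "write_sensitivity_csv",
    "write_census_csv",
]

log = logging.getLogger(__name__)

LEAK_LEVELS = (0.0, 0.1, 1.0, 10.0)
MAX_LEAK = 200.0


@dataclass
class StudyConfig:
    """Configuration for one named study."""

    circuit: str
    grid: ParameterGrid | None = None
    resolution: int | None = None
    pair: ObjectivePair | None = None
    leak_levels: Sequence[float] = LEAK_LEVELS
    policy: SolverPolicy = field(default_factory=SolverPolicy)
    outdir: Path | None = None
    seed: int = 0  # reserved for randomized start strategies

    def __post_init__(self):
        make_circuit(self.circuit.removesuffix("_leaky")
                     if self.circuit.endswith("_leaky") else self.circuit)
        for lvl in self.leak_levels:
            if not 0.0 <= lvl <= MAX_LEAK:
                raise ValueError(
                    f"leakiness level {lvl} outside [0, {MAX_LEAK}]")


def default_pair(model: CircuitModel) -> ObjectivePair:
    """The representative objective pair for a circuit: the first species'
    sensitivities to its own feedback strength and to the cooperativity."""
    strength = model.swept[0]
    return ObjectivePair((model.species[0], strength),
                         (model.species[0], "n"))


@dataclass
class LeakinessSweep:
    circuit: str
    pair: ObjectivePair
    levels: tuple[float, ...]
    results: dict[float, ParetoResult]

    def front_max(self, level: float) -> float:
        """Largest objective coordinate on the front at one leak level."""
        return float(self.results[level].front_points.max())

    def cloud_extent(self, level: float) -> np.ndarray:
        obj = self.results[level].objectives
        return obj.max(axis=0) - obj.min(axis=0)


def leakiness_sweep(config: StudyConfig) -> LeakinessSweep:
    """Run one MOO problem at each promoter-leakiness level.

    The same parameter grid is reused with L held fixed per level; the
    L = 0 run reproduces the base circuit exactly.
    """
    base = config.circuit.removesuffix("_leaky")
    model = leaky_variant(base)
    pair = config.pair or default_pair(model)
    results: dict[float, ParetoResult] = {}
    for lvl in config.leak_levels:
        grid = config.grid or default_grid(model, config.resolution)
        fixed = dict(grid.fixed)
        fixed["L"] = float(lvl)
        grid = ParameterGrid(axes=grid.axes, fixed=fixed,
                             spacing=grid.spacing, extra=grid.extra)
        results[float(lvl)] = moo_pair(model, grid, pair,
                                       policy=config.policy)
    return LeakinessSweep(circuit=model.name, pair=pair,
                          levels=tuple(float(l) for l in config.leak_levels),
                          results=results)


def leakiness_census(circuit: str, level: float,
                     resolution: int | None = None,
                     grid: ParameterGrid | None = None,
                     policy: SolverPolicy | None = None) -> pd.DataFrame:
    """Trade-off census of a circuit's leaky variant at a fixed leak L."""
    model = leaky_variant(circuit.removesuffix("_leaky"))
    grid = grid or default_grid(model, resolution, fixed={"L": float(level)})
    if "L" not in grid.fixed:
        fixed = dict(grid.fixed)
        fixed["L"] = float(level)
        grid = ParameterGrid(axes=grid.axes, fixed=fixed,
                             spacing=grid.spacing, extra=grid.extra)
    return tradeoff_census(model, grid, policy=policy)


@dataclass
class DownstreamComparison:
    pair: ObjectivePair
    constitutive: ParetoResult
    autoregulated: ParetoResult
    trajectories: dict[str, Trajectory] | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, res in (("constitutive_plus_downstream", self.constitutive),
                          ("autoreg_plus_downstream", self.autoregulated)):
            rows.append({
                "circuit": name,
                "classification": res.tradeoff,
                "front_size": len(res.front_indices),
                "n_cloud": len(res.objectives),
            })
        return pd.DataFrame(rows)


def downstream_comparison(config: StudyConfig,
                          simulate_timecourses: bool = False,
                          x0: Sequence[float] = (10.0, 10.0),
                          timecourse_theta: Mapping[str, float] | None = None,
                          horizon: float = 10.0) -> DownstreamComparison:
    """Same grid, same objective pair, constitutive vs autoregulated
    upstream gene.

    The default objective pair tracks the downstream species' sensitivity
    to the upstream feedback strength and to the cooperativity.
    """
    con = make_circuit("constitutive_plus_downstream")
    aut = make_circuit("autoreg_plus_downstream")
    pair = config.pair or ObjectivePair(("y", "beta_x"), ("y", "n"))
    grid = config.grid or default_grid(con, config.resolution)
    res_con = moo_pair(con, grid, pair, policy=config.policy)
    res_aut = moo_pair(aut, grid, pair, policy=config.policy)
    trajectories = None
    if simulate_timecourses:
        theta = dict(timecourse_theta
                     or {"beta_x": 30.0, "beta_y": 20.0, "n": 10.0})
        trajectories = {
            m.name: simulate(m, theta, x0, horizon) for m in (con, aut)
        }
    return DownstreamComparison(pair=pair, constitutive=res_con,
                                autoregulated=res_aut,
                                trajectories=trajectories)


# ---------------------------------------------------------------------------
# tabular writers
# ---------------------------------------------------------------------------

def steady_state_table(model: CircuitModel, grid: ParameterGrid,
                       policy: SolverPolicy | None = None) -> pd.DataFrame:
    """One row per (parameter point, branch): parameters, species values,
    eigenvalue real parts, stability flag."""
    from .circuits import sample_grid
    policy = policy or SolverPolicy()
    rows = []
    for vec in sample_grid(grid):
        theta = dict(zip(grid.labels, vec))
        theta.update(grid.fixed)
        states = find_steady_states(model, theta, policy)
        for b_id, ss in enumerate(states):
            row = {k: float(v) for k, v in theta.items()}
            row["branch_id"] = b_id
            for i, sp_name in enumerate(model.species):
                row[sp_name] = float(ss.state[i])
            for i in range(len(model.species)):
                row[f"eig_re_{i}"] = float(ss.eigenvalues[i].real)
            row["stable"] = bool(ss.stable)
            row["marginal"] = bool(ss.marginal)
            row["residual"] = float(ss.residual)
            rows.append(row)
    return pd.DataFrame(rows)


def write_steady_state_csv(model, grid, path, policy=None) -> pd.DataFrame:
    df = steady_state_table(model, grid, policy)
    df.to_csv(path, index=False)
    return df


def write_sensitivity_csv(model, grid, path, policy=None,
                          params=None) -> pd.DataFrame:
    df = grid_sensitivities(model, grid, policy, params=params)
    out = df.copy()
    for sp_name in model.species:
        for p in (params or model.swept):
            col = sensitivity_column(sp_name, p)
            if col in out.columns:
                out[f"abs_{col}"] = out[col].abs()
    out.to_csv(path, index=False)
    return out


def write_census_csv(model, grid, path, policy=None, **kw) -> pd.DataFrame:
    df = tradeoff_census(model, grid, policy=policy, **kw)
    df.to_csv(path, index=False)
    return df
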