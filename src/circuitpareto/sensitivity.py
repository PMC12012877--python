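"""Relative steady-state sensitivities of circuit species to parameters.

The relative (logarithmic) sensitivity S^{x_i}_{theta_j} =
(theta_j / x_i) * dx_i/dtheta_j measures the percent change of a
steady-state species per percent change of a parameter.  The derivative
of the implicitly defined root is obtained from the implicit function
theorem, dx/dtheta = -(df/dx)^{-1} (df/dtheta), using the exact symbolic
Jacobians compiled with each circuit -- this is the closed form the
per-circuit expressions reduce to.  A central finite-difference route,
which re-solves the steady state at perturbed parameters with branch
tracking, serves as an independent verification oracle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuits import CircuitModel, ParameterGrid, sample_grid
from .steady_state import (SolverPolicy, SteadyState, exclude_zero_states,
                           find_steady_states)

__all__ = [
    "SensitivityRecord",
    "SensitivityError",
    "BranchJumpError",
    "sensitivity_analytic",
    "sensitivity_fd",
    "grid_sensitivities",
    "sensitivity_column",
]

log = logging.getLogger(__name__)


class SensitivityError(RuntimeError):
    """Sensitivity evaluation failed (singular Jacobian or zero species)."""


class BranchJumpError(SensitivityError):
    """A finite-difference re-solve left the steady-state branch."""


@dataclass(frozen=True)
class SensitivityRecord:
    """Matrix of relative sensitivities at one stable steady state.

    ``S[i, j]`` is the sensitivity of species ``species[i]`` to parameter
    ``params[j]``; all entries are unitless and signed.
    """

    theta: np.ndarray
    state: np.ndarray
    S: np.ndarray
    species: tuple[str, ...]
    params: tuple[str, ...]
    branch_id: int = 0

    def value(self, species: str, param: str) -> float:
        return float(self.S[self.species.index(species),
                            self.params.index(param)])

    def abs_value(self, species: str, param: str) -> float:
        return abs(self.value(species, param))


def _check_inputs(model: CircuitModel, ss: SteadyState,
                  zero_threshold: float) -> None:
    if not ss.stable:
        raise SensitivityError(
            f"{model.name}: sensitivities are defined on stable branches "
            "only")
    if float(np.min(ss.state)) <= zero_threshold:
        raise SensitivityError(
            f"{model.name}: species at {ss.state} too close to zero; the "
            "relative sensitivity divides by the species value")


def sensitivity_analytic(model: CircuitModel, theta, ss: SteadyState,
                         params: tuple[str, ...] | None = None,
                         branch_id: int = 0,
                         zero_threshold: float = 1e-8) -> SensitivityRecord:
    """Exact sensitivities via implicit differentiation at a stable root."""
    params = tuple(params or model.swept)
    th = model.pack(theta)
    _check_inputs(model, ss, zero_threshold)
    A = model.jac_x(ss.state, th)
    B = model.jac_theta(ss.state, th)
    try:
        dxdth = -np.linalg.solve(np.atleast_2d(A),
                                 np.atleast_2d(B))
    except np.linalg.LinAlgError as err:
        raise SensitivityError(
            f"{model.name}: singular species Jacobian at theta="
            f"{model.theta_dict(th)} (bifurcation point?)") from err
    S_full = dxdth * th[None, :] / ss.state[:, None]
    cols = [model.params.index(p) for p in params]
    S = S_full[:, cols]
    if not np.all(np.isfinite(S)):
        raise SensitivityError(
            f"{model.name}: non-finite sensitivity at theta="
            f"{model.theta_dict(th)}")
    return SensitivityRecord(theta=th, state=ss.state.copy(), S=S,
                             species=model.species, params=params,
                             branch_id=branch_id)


def _resolve_branch(model: CircuitModel, th: np.ndarray, ref: np.ndarray,
                    policy: SolverPolicy, param: str) -> np.ndarray:
    states = exclude_zero_states(find_steady_states(model, th, policy),
                                 policy.zero_threshold)
    if not states:
        raise BranchJumpError(
            f"{model.name}: no nonzero root after perturbing {param!r}")
    dists = [float(np.linalg.norm(s.state - ref)) for s in states]
    best = states[int(np.argmin(dists))]
    rel = min(dists) / (1.0 + float(np.linalg.norm(ref)))
    if rel > 0.1:
        raise BranchJumpError(
            f"{model.name}: steady state jumped branches when perturbing "
            f"{param!r} (relative move {rel:.3g}); likely near a "
            "bifurcation")
    return best.state


def sensitivity_fd(model: CircuitModel, theta, ss: SteadyState,
                   h_rel: float = 1e-6,
                   params: tuple[str, ...] | None = None,
                   policy: SolverPolicy | None = None,
                   branch_id: int = 0,
                   zero_threshold: float = 1e-8) -> SensitivityRecord:
    """Central-difference sensitivities; independent check of the
    implicit-differentiation route."""
    params = tuple(params or model.swept)
    policy = policy or SolverPolicy()
    th = model.pack(theta)
    _check_inputs(model, ss, zero_threshold)
    n_sp = len(model.species)
    S = np.empty((n_sp, len(params)))
    for j, p in enumerate(params):
        k = model.params.index(p)
        step = h_rel * th[k]
        if step == 0.0:
            S[:, j] = 0.0
            continue
        th_hi, th_lo = th.copy(), th.copy()
        th_hi[k] += step
        th_lo[k] -= step
        x_hi = _resolve_branch(model, th_hi, ss.state, policy, p)
        x_lo = _resolve_branch(model, th_lo, ss.state, policy, p)
        S[:, j] = (th[k] / ss.state) * (x_hi - x_lo) / (2.0 * step)
    return SensitivityRecord(theta=th, state=ss.state.copy(), S=S,
                             species=model.species, params=params,
                             branch_id=branch_id)


def sensitivity_column(species: str, param: str) -> str:
    """Column name used for S^{species}_{param} in tabular outputs."""
    return f"S_{species}_{param}"


def grid_sensitivities(model: CircuitModel, grid: ParameterGrid,
                       policy: SolverPolicy | None = None,
                       params: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Signed sensitivities on every stable nonzero branch of a grid.

    One row per (parameter point, stable branch).  Parameter points where
    no stable nonzero root exists, or where the Jacobian is singular, are
    skipped and counted in ``df.attrs``.
    """
    policy = policy or SolverPolicy()
    params = tuple(params or model.swept)
    pts = sample_grid(grid)
    labels = grid.labels
    rows: list[dict] = []
    n_empty = n_singular = 0
    for vec in pts:
        theta = dict(zip(labels, vec))
        theta.update(grid.fixed)
        th = model.pack(theta)
        states = exclude_zero_states(find_steady_states(model, th, policy),
                                     policy.zero_threshold)
        branches = [s for s in states if s.stable and not s.marginal]
        if not branches:
            n_empty += 1
            continue
        for b_id, ss in enumerate(branches):
            try:
                rec = sensitivity_analytic(model, th, ss, params=params,
                                           branch_id=b_id,
                                           zero_threshold=policy.zero_threshold)
            except SensitivityError:
                n_singular += 1
                continue
            row = {lab: float(v) for lab, v in zip(labels, vec)}
            row.update({k: float(v) for k, v in grid.fixed.items()})
            row["branch_id"] = b_id
            row["n_branches"] = len(branches)
            for i, sp_name in enumerate(model.species):
                row[sp_name] = float(ss.state[i])
            row["max_eig_re"] = float(np.max(ss.eigenvalues.real))
            for i, sp_name in enumerate(model.species):
                for j, p in enumerate(params):
                    row[sensitivity_column(sp_name, p)] = float(rec.S[i, j])
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["circuit"] = model.name
    df.attrs["n_points"] = len(pts)
    df.attrs["n_no_stable_root"] = n_empty
    df.attrs["n_singular"] = n_singular
    if n_empty or n_singular:
        log.info("%s: grid of %d points, %d without stable nonzero root, "
                 "%d singular", model.name, len(pts), n_empty, n_singular)
    return df
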