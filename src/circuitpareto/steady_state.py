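"""Steady-state solving, stability classification and timecourse simulation.

Roots of the circuit dynamics are located deterministically: the system is
reduced to a scalar equation in the first species (for two-species models
by substituting the second species' nullcline), the residual is scanned on
a mixed log/linear grid spanning the admissible range, and every sign
change is refined with Brent's method to machine precision.  The origin is
checked explicitly because it can be an exact root (e.g. under positive
autoregulation) that a sign-change scan cannot bracket.

Stability is read off the eigenvalues of the species Jacobian: a root is
stable when every eigenvalue has real part below -margin; roots within the
margin of the imaginary axis are flagged marginal (likely bifurcation
points) and excluded from downstream sensitivity analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root as scipy_root

from .circuits import CircuitModel

__all__ = [
    "SteadyState",
    "SolverPolicy",
    "Trajectory",
    "SteadyStateError",
    "find_steady_states",
    "exclude_zero_states",
    "count_branches",
    "stable_states",
    "simulate",
]

log = logging.getLogger(__name__)


class SteadyStateError(RuntimeError):
    """Steady-state solving or integration failed at a parameter point."""


@dataclass(frozen=True)
class SteadyState:
    """A nonnegative root of the dynamics with its stability label."""

    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    residual: float
    marginal: bool = False

    @property
    def x(self) -> float:
        return float(self.state[0])


@dataclass(frozen=True)
class SolverPolicy:
    """Numerical settings for the deterministic root search."""

    scan_points: int = 256        # residual scan resolution per bracket pass
    residual_tol: float = 1e-9    # max |f| accepted for a root
    dedup_rel: float = 1e-6       # roots merged below this relative distance
    dedup_abs: float = 1e-9       # ... with this absolute floor near zero
    stability_margin: float = 1e-9
    zero_threshold: float = 1e-8  # min species value of a "nonzero" state

    def tighter(self, factor: float = 10.0) -> "SolverPolicy":
        """Same policy with a denser scan and tighter residual tolerance."""
        return replace(self, scan_points=int(self.scan_points * 2),
                       residual_tol=self.residual_tol / factor)


@dataclass(frozen=True)
class Trajectory:
    """A simulated timecourse: times strictly increasing, states >= 0."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_species)


def _scalar_root_candidates(model: CircuitModel, theta: np.ndarray,
                            policy: SolverPolicy) -> list[float]:
    hi = model.x_upper(theta) * 1.05 + 1e-9
    m = policy.scan_points // 2
    xs = np.unique(np.concatenate([
        np.geomspace(1e-12, hi, m),
        np.linspace(1e-12, hi, m),
    ]))
    with np.errstate(all="ignore"):
        res = np.asarray(model.scalar_residual(xs, theta), dtype=float)
    ok = np.isfinite(res)
    xs, res = xs[ok], res[ok]
    roots: list[float] = []
    fn = lambda x: float(model.scalar_residual(x, theta))
    for i in range(len(xs) - 1):
        if res[i] == 0.0:
            roots.append(float(xs[i]))
        elif res[i] * res[i + 1] < 0:
            roots.append(brentq(fn, xs[i], xs[i + 1],
                                xtol=1e-14, rtol=4 * np.finfo(float).eps))
    if len(res) and res[-1] == 0.0:
        roots.append(float(xs[-1]))
    return roots


def _classify(model: CircuitModel, state: np.ndarray, theta: np.ndarray,
              policy: SolverPolicy, residual: float) -> SteadyState:
    with np.errstate(all="ignore"):
        jac = model.jac_x(state, theta)
    if not np.all(np.isfinite(jac)):
        eig = np.full(len(state), np.nan, dtype=complex)
        return SteadyState(state=state, eigenvalues=eig, stable=False,
                           residual=residual, marginal=True)
    eig = np.atleast_1d(np.linalg.eigvals(np.atleast_2d(jac)))
    max_re = float(np.max(eig.real))
    stable = max_re < -policy.stability_margin
    marginal = abs(max_re) <= policy.stability_margin
    return SteadyState(state=state, eigenvalues=eig, stable=stable,
                       residual=residual, marginal=marginal)


def find_steady_states(model: CircuitModel, theta,
                       policy: SolverPolicy | None = None,
                       ) -> list[SteadyState]:
    """All distinct nonnegative steady states at one parameter point.

    Roots are deduplicated, classified for stability, and ordered by the
    first species value ascending.  An empty result is logged as a
    warning, never silently dropped.
    """
    policy = policy or SolverPolicy()
    th = model.pack(theta)
    states: list[np.ndarray] = []

    # explicit origin check (exact root under pure activation)
    origin = np.zeros(len(model.species))
    with np.errstate(all="ignore"):
        f0 = model.f(origin, th)
    if np.all(np.isfinite(f0)) and np.max(np.abs(f0)) <= policy.residual_tol:
        states.append(origin)

    for x_root in _scalar_root_candidates(model, th, policy):
        if len(model.species) == 1:
            cand = np.array([x_root])
        else:
            y_root = float(model.y_given_x(x_root, th))
            cand = np.array([x_root, y_root])
        if np.any(cand < 0) or not np.all(np.isfinite(cand)):
            continue
        resid = float(np.max(np.abs(model.f(cand, th))))
        if resid > policy.residual_tol:
            # fall back to a damped Newton polish on the full system
            sol = scipy_root(lambda s: model.f(s, th), cand,
                             jac=lambda s: model.jac_x(s, th), method="hybr")
            cand2 = np.asarray(sol.x, dtype=float)
            resid2 = float(np.max(np.abs(model.f(cand2, th))))
            if sol.success and resid2 <= policy.residual_tol \
                    and np.all(cand2 >= -policy.dedup_abs):
                cand, resid = np.clip(cand2, 0, None), resid2
            else:
                log.warning("%s: discarding unconverged root %s (|f|=%.2e) "
                            "at theta=%s", model.name, cand, resid,
                            model.theta_dict(th))
                continue
        states.append(cand)

    # deduplicate
    unique: list[np.ndarray] = []
    for cand in sorted(states, key=lambda s: s[0]):
        dup = False
        for kept in unique:
            scale = np.maximum(np.abs(kept), np.abs(cand))
            tol = np.maximum(policy.dedup_abs, policy.dedup_rel * scale)
            if np.all(np.abs(kept - cand) <= tol):
                dup = True
                break
        if not dup:
            unique.append(cand)

    if not unique:
        log.warning("%s: no steady state converged at theta=%s",
                    model.name, model.theta_dict(th))
        return []

    out = []
    for cand in unique:
        resid = float(np.max(np.abs(model.f(cand, th))))
        out.append(_classify(model, cand, th, policy, resid))
    return out


def exclude_zero_states(states: list[SteadyState],
                        threshold: float = 1e-8) -> list[SteadyState]:
    """Drop steady states with any species below threshold.

    The relative sensitivity divides by the species value, so (near-)zero
    roots are ill-defined for the analysis and must be removed.
    """
    return [s for s in states if float(np.min(s.state)) >= threshold]


def stable_states(model: CircuitModel, theta,
                  policy: SolverPolicy | None = None) -> list[SteadyState]:
    """Nonzero, strictly stable (non-marginal) steady states."""
    policy = policy or SolverPolicy()
    states = exclude_zero_states(find_steady_states(model, theta, policy),
                                 policy.zero_threshold)
    kept = [s for s in states if s.stable and not s.marginal]
    if any(s.marginal for s in states):
        log.warning("%s: marginal root near a bifurcation excluded at "
                    "theta=%s", model.name, model.theta_dict(theta))
    return kept


def count_branches(model: CircuitModel, theta,
                   policy: SolverPolicy | None = None) -> tuple[int, int]:
    """(total, stable) counts over the nonzero steady-state branches."""
    policy = policy or SolverPolicy()
    states = exclude_zero_states(find_steady_states(model, theta, policy),
                                 policy.zero_threshold)
    return len(states), sum(1 for s in states if s.stable)


def simulate(model: CircuitModel, theta, x0, horizon: float,
             n_points: int = 400, rtol: float = 1e-9,
             atol: float = 1e-12) -> Trajectory:
    """Integrate the circuit ODEs from x0 over [0, horizon]."""
    th = model.pack(theta)
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    sol = solve_ivp(
        lambda t, s: model.f(np.clip(s, 0, None), th),
        (0.0, float(horizon)), x0, method="LSODA",
        t_eval=np.linspace(0.0, float(horizon), n_points),
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SteadyStateError(
            f"{model.name}: integration failed at theta="
            f"{model.theta_dict(th)}: {sol.message}")
    return Trajectory(times=sol.t, states=np.clip(sol.y.T, 0.0, None))
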