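"""Registry of nondimensionalized feedback gene-circuit models.

The circuits are small ODE systems built from Hill kinetics: positive and
negative autoregulation of a single gene, the double-positive feedback
loop, the positive-negative feedback loop, the toggle switch (mutual
repression), and two upstream/downstream cascade variants.  After
nondimensionalization every production rate becomes a unitless "feedback
strength" -- the ratio of the maximal production rate to the product of
the dissociation constant and the degradation rate -- the first species
degrades at unit rate, and two-species circuits carry the
degradation-rate ratio ``gamma``.  Promoter leakiness enters as a
unitless additive production term ``L``.

Models are stored symbolically (sympy) and compiled once to numpy
callables: the dynamics ``f(state, theta)``, the species Jacobian
``jac_x`` and the parameter Jacobian ``jac_theta``.  For root finding,
each two-species system is additionally reduced to one scalar equation in
the first species by substituting the second species' nullcline.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "CIRCUIT_NAMES",
    "COOPERATIVITY_RANGE",
    "DEGRADATION_RANGE",
    "DISSOCIATION_RANGE",
    "LEAKINESS_FRACTION",
    "PRODUCTION_RANGE",
    "STRENGTH_RANGE",
    "CircuitModel",
    "CircuitRegistryError",
    "DimensionalRates",
    "ParameterGrid",
    "UnitlessParameters",
    "default_grid",
    "feedback_strength_bounds",
    "leakiness_bounds",
    "leaky_variant",
    "make_circuit",
    "nondimensionalize",
    "sample_grid",
]

# Dimensional ranges for bacterial/yeast gene expression.
PRODUCTION_RANGE = (0.02, 0.1)      # synthesis rate, nM / min
DISSOCIATION_RANGE = (0.01, 10.0)   # dissociation constant, nM
DEGRADATION_RANGE = (0.01, 0.24)    # degradation + dilution, 1 / min
LEAKINESS_FRACTION = 0.2            # max basal rate as fraction of production

# Unitless ranges actually sampled.
STRENGTH_RANGE = (0.01, 50.0)       # feedback strengths alpha, beta_x, beta_y
COOPERATIVITY_RANGE = (0.01, 10.0)  # Hill exponent n


class CircuitRegistryError(ValueError):
    """Unknown circuit name requested from the registry."""


# ---------------------------------------------------------------------------
# symbolic building blocks
# ---------------------------------------------------------------------------

_X, _Y = sp.symbols("x y", positive=True)
_SYM = {name: sp.Symbol(name, positive=True)
        for name in ("alpha", "beta_x", "beta_y", "n", "gamma", "L")}


def _act(s: sp.Expr) -> sp.Expr:
    """Activating Hill term s^n / (1 + s^n)."""
    n = _SYM["n"]
    return s ** n / (1 + s ** n)


def _rep(s: sp.Expr) -> sp.Expr:
    """Repressing Hill term 1 / (1 + s^n)."""
    n = _SYM["n"]
    return 1 / (1 + s ** n)


# Each entry: species symbols, production expressions, ordered parameters,
# default MOO-swept subset.  dx/dt = prod_x - x; for a second species,
# dy/dt = gamma * (prod_y - y) when gamma is a parameter, else prod_y - y.
_BASE_DEFS: dict[str, dict] = {
    "positive_autoreg": dict(
        species=(_X,),
        prods={_X: _SYM["alpha"] * _act(_X)},
        params=("alpha", "n"),
        swept=("alpha", "n"),
    ),
    "negative_autoreg": dict(
        species=(_X,),
        prods={_X: _SYM["alpha"] * _rep(_X)},
        params=("alpha", "n"),
        swept=("alpha", "n"),
    ),
    "double_positive": dict(
        species=(_X, _Y),
        prods={_X: _SYM["beta_x"] * _act(_Y), _Y: _SYM["beta_y"] * _act(_X)},
        params=("beta_x", "beta_y", "n", "gamma"),
        swept=("beta_x", "beta_y", "n"),
    ),
    "positive_negative": dict(
        species=(_X, _Y),
        prods={_X: _SYM["beta_x"] * _rep(_Y), _Y: _SYM["beta_y"] * _act(_X)},
        params=("beta_x", "beta_y", "n", "gamma"),
        swept=("beta_x", "beta_y", "n"),
    ),
    "toggle": dict(
        species=(_X, _Y),
        prods={_X: _SYM["beta_x"] * _rep(_Y), _Y: _SYM["beta_y"] * _rep(_X)},
        params=("beta_x", "beta_y", "n", "gamma"),
        swept=("beta_x", "beta_y", "n"),
    ),
    # Autoregulated gene x driving a downstream gene y at no cost to x.
    # y shares the cooperativity n and degrades at unit rate.
    "autoreg_plus_downstream": dict(
        species=(_X, _Y),
        prods={_X: _SYM["beta_x"] * _act(_X), _Y: _SYM["beta_y"] * _act(_X)},
        params=("beta_x", "beta_y", "n"),
        swept=("beta_x", "beta_y", "n"),
    ),
    # Constitutively expressed x driving the same downstream gene y.
    "constitutive_plus_downstream": dict(
        species=(_X, _Y),
        prods={_X: _SYM["beta_x"], _Y: _SYM["beta_y"] * _act(_X)},
        params=("beta_x", "beta_y", "n"),
        swept=("beta_x", "beta_y", "n"),
    ),
}

CIRCUIT_NAMES: tuple[str, ...] = (
    "positive_autoreg",
    "negative_autoreg",
    "negative_autoreg_leaky",
    "double_positive",
    "positive_negative",
    "toggle",
    "autoreg_plus_downstream",
    "constitutive_plus_downstream",
)


@dataclass(frozen=True)
class CircuitModel:
    """A named nondimensionalized ODE circuit.

    ``params`` fixes the ordering of parameter vectors; ``swept`` is the
    default subset entering sensitivity/MOO analyses (``gamma`` and ``L``
    never appear in it: gamma is absent from the steady-state equations
    and L is treated as a study condition, not an optimization variable).
    """

    name: str
    species: tuple[str, ...]
    params: tuple[str, ...]
    swept: tuple[str, ...]
    defaults: Mapping[str, float]
    leaky: bool = False
    sym_species: tuple = field(default=(), repr=False)
    sym_params: tuple = field(default=(), repr=False)
    sym_dynamics: tuple = field(default=(), repr=False)
    _f: Callable = field(default=None, repr=False)
    _jac_x: Callable = field(default=None, repr=False)
    _jac_theta: Callable = field(default=None, repr=False)
    _scalar: Callable = field(default=None, repr=False)
    _y_of_x: Callable | None = field(default=None, repr=False)

    # -- parameter handling -------------------------------------------------
    def pack(self, theta) -> np.ndarray:
        """Coerce a mapping or sequence into the canonical parameter vector."""
        if isinstance(theta, Mapping):
            missing = [p for p in self.params
                       if p not in theta and p not in self.defaults]
            if missing:
                raise ValueError(
                    f"{self.name}: missing parameter(s) {missing}; "
                    f"expected {self.params}")
            return np.array([float(theta.get(p, self.defaults.get(p)))
                             for p in self.params])
        vec = np.asarray(theta, dtype=float)
        if vec.shape != (len(self.params),):
            raise ValueError(
                f"{self.name}: expected {len(self.params)} parameters "
                f"{self.params}, got shape {vec.shape}")
        return vec

    def theta_dict(self, theta) -> dict[str, float]:
        vec = self.pack(theta)
        return dict(zip(self.params, vec.tolist()))

    # -- compiled evaluators ------------------------------------------------
    def f(self, state, theta) -> np.ndarray:
        """Time derivative of the species vector."""
        th = self.pack(theta)
        state = np.asarray(state, dtype=float)
        return np.asarray(self._f(*state, *th), dtype=float).reshape(-1)

    def jac_x(self, state, theta) -> np.ndarray:
        """Jacobian of the dynamics w.r.t. the species."""
        th = self.pack(theta)
        state = np.asarray(state, dtype=float)
        return np.asarray(self._jac_x(*state, *th), dtype=float)

    def jac_theta(self, state, theta) -> np.ndarray:
        """Jacobian of the dynamics w.r.t. all declared parameters."""
        th = self.pack(theta)
        state = np.asarray(state, dtype=float)
        return np.asarray(self._jac_theta(*state, *th), dtype=float)

    def scalar_residual(self, x, theta):
        """dx/dt along the second species' nullcline (scalar in x)."""
        th = self.pack(theta)
        return self._scalar(x, *th)

    def y_given_x(self, x, theta):
        """Second species' nullcline value y(x); None for 1-species models."""
        if self._y_of_x is None:
            return None
        th = self.pack(theta)
        return self._y_of_x(x, *th)

    def x_upper(self, theta) -> float:
        """Upper bound on any steady-state value of the first species."""
        d = self.theta_dict(theta)
        return float(d[self.params[0]] + d.get("L", 0.0))

    def state_upper(self, theta) -> np.ndarray:
        d = self.theta_dict(theta)
        leak = d.get("L", 0.0)
        bounds = [d[self.params[0]] + leak]
        if len(self.species) == 2:
            bounds.append(d["beta_y"] + leak)
        return np.asarray(bounds)


def _compile(name: str, species: tuple, prods: dict, params: tuple,
             swept: tuple, leaky: bool) -> CircuitModel:
    param_syms = tuple(_SYM[p] for p in params)
    gamma = _SYM["gamma"]
    dynamics = []
    for s in species:
        rate = prods[s] - s
        if s is _Y and "gamma" in params:
            rate = gamma * rate
        dynamics.append(rate)
    dyn = sp.Matrix(dynamics)
    # cancel() collapses each derivative into a single fraction; the raw
    # chain-rule form is a difference of two nearly equal terms that loses
    # all precision where the Hill functions saturate
    jac_x_expr = dyn.jacobian(sp.Matrix(species)).applyfunc(sp.cancel)
    jac_th_expr = dyn.jacobian(sp.Matrix(param_syms)).applyfunc(sp.cancel)

    if len(species) == 1:
        scalar_expr = dynamics[0]
        y_of_x_expr = None
    else:
        y_of_x_expr = prods[_Y]  # dy/dt = 0  <=>  y = prod_y(x)
        scalar_expr = dynamics[0].subs(_Y, y_of_x_expr)

    args = tuple(species) + param_syms
    lam = lambda e: sp.lambdify(args, e, modules="numpy")
    defaults = {}
    if "gamma" in params:
        defaults["gamma"] = 1.0
    if "L" in params:
        defaults["L"] = 0.0
    return CircuitModel(
        name=name,
        species=tuple(str(s) for s in species),
        params=params,
        swept=swept,
        defaults=defaults,
        leaky=leaky,
        sym_species=tuple(species),
        sym_params=param_syms,
        sym_dynamics=tuple(dynamics),
        _f=lam(tuple(dynamics)),
        _jac_x=lam(jac_x_expr),
        _jac_theta=lam(jac_th_expr),
        _scalar=sp.lambdify((species[0],) + param_syms, scalar_expr,
                            modules="numpy"),
        _y_of_x=(None if y_of_x_expr is None else
                 sp.lambdify((species[0],) + param_syms, y_of_x_expr,
                             modules="numpy")),
    )


def _build_base(name: str) -> CircuitModel:
    d = _BASE_DEFS[name]
    return _compile(name, d["species"], d["prods"], d["params"],
                    d["swept"], leaky=False)


def leaky_variant(circuit: "CircuitModel | str") -> CircuitModel:
    """Add a basal (leaky) production rate ``L`` to every production term.

    Mirrors how promoter leakiness enters the negative-autoregulation
    model: the unitless leak L adds to each Hill production term.  The
    variant reduces exactly to its base circuit at L = 0.
    """
    name = circuit if isinstance(circuit, str) else circuit.name
    if name.endswith("_leaky"):
        raise CircuitRegistryError(f"{name!r} is already a leaky variant")
    if name not in _BASE_DEFS:
        raise CircuitRegistryError(
            f"unknown circuit {name!r}; base circuits: {sorted(_BASE_DEFS)}")
    d = _BASE_DEFS[name]
    prods = {s: expr + _SYM["L"] for s, expr in d["prods"].items()}
    return _compile(name + "_leaky", d["species"], prods,
                    d["params"] + ("L",), d["swept"], leaky=True)


_CACHE: dict[str, CircuitModel] = {}


def make_circuit(name: str) -> CircuitModel:
    """Look up a circuit by name.

    Valid names are listed in :data:`CIRCUIT_NAMES`; leaky variants of any
    base circuit are available through :func:`leaky_variant`.
    """
    if name not in CIRCUIT_NAMES:
        raise CircuitRegistryError(
            f"unknown circuit {name!r}; valid names: {list(CIRCUIT_NAMES)}")
    if name not in _CACHE:
        if name == "negative_autoreg_leaky":
            _CACHE[name] = leaky_variant("negative_autoreg")
        else:
            _CACHE[name] = _build_base(name)
    return _CACHE[name]


# ---------------------------------------------------------------------------
# dimensional rates -> unitless parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimensionalRates:
    """Dimensional kinetic rates for one regulated gene.

    production  maximal synthesis rate (nM/min)
    dissociation  Hill dissociation constant (nM)
    degradation  degradation + dilution rate (1/min)
    leakiness  basal synthesis rate (nM/min), optional
    cooperativity  Hill exponent, unitless, passes through unchanged
    """

    production: float
    dissociation: float
    degradation: float
    leakiness: float | None = None
    cooperativity: float | None = None

    def __post_init__(self):
        for attr in ("production", "dissociation", "degradation"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{attr} must be strictly positive, "
                                 f"got {getattr(self, attr)}")
        if self.leakiness is not None and self.leakiness < 0:
            raise ValueError("leakiness must be nonnegative")


@dataclass(frozen=True)
class UnitlessParameters:
    feedback_strength: float
    leakiness: float | None = None
    cooperativity: float | None = None


def nondimensionalize(rates: DimensionalRates) -> UnitlessParameters:
    """Map dimensional rates to unitless model parameters.

    The feedback strength is production / (dissociation * degradation);
    the leak maps the same way; cooperativity is already unitless.
    """
    denom = rates.dissociation * rates.degradation
    if not denom > 0:
        raise ValueError("dissociation and degradation must be positive")
    leak = None if rates.leakiness is None else rates.leakiness / denom
    return UnitlessParameters(
        feedback_strength=rates.production / denom,
        leakiness=leak,
        cooperativity=rates.cooperativity,
    )


def feedback_strength_bounds(
    production_range: tuple[float, float] = PRODUCTION_RANGE,
    dissociation_range: tuple[float, float] = DISSOCIATION_RANGE,
    degradation_range: tuple[float, float] = DEGRADATION_RANGE,
) -> tuple[float, float]:
    """Unitless feedback-strength bounds from the dimensional corners."""
    vals = [
        nondimensionalize(DimensionalRates(p, k, g)).feedback_strength
        for p, k, g in itertools.product(
            production_range, dissociation_range, degradation_range)
    ]
    return (min(vals), max(vals))


def leakiness_bounds(
    production_range: tuple[float, float] = PRODUCTION_RANGE,
    dissociation_range: tuple[float, float] = DISSOCIATION_RANGE,
    degradation_range: tuple[float, float] = DEGRADATION_RANGE,
    fraction: float = LEAKINESS_FRACTION,
) -> tuple[float, float]:
    """Bounds of the unitless leak L with basal rate up to fraction*production."""
    vals = [
        nondimensionalize(
            DimensionalRates(p, k, g, leakiness=fraction * p)).leakiness
        for p, k, g in itertools.product(
            production_range, dissociation_range, degradation_range)
    ]
    return (min(vals), max(vals))


# ---------------------------------------------------------------------------
# parameter grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterGrid:
    """Even grid over selected parameters, with others held fixed.

    axes  label -> (lower, upper, count); endpoints included, count >= 2
    fixed  parameters held constant (e.g. gamma=1, L=10)
    spacing  "linear" (default) or "log"
    extra  label -> additional values merged into that axis
    """

    axes: Mapping[str, tuple[float, float, int]]
    fixed: Mapping[str, float] = field(default_factory=dict)
    spacing: str = "linear"
    extra: Mapping[str, Sequence[float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.spacing not in ("linear", "log"):
            raise ValueError(f"spacing must be 'linear' or 'log', "
                             f"got {self.spacing!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.axes)

    def axis_values(self, label: str) -> np.ndarray:
        lo, hi, count = self.axes[label]
        if count < 2:
            raise ValueError(
                f"axis {label!r}: swept axes need at least 2 points, "
                f"got count={count}")
        if not hi > lo:
            raise ValueError(f"axis {label!r}: upper bound must exceed lower")
        if self.spacing == "log":
            if lo <= 0:
                raise ValueError(f"axis {label!r}: log spacing needs lo > 0")
            vals = np.geomspace(lo, hi, count)
        else:
            vals = np.linspace(lo, hi, count)
        if label in self.extra:
            vals = np.unique(np.concatenate(
                [vals, np.asarray(self.extra[label], dtype=float)]))
        return vals

    @property
    def size(self) -> int:
        return int(np.prod([len(self.axis_values(a)) for a in self.axes]))


def sample_grid(grid: ParameterGrid) -> np.ndarray:
    """Cartesian product of the axis values, row-major over the axis order.

    Returns an array of shape (n_points, n_axes); the column order matches
    ``grid.labels`` and axis endpoints are always included.
    """
    values = [grid.axis_values(a) for a in grid.labels]
    mesh = np.meshgrid(*values, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def default_grid(model: CircuitModel, resolution: int | None = None,
                 fixed: Mapping[str, float] | None = None,
                 extra: Mapping[str, Sequence[float]] | None = None,
                 ) -> ParameterGrid:
    """The standard sampling grid for a circuit's swept parameters.

    Feedback strengths sweep STRENGTH_RANGE and the cooperativity sweeps
    COOPERATIVITY_RANGE.  Default resolution is 100 points per axis for
    two swept parameters and 30 for three (desk-scale stand-ins for the
    much denser production grids; classifications are checked to be
    stable under grid refinement).
    """
    if resolution is None:
        resolution = 100 if len(model.swept) == 2 else 30
    axes = {}
    for p in model.swept:
        rng = COOPERATIVITY_RANGE if p == "n" else STRENGTH_RANGE
        axes[p] = (rng[0], rng[1], resolution)
    fixed_all = {p: model.defaults[p] for p in model.params
                 if p in model.defaults}
    if fixed:
        fixed_all.update(fixed)
    return ParameterGrid(axes=axes, fixed=fixed_all,
                         extra=dict(extra or {}))
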