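# Methods

## Circuit models

All circuits are deterministic ODE models of gene regulation with Hill
kinetics, after nondimensionalization: species are measured in units of
the Hill dissociation constant and time in units of the first species'
degradation rate. The registry holds eight models:

| name | equations (unitless) |
|---|---|
| `positive_autoreg` | dx/dt = α·xⁿ/(1+xⁿ) − x |
| `negative_autoreg` | dx/dt = α/(1+xⁿ) − x |
| `negative_autoreg_leaky` | dx/dt = L + α/(1+xⁿ) − x |
| `double_positive` | dx/dt = β_x·yⁿ/(1+yⁿ) − x; dy/dt = γ(β_y·xⁿ/(1+xⁿ) − y) |
| `positive_negative` | dx/dt = β_x/(1+yⁿ) − x; dy/dt = γ(β_y·xⁿ/(1+xⁿ) − y) |
| `toggle` | dx/dt = β_x/(1+yⁿ) − x; dy/dt = γ(β_y/(1+xⁿ) − y) |
| `autoreg_plus_downstream` | dx/dt = β_x·xⁿ/(1+xⁿ) − x; dy/dt = β_y·xⁿ/(1+xⁿ) − y |
| `constitutive_plus_downstream` | dx/dt = β_x − x; dy/dt = β_y·xⁿ/(1+xⁿ) − y |

`leaky_variant(name)` adds the unitless basal rate `L` to every
production term of any base circuit; every leaky variant reduces
exactly to its base at `L = 0`.

The downstream-cascade models assume the downstream gene `y` shares the
cooperativity `n`, imposes no load on `x`, and degrades at unit rate
(no separate `γ`); this is the natural minimal reading of "x drives y
at no cost to x", and it makes the cascade's x-sensitivities provably
identical to plain positive autoregulation (checked in the tests).

Models are written once symbolically (sympy) and compiled to numpy
callables for the dynamics and both Jacobians. Jacobian entries are
canonicalized to single fractions (`cancel`) before compilation: the
raw chain-rule form is a difference of nearly equal terms and loses all
significant digits where the Hill functions saturate.

### Parameters, units, defaults

- Dimensional ranges (bacterial/yeast gene expression): production
  α, β ∈ [0.02, 0.1] nM·min⁻¹; dissociation k ∈ [0.01, 10] nM;
  degradation+dilution γ ∈ [0.01, 0.24] min⁻¹; basal (leaky)
  production up to 20 % of the maximal rate.
- Unitless feedback strength = production/(k·γ), hence spanning
  [1/120, 1000] over the corners; the sampled range is truncated to
  [0.01, 50] for practicality. The unitless leak L spans up to 200.
- Cooperativity n ∈ [0.01, 10]: n = 0 removes the feedback entirely,
  so a small positive lower bound is used; 10 covers the single-digit
  cooperativities typical of real promoters.
- γ (degradation-rate ratio of the two species) defaults to 1 and is
  held fixed: it is absent from every steady-state equation (checked as
  a test invariant), so steady-state sensitivities to the swept
  parameters do not depend on it and its own sensitivity is
  identically zero. It is therefore excluded from the MOO objective
  universe, as is L, which is treated as a study condition.

## Steady states

Every registry circuit admits an explicit nullcline for the second
species (`dy/dt = 0 ⇔ y = g(x)`), so the root problem reduces to one
scalar equation in `x`. The solver scans the scalar residual on a
merged log/linear grid (default 256 points) over `(1e−12, x_max]`,
where `x_max` bounds any steady state by the total production rate, and
refines each sign change with Brent's method to machine precision. The
origin is tested explicitly because it can be an exact root (pure
activation) that no sign change brackets. A `scipy.optimize.root`
polish acts as a fallback for candidates whose full-system residual
exceeds the tolerance (1e−9). This deterministic reduction replaces a
multi-start fsolve scheme: it provably brackets every root of the
monotone Hill nullclines, captures all three toggle branches, and is
fast enough to make three-dimensional grid censuses interactive.

Roots are deduplicated (relative 1e−6, absolute 1e−9), ordered by
ascending first species, and classified by the eigenvalues of ∂f/∂x:
stable if max Re(λ) < −1e−9, marginal (near a bifurcation) if
|max Re(λ)| ≤ 1e−9. Marginal roots are excluded from sensitivity
analysis with a warning. States with any species below 1e−8 are
excluded from the analysis because the relative sensitivity divides by
the species value.

Known limitation: a tangency (double) root exactly at a fold produces
no sign change and can be missed between scan points; such roots are
marginal and would be excluded anyway.

## Sensitivities

The relative sensitivity matrix is evaluated by the implicit function
theorem, `∂x/∂θ = −(∂f/∂x)⁻¹(∂f/∂θ)`, scaled to
`S = diag(θ)·∂x/∂θ·diag(1/x)` — this *is* the closed form each
per-circuit expression reduces to (for negative autoregulation,
`S_α = 1/(1+n·h)` and `S_n = −n·h·ln(x)/(1+n·h)` with
`h = xⁿ/(1+xⁿ)`; the tests pin several such hand-derived forms). An
independent central-difference route re-solves the steady state at
`θ_j(1 ± 1e−6)` with nearest-branch tracking and raises an error if the
re-solve jumps branches (a bifurcation signal). Analytic and
finite-difference routes agree to better than 1e−5 relative error on
random in-range points of every circuit; this dual route is part of the
test suite and the `verify` CLI command.

## Pareto analysis

The cloud for an objective pair collects `(|S| , |S|)` at every stable
nonzero branch of every grid point (both toggle branches contribute,
with branch provenance). The non-dominated subset is found by a
sort-and-sweep pass, cross-checked against a brute-force all-pairs
oracle in the tests. Two numerical policies matter:

- **Tie snapping.** Dominance comparisons are made on values rounded to
  12 significant digits. The linear solve carries ~1e−15 relative
  noise, and in saturated regions thousands of points tie at the true
  value (e.g. `|S_α| = 1` for positive autoregulation); comparing raw
  doubles would let that noise pick an arbitrary tie winner.
- **Artifact filtering.** Every front member is re-solved at tighter
  tolerance and cross-checked analytic-vs-finite-difference; members
  failing either check are removed and the front is re-formed. This
  guards against spurious front points caused by an unconverged root.

**Trade-off classification.** A pair is labeled `none` when the utopia
point — the per-objective minima over the cloud — is attained by a
single sampled point to within 1e−3 of the cloud's extent per
objective (absolute floor 1e−6); otherwise `tradeoff`. This captures
the scientific question directly (can both sensitivities be minimized
at once?) and is robust to two artifacts of exact dominance on discrete
clouds: single-point fronts trivially classify as `none`, and L-shaped
fronts that hug the axes but pass through a joint near-minimum (the
toggle's typical geometry, with spurs whose coordinates differ only at
1e−79) also classify as `none`, matching their collapsed appearance at
any plotting scale. All classifications are unchanged under doubling of
the grid resolution (tested).

**Objective equivalence.** In the mutually coupled two-species loops
the sensitivity of `x` to `β_x` is *pointwise identical* to that of `y`
to `β_y` (both equal `1/(1 ± ab)` where `a`, `b` are the cross-coupling
strengths), so pairs built from the two restate the same trade-off. The
census detects identical objective columns, reports every raw pair, and
counts distinct trade-offs at the equivalence-class level: the
positive–negative loop has 8 trade-off rows but exactly 4 distinct
trade-offs, all involving `|S^x_{β_x}|`.

## Studies

- **Leakiness sweep** re-runs one MOO problem on a circuit's leaky
  variant at `L ∈ {0, 0.1, 1, 10}` over the same grid. Raising `L`
  raises the steady state while barely moving the absolute derivatives,
  so relative sensitivities shrink: `|S_α|` shrinks at every grid
  point, the *extent* of the `|S_n|` region shrinks (pointwise
  monotonicity fails near the `S_n = 0` locus, where the leak can push
  `x_ss` across 1), fronts move toward the origin monotonically, and by
  `L = 10` every circuit's census is trade-off free.
- **Downstream comparison** runs the same grid and objective pair
  through the constitutive and autoregulated cascade variants. Under
  the minimal shared-`n` cascade model above, both variants' downstream
  objectives vanish together at the saturated grid corner, so both
  classify `none` with the default pair `(|S^y_{β_x}|, |S^y_n|)`; a
  qualitative upstream-feedback-induced contrast between the two would
  require a cascade model with additional asymmetry (e.g. a separate
  downstream Hill exponent or dissociation scale), which is outside the
  registry's minimal reading. The pair is fully configurable.

## Problem sizes and determinism

Default grids are 100×100 for two swept parameters and 30×30×30 for
three — desk-scale stand-ins for much denser production sampling,
justified by the grid-refinement stability of every classification.
Everything is deterministic: fixed grid ordering, deterministic
bracketing, no random starts; repeated runs byte-reproduce all CSV/JSON
outputs. The synthetic parameter grids *are* the study inputs — no
external data exists in this problem — so the tests exercise the same
objects a production analysis would, only at reduced resolution; what
they cannot show is anything about kinetics outside the Hill-type model
class (no transcription/translation delays, no stochasticity, no
transient sensitivity).
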