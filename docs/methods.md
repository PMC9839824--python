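# Methods

## Model class and assumptions

`kmreduce` treats outbreaks in a closed population: no births, deaths,
immigration or waning immunity.  This is essential, not cosmetic — the
integrated form tracks *Q(t)*, the per-compartment person-time integral
accumulated since the infinite past, and with demographic turnover or
reinfection those integrals diverge, so no integrated version exists.
Endemic-equilibrium questions are out of scope.

The infection process is coded by the triple *(V, Σ, U)*:

* *V* (length *n*, entries ≥ 0, sum in (0, 1]) — the probability
  distribution of the compartment an individual enters at infection.  A
  sum below one is accepted and interpreted as a fraction of infections
  that never contribute to transmission (a warning is logged).
* *Σ* (*n* × *n*, units 1/time) — transition rates among the infected
  compartments, with the column-to-row convention `dQ/dt = ΣQ`:
  `Sigma[i][j]` is the rate from compartment *j* into compartment *i*.
  We require a *subgenerator*: nonnegative off-diagonal entries,
  nonpositive diagonal, and every eigenvalue with real part below
  −1e−12.  This guarantees `e^{τΣ}` is entrywise nonnegative, the kernel
  `b(τ) = U e^{τΣ} V` is nonnegative and integrable, and
  `∫₀^∞ e^{τΣ} dτ = −Σ⁻¹` exists.  The restriction excludes exotic
  (e.g. oscillatory) kernels that the matrix-exponential form could in
  principle represent; nothing in the package depends on them.
* *U* (length *n*, units 1/(time·individual)) — each compartment's
  contribution rate to the force of infection, with at least one
  positive entry.

Heterogeneity is *separable and static*: the three-argument kernel
factorises as `A(τ, x, ξ) = a(x) b(τ) c(ξ)` with traits fixed for life.
Non-separable kernels and dynamically changing traits are out of scope.
The trait model consists of a distribution Φ (finite atoms, or a density
on an interval with possibly infinite right endpoint), a susceptibility
map *a* and an infectiousness map *c*, normalised so `a(x̄) = c(x̄) = 1`
at a reference trait x̄ (the mean trait for continuous distributions).
All trait-specific observables then follow from the reference-trait
cumulative force *w*: `s(t, x) = s̄(t)^{a(x)}` with `s̄ = e^{−w}`.

## The Ψ builders

Ψ(w) is the infectiousness-weighted mass of no-longer-susceptibles at
cumulative force *w*; Ψ′ is always constructed analytically alongside it,
never by runtime differencing, because the standard form evaluates Ψ′
inside the ODE right-hand side where differencing noise would contaminate
trajectories.  Four builders:

* homogeneous: `Ψ(w) = N(1 − e^{−w})`;
* finite types: `Ψ(w) = N Σₖ wₖ cₖ (1 − e^{−aₖ w})`;
* Gamma susceptibility (a(x) = x, mean 1, variance 1/p): closed forms via
  the Gamma Laplace transform `Φ̂(λ) = (λ/p + 1)^{−p}`, namely
  `Ψ = N[1 − (w/p + 1)^{−p}]` for constant infectiousness and
  `N[1 − (w/p + 1)^{−p−1}]` for infectiousness proportional to the trait.
  Only these two c-modes have closed forms here; other polynomial c maps
  route through the quadrature builder;
* generic quadrature for arbitrary continuous traits.

**Quadrature choice.**  The continuous-trait integrals use fixed
tanh–sinh (double-exponential) nodes — 240 by default, a config knob —
on (0, 1), with an infinite right endpoint mapped by `x = lo + t/(1−t)`.
Gauss–Legendre on the same map was rejected: the Gamma density carries an
`x^{p−1}` endpoint singularity for p < 1, and GL-200 only reaches ~1e−3
on the unit-mass self-check at p = 0.5, while tanh–sinh reaches ~5e−9
there and machine precision on Ψ itself for p ∈ {0.5, 1, 2, 5}.  The
builder refuses to proceed if the node set cannot reproduce ∫Φ = 1 to
1e−8.  Fixed nodes keep Ψ fully deterministic.

## Seeding a finite-time run

The renewal equation lives on (−∞, t]; a finite-time computation needs a
convention for mapping an initial condition onto that history.  The
package's convention ("eigen" mode) places the system on the exponential
ansatz of the linearised outbreak: with *r* the Euler–Lotka root,

    Q(0) = Ψ′(0) · w₀ · (rI − Σ)⁻¹ V,      w(t) = w₀ e^{rt}  (t ≤ 0),

which satisfies `U Q(0) = w₀` *exactly* because r solves the Euler–Lotka
equation, and `Y(0) = r Q(0)` (the time derivative of the ansatz, keeping
Q = ∫Y consistent at t = 0).  This is the unique initialisation
consistent with both the ODE and the renewal-equation history, which is
what makes the oracle comparisons well posed.  It requires R₀ > 1;
subcritical or off-manifold studies use explicit (Q₀, Y₀) seeds, for
which the monotonicity of w is no longer guaranteed (a warning, not an
error).  w₀ defaults to 1e−6 and should be ≪ 1 (warned above 0.01): the
ansatz is a linearisation, and the residual inconsistency it leaves
between the forms is O(w₀).

## The ODE forms

The integrated form `dQ/dt = ΣQ + VΨ(UQ)` serves homogeneous and
heterogeneous models identically — heterogeneity enters only through Ψ.
The standard form is integrated in the state `(w, Y, Q)` with
`dw/dt = UY`, `dY/dt = ΣY + (UY)Ψ′(w)V`, `dQ/dt = Y`; this is the same
dynamical system as the textbook `(s̄, Y)` form (with `s̄ = e^{−w}` and,
homogeneously, `Ψ′(w) = N s̄` so the infection term is the familiar
`F·S`), but w is monotone and never underflows, so no log-space switching
is needed.  The Gamma-trait system can also be run directly in
`(s_tot, Y)` variables: `ds_tot/dt = −F̄ s_tot^{1+1/p}` with input weight
`H(s) = N s^{1+1/p}` (constant c) or `N(1+1/p)s^{1+2/p}` (proportional
c); `w = p(s_tot^{−1/p} − 1)` recovers the reference-trait force.

Integration uses SciPy's LSODA (stiff-capable; quarantine rates can far
exceed recovery rates) at rtol 1e−9 and atol 1e−12·N by default, output
on a uniform grid (2001 points by default).  Observables: `w`,
`s̄ = e^{−w}`, `s_tot = ∫ s̄^{a(ξ)} Φ(dξ)`, `S = N·s_tot`, and incidence
`−dS/dt = N (∫ a e^{−aw} dΦ) dw/dt` computed from the same analytic
trait integrals.

A practical accuracy note: over the exponential growth phase local solver
errors accumulate, so at the default rtol 1e−9 two equivalent forms of
the same model agree to roughly 3e−7 (scalar) to ~1.5e−6 (multitype) in
sup-norm of w.  The equivalence tests that assert 1e−6 therefore run at
rtol 1e−10; the default stays at 1e−9 because that accuracy is ample for
modelling work and noticeably cheaper.

## The renewal-equation oracle

`solve_re` discretises the convolution with the trapezoidal rule on a
uniform τ/t grid and marches forward, resolving the implicit
`Ψ(w(t_k))` term (weight `(h/2)b(0)`) by fixed-point iteration to 1e−12;
the iteration is a contraction when `(h/2)·b(0)·Ψ′(0) < 1`, checked up
front with automatic step halving (at most 5 times).  The kernel is
truncated where its *exact* tail integral `−U e^{τΣ} Σ⁻¹ V` falls below
`tail_tol` (default 1e−10; the bisection targets half that for margin)
and tabulated once per run by repeated multiplication with `e^{hΣ}`.
The scheme is second order: halving h shrinks the discrepancy against
the ODE reduction by ≈ 4× (observed 4.4 on the SIR benchmark, 1.1e−5
relative at h = 0.01 over [0, 200]).  The solver never imports from the
dynamics module — independence is the point, and a test enforces it.
Kernels with Dirac atoms and adaptive-in-τ quadrature are not supported.

## Epidemic indices

With `B = −UΣ⁻¹V` (computed by linear solve, never an explicit inverse):

* `R₀ = B·Ψ′(0)`.  The classical formula is the homogeneous special case
  Ψ′(0) = N.  For heterogeneous models this definition is the natural
  linearisation-based extension — the unique one under which the
  Euler–Lotka equation (with N replaced by Ψ′(0)) has root 0 exactly at
  R₀ = 1 — and is documented as such rather than as a transcribed
  result.
* growth rate: the unique real root of `Ψ′(0)·U(λI − Σ)⁻¹V = 1` above
  the spectral abscissa of Σ, where the left side is strictly
  decreasing; bracketed then solved by Brent to residual < 1e−12.
* generation time `T = −(UΣ⁻²V)/(UΣ⁻¹V)`, two linear solves; equals the
  kernel's normalised first moment ∫τb/∫b.
* final size: the positive fixed point of `w = B·Ψ(w)` (bisection
  bracket doubled until sign change, Brent to 1e−12); attack rate
  `1 − ∫ e^{−a(ξ)w∞} Φ(dξ)`.  Subcritical models return (0, 0).
* herd-immunity threshold: the depletion level at which the effective
  reproduction number reaches one, i.e. `1 − s_tot(w*)` at the root of
  `B·Ψ′(w*) = 1` (Ψ′ strictly decreasing ⇒ unique).

All one-dimensional root-finding is bracketing-first on monotone
functions; no derivative-free black boxes, so results are deterministic
and residuals are checkable.

## Multitype systems

The two-sex / host–vector structure couples one renewal equation per
type through an arc matrix with zero diagonal; each type carries its own
(V, Σ, U), population size and optional trait model (traits may differ
between the receiving sexes; the contact-symmetry constraint between
sexes is deliberately not enforced, and arbitrary m with a sparse arc
structure is supported although the two-type case is the tested
surface).  The next-generation matrix takes
`K_ij = Ψ_i′(0)·(−U_jΣ_j⁻¹V_j)` on present arcs — receiver-side Ψ′
weighting; the transmitter-side convention gives a diagonally similar
matrix with the same spectral radius, which is what `multitype_r0`
reports (√(K₁₂K₂₁) in the two-type case).  Eigen seeding uses the
leading eigenvector of the block linearisation (the multitype analogue
of the scalar ansatz), scaled so the force on type 1 starts at w₀, and
requires an irreducible arc structure.

## Fixture generator

Tests and the acceptance sweep use randomly generated valid triples:
uniform nonnegative off-diagonal Σ entries with diagonals set so each
column sum is strictly negative (guaranteeing the subgenerator and
eigenvalue conditions), Dirichlet V, positive U — deterministic in the
seed.  Fixture *models* attach N so that R₀ lands on a prescribed target
(1.5–2.5 in the sweeps), optionally with a Gamma (p ∈ {0.5, 1, 2}) or
two-atom discrete trait.  These fixtures probe the algebraic and
numerical machinery, not epidemiological realism: rates are O(1) in
arbitrary time units and compartment topologies are dense.  Passing
tests therefore demonstrate correctness of the reductions and indices
for valid kernels, not calibration to any real pathogen.

## Problem sizes used in checks

The benchmark comparisons run the SIR-class models (n ≤ 4) on [0, 200]
time units: the renewal marches at h = 0.01 and h = 0.005 (τ-grid ≈ 5800
and 11600 nodes after truncation), the ODE comparisons on matched output
grids, index consistency sweeps over 50 random fixtures and slope checks
over 5 simulated fixtures.  These sizes resolve every quantity far below
the tolerances asserted while keeping any single check in seconds.

## Known limitations

* No demographic turnover, waning immunity or endemic states (no
  integrated form exists there).
* Heterogeneity must be separable and static; dynamically varying
  activity is not representable.
* Gamma closed forms cover only c ≡ 1 and c(ξ) = ξ; other infectiousness
  maps fall back to quadrature.
* The renewal solver assumes a smooth, atomless kernel of
  matrix-exponential type (or a user-tabulated b on the grid).
* Eigen seeding needs R₀ > 1 and (multitype) irreducibility; there is no
  canonical finite-time seed for subcritical history-dependent runs.
* No fitting of (V, Σ, U), Φ, a or c to data, and no sensitivity
  analysis of the indices.
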