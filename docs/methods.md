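# Methods

## Model and assumptions

Three infinite, well-mixed populations — ADR manufacturers, third-party
inspection agencies, regulatory authorities — each mix over two pure
strategies under bounded rationality. Payoffs are common knowledge and
additive in the fifteen monetary parameters; there is no discounting,
no finite-population noise, and no memory. Strategy shares evolve by the
standard replicator equation, so each face and edge of the unit cube is
invariant: a strategy absent from the population can never re-enter.

The payoff table is reconstructed to be exactly consistent with the
conditional expected utilities that generate the dynamics (the package's
single source of truth). Two modelling choices embedded in that table:
under strict supervision a high-quality manufacturer does not end up
paying the solicited bribe (the transfer is blocked), and an agency that
accepts bribes under lax supervision still receives its subsidy. The
operating income `Et`, social benefit `Eg` and remediation cost `Gg`
cancel from every payoff difference, so they never affect the dynamics;
they default to 0 in the scenario fixtures but remain settable for payoff
reporting.

## Parameters and scenarios

The three printed scenarios share `Ee=500, Ch=180, Cl=30, Ve=20, Pe=10,
Se=15, Vt=40, Pt=30, St=20, Cr=120` and differ in the bribe and the
credibility loss: A has `K=30, Pg=20`; B raises `K` to 100; C addition-
ally raises `Pg` to 100. A stabilises E1, B stabilises E5, C stabilises
E8, and each is the unique stable corner for its scenario.

Standing-constraint checking uses strict inequalities with tolerance
1e-9. Violations warn in `exploratory` mode and abort in `strict` mode.

## Stability classification

At every corner the Jacobian is diagonal (each off-diagonal entry carries
a factor `x(1-x)`, `y(1-y)` or `z(1-z)`), so corner eigenvalues are the
diagonal entries in closed form; they are reported sorted ascending. A
corner is `stable` when all eigenvalues are below `-tol`, `unstable` when
any exceeds `+tol`, and `marginal` otherwise, with `tol = 1e-9` — the
first-order (Lyapunov indirect) analysis is inconclusive at zero
eigenvalues, so they are flagged rather than forced into a verdict.

Feasibility of the eight corners is decided analytically: at E2, E3, E4,
E6 and E7 one eigenvalue is a parameter combination forced nonnegative by
the standing constraints, so those five can never be stable; E1, E5 and
E8 are feasible by the explicit scenario witnesses. A seeded
rejection-sampling cross-check (10,000 valid parameter sets by default)
verifies that no sampled set contradicts the analytic exclusions.

## Numerical integration

Default integrator: adaptive Runge–Kutta (RK45) with `rtol=1e-8`,
`atol=1e-10`; a classical fixed-step RK4 (`h=0.01`) serves as an
independent cross-check scheme. Default horizon `T=200` with early
stopping once the max-norm of the field drops below `1e-10` (implemented
as a terminal event; the convergence flag allows a 1e-6 relative slack
because the event root lands exactly on the threshold). States are
clipped to `[0,1]^3` after integration; with clipping disabled the
measured excursion under the three scenarios stays below 1e-6, so
clipping only removes floating-point drift. A limit is attributed to a
corner when within 1e-3 in max-norm. Starts exactly on faces or corners
are accepted and stay there; no interior nudging is applied.

The default initial condition is the cube centre (0.5, 0.5, 0.5); the
grid driver uses the uniform interior grid `(i+0.5)/r` per axis. These
are the package's stand-ins for unspecified initial conditions, not a
claim about any particular published figure's starting points.

## Sensitivity sweeps and shape labels

Sweeps substitute one parameter at a time into a base set and integrate
from a common start. Qualitative trajectory shapes are classified from
the signs of successive differences after a centred 3-point moving
average, with differences below 1e-6 treated as flat (solver
micro-oscillations must not flip a label): no sign change gives a
monotone label, a single `-` to `+` change `single_trough`, `+` to `-`
`single_peak`, all-flat `flat`, anything else `other`. A trajectory that
falls and then recovers is thus labelled a trough regardless of how one
might describe the curve informally.

The regulation-cost sweep (Cr in {40, 120, 200} over the scenario-C base)
is reported exactly as computed and no narrative is asserted for the low
end: at `Cr=40` the corner E8 is the locally stable equilibrium (both of
its closed-form conditions hold), but from the cube centre the
low-quality share collapses onto the `x=0` face — which replicator
dynamics cannot leave — and `(y, z)` keep circulating without settling,
so the run legitimately reports no corner. Local stability is not global
reachability.

## Synthetic parameter sampling

Random parameter sets are proposed uniformly per parameter on `[0, 500]`
(a range bracketing every scenario value; the choice of distribution is a
package design decision, as nothing in the model prescribes one) and
rejection-filtered on the standing constraints. Because the constraints
involve only the seven manufacturer-side parameters, that block is
rejection-sampled separately and the free block drawn unconditionally,
which keeps accepted "any"-regime draws exactly uniform on the valid
region. Regime-targeted sampling for E1 adds its predicate to the
rejection filter. For the rare regimes E5 and E8, plain joint rejection
accepts roughly 5e-7 of proposals and is impractical, so the free block
(`Vt, Pt, St, Cr, Pg`, ...) is resampled conditionally on each accepted
constrained block until the corner's stability predicate holds, moving to
the next block when it resists; the result is uniform per parameter but
only approximately uniform over the joint regime region. Sampling is
driven by a single `numpy.random.default_rng(seed)` PCG64 stream per call and is reproducible for a fixed seed; a draw budget (default
1e6 proposals) bounds the work, and exceeding it raises a dedicated
error.

In validation, 50 sampled sets per regime all classify the target corner
stable, and integration from the cube centre reaches that corner in 100%
(E1), 98% (E5) and 94% (E8) of cases — the misses are basin effects of
the kind described above, which is why the recovery check asserts a 90%
floor rather than universality.

## What the scenarios do and do not show

The printed scenarios and sampled parameter sets exercise the model's
full qualitative repertoire (three stable regimes, regime flips under
single-parameter changes, non-corner limiting behaviour), but they are
abstract monetary units: nothing here calibrates the parameters to real
manufacturer accounts, inspection fees or enforcement budgets, and
passing tests say nothing about how actual ADR markets behave. Interior
(mixed-strategy) equilibria are out of scope throughout: the stability
analysis covers only the eight corners, and the dynamics module reports —
but does not classify — convergence to anything else.

## Problem sizes

The default verification runs use 1000 random parameter sets for the
closed-form-vs-enumeration check, 200 for the Jacobian cross-check, a
3x3x3 grid of starts per scenario, and 50 sampled sets per regime for
recovery; these sizes make the whole suite and the reproduction script
run in a few minutes on a single core while keeping every check
statistically meaningful.
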