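# Methods

## Model

A composite process is a CTMC over the product of finite per-subsystem state
spaces, with the generator a sum of mechanism generators.  A mechanism `v`
is declared as a puppet set `P(v)` plus a rate table keyed by (source
configuration over the leader set, target configuration over the puppet
set); the Kronecker-delta structure — coordinates outside `P(v)` never
change in a jump of `v` — is enforced by construction, and the restriction
that rates read only the leader set `L(v) = ⋃_{i∈P(v)} ({i} ∪ pa(i))` is a
hard validation error.  Generator convention: entry `K[x, x']` is the rate
from source `x'` to target `x`; columns sum to zero; `dp/dt = K p`.

Joint states are tuples of labels in declared subsystem order; the
lexicographic order of that enumeration is the total order used by every
"each unordered pair once" sum (currents, information flows).  States
serialize as comma-joined labels.

Rates are primitive: no Hamiltonian or temperature is modelled, `k_B = 1`,
entropies and EP are in nats.  Local detailed balance is the modeller's
responsibility.  Per-mechanism reversibility (positive rate iff the reverse
is positive) *is* enforced at validation, because every EP expression
divides by reverse flows; the EP conventions are `0·ln(0/0) = 0`,
`0·ln(0/a) = 0`, and a positive flow against a zero reverse flow raises an
infinite-EP error naming the transition.

Units are operationalized *structurally*: `ω` is a unit iff every mechanism
has `L(v) ⊆ ω` or `P(v) ∩ ω = ∅`.  This is sufficient for autonomy of the
marginal, and the dynamical statement — the marginal of the full propagation
equals propagation under the unit's own generator — is kept as a test oracle
rather than as the definition.  Unit structures are closed under pairwise
intersection programmatically; empty intersections are excluded from the
family but contribute zero to inclusion–exclusion sums (the convention
forced by the disjoint-unit case, where the in–ex information must reduce to
the mutual information).  The in–ex sum follows the index-tuple formula, so
coinciding intersections are counted per tuple; order invariance is
property-tested.

Dependency inference declares an edge `(j, i)` realized when some mechanism
with `i ∈ P(v)` has rates that change when only the `j`-coordinate of the
source varies.  Rate functions are compared on targets reachable from *all*
sources in a comparison group — "stay put" is not a jump, so a target equal
to some group member's own puppet configuration carries no rate information.
Under this rule a joint-puppet mechanism whose targets track its source
(e.g. a collective flip, or count vectors shifting by a stoichiometric
vector) realizes dependence among its co-puppets; builders therefore declare
those intra-puppet edges.  The declared network must be a superset of the
inferred one (hard error); over-declared edges only warn.

## Numerics

**Propagation** is exact per constant protocol piece (`expm`), with
piecewise-constant periodic protocols as the only supported driving; this
keeps both propagation and Gillespie sampling exact.  Dense linear algebra
throughout: the intended scale is toy models up to a few thousand joint
states (the CRN compiler's default cap of 5 per species gives 6^S states).

**EP quadrature.**  Integrated EP and activity use composite Simpson along
the exactly propagated marginal.  The EP rate of an arbitrary strictly
positive initial distribution has a near-logarithmic opening transient
(entries as small as 1e-12 relax through a boundary layer of their own
width), so the first 10% of the first protocol piece — capped at 50 time
steps — is integrated on a grid uniform in `ln(t − t0)` (257 nodes, inner
offset 1e-8 of the layer width), which resolves the layer at any scale; the
remainder uses a uniform grid with default step `τ/1000`.  Within-piece
node distributions are obtained by eigendecomposition of the generator when
it is cleanly diagonalizable (condition number of the eigenvector matrix
below 1e10 and reconstruction at the first node below 1e-10), with stepped
exponentials as fallback.  The in–ex identity residual — an exact identity,
so a pure measure of numerical error — sits near 1e-8 relative under these
defaults; `integrated_ep(..., check=True)` recomputes at half the step and
errors above 1e-6 relative change.

**Steady states** come from the generator's null space after a strong
connectivity check; reducible generators raise, listing the communicating
classes (e.g. a truncated isomerization network splits into conservation
classes).  The residual `‖Kπ‖∞ ≤ 1e-10` is verified, with one least-squares
polish if needed.

**Sampling.**  Gillespie with per-trajectory child streams spawned from one
root `SeedSequence`, so results are independent of how many paths are
requested.  At a protocol breakpoint the waiting time is re-drawn from the
new rates (exact, by memorylessness).

**Prior minimization** (periodicity bound): the infimum over priors of the
summed per-period mismatch costs is computed by SLSQP on the simplex with
the iterate mixture as a fallback start, and must agree with the
closed-form `N·ΔJS` to 1e-6 — a mandatory cross-check, not an assumption.
The Jensen–Shannon drop is implemented with the orientation that makes it
nonnegative, `ΔJS = [S(E p) − E S(p)] − [S(P E p) − E S(P p)]`, and the
iterate family runs over `t = 0..N−1`, the indexing under which the bound
vanishes at `N = 1` with prior `q = p0`.

**Speed limits and τ***: Pinsker's `g(x) = √(x/2)` is built in; user `g`s
are spot-checked for concavity, monotonicity, and `g(0)=0` on a grid.  A
zero-activity mechanism contributes zero to the mechanism-resolved bound.
The duration bound `τ*` inverts the mechanism-resolved bound with
time-averaged activities numerically (bisection on the monotone bound
function); for a single mechanism with Pinsker `g` this reduces to
`τ* = 2𝕃²/(⟨A⟩ζ)`, used as an algebraic oracle in tests.  The printed form
of the duration bound in the source derivation is garbled, so only this
numeric inversion of the verified mechanism-resolved bound is claimed.

**TURs** are checked in integrated-current form.  The scalar check reports
`σ·Var/(2⟨C⟩²)` with a delta-method standard error (mean and variance
contributions combined); a mean current within 3 SE of zero yields an
*inconclusive* flag rather than a verdict.  The vector TUR uses
`⟨C⟩ᵀΞ⁻¹⟨C⟩ ≤ σ/2` (the rate form printed in the source is dimensionally
ambiguous; the report carries a note), rejects current families whose
covariance condition number exceeds 1e10, and bootstraps its standard error
over paths.  Information-flow TURs freeze the log-ratio weights at the NESS
conditionals of the containing unit, making the path functional a genuine
antisymmetric current; the check is run against every containing unit to
exhibit — not assert — that the smallest unit bounds the precision best.

## Synthetic instances and what they do (not) show

All fixtures are generated programmatically.

- `random_composite_process`: random puppet sets covering all subsystems,
  random dependency edges closed to the fixpoint the dense rate tables
  realize, and strictly positive rates in `[0.2, 1.2]` — reversibility and
  validation hold by construction.  This is the ensemble for partition
  identities, speed-limit chains, and jump-distribution identities.
- `random_overlapping_units_process`: a binary hub A (autonomous) driving
  leaves B, C with flip rates in `[0.3, 1.5]` — the minimal ensemble whose
  unit structure {A, AB, AC} has genuinely overlapping units, used for the
  in–ex decomposition, monotonicity, and autonomy suites.
- `build_nested_periodic(m, n, λC)`: frozen binary hub, two-phase
  piecewise-constant driving of B and C with periods `λB = mλC/n`
  (coprime, `n > m > 2`), rates in `[0.5, 2.0]` per hub state and phase, so
  both period kernels are strictly positive within the frozen-hub blocks.
- `biased_ring(n, forward, backward)`: the classic single-cycle NESS.  The
  steady-state and current examples use bias (2, 1); the TUR significance
  checks use (4, 1), where the finite-time TUR has a genuine ~15% slack —
  at bias (2, 1) the bound is ~4% from saturation, which no affordable
  sample size separates from 1 at 3 SE.
- The toy reaction network and circuit builders fix topology from their
  source illustrations; rate values there are undocumented, so placeholder
  constants (1.0) are used, and the circuit's device–conductor incidence
  beyond "three devices, two free conductors" is an assumption stated in
  the builder's docstring.

These ensembles exercise the *identities and bounds*, which are
parameter-free statements; passing them does not validate any particular
physical parameterization, thermodynamic consistency of rate choices (local
detailed balance is not enforced), or behaviour at scales beyond dense
linear algebra.

Stochastic checks compare simulation to ensemble quantities at 3 standard
errors; where several comparisons run simultaneously (per-state histograms,
per-mechanism counts) the threshold is Bonferroni-adjusted so the family
has the error rate of a single 3-SE check.

## Known limitations

- Continuous driving, time-varying unit structures, tau-leaping, continuous
  state spaces, and trajectory-level (fluctuating) EP estimators are out of
  scope.
- Information flow is evaluated by the same formula off stationarity but
  flagged with a warning: its interpretation here is tied to NESS.
- Kernel embeddability is sidestepped by always building the CTMC first and
  deriving period kernels from its propagator.
- CRN truncation is reflecting (boundary-crossing transition pairs deleted),
  which preserves reversibility but distorts boundary kinetics relative to
  the untruncated network; conservation laws confine dynamics to
  compatibility classes, so global steady states of truncated conservative
  networks are per-class objects.
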