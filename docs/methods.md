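# Methods

## Model and state representation

A chemical reaction network is a list of species with initial
concentrations (nM) and a list of irreversible mass-action reactions with
rate constants (s⁻¹ for first order, (nM s)⁻¹ for second order).  Units are
fixed to nM and seconds throughout; there is no unit-conversion layer.
Reversible reactions are always stored as two irreversible reactions linked
by `reverse_of` — the calibrated signaling networks this package targets
list forward and backward constants separately, and the split makes flux
evaluation uniform and lets GoF mutations remove a single direction.
Species and reactions keep file order with 0-based internal indexing; every
report uses names, never indices.

Constant-pool ("generator") species model inexhaustible synthesis pools:
their row of the stoichiometric matrix is zeroed so their concentration
never changes.  The equivalent formulation — a zeroth-order pseudo-reaction
from the null complex with constant k·[pool] — is available as
`fold_constant_pools`, and the two give identical dynamics; the zero-row
convention is the default because it keeps the pool species addressable by
LoF mutations.

SBML reading covers the subset this model class needs: species with initial
concentration/amount and boundary/constant flags, reactions with integer
stoichiometries, and mass-action kinetic laws whose two (reversible) or one
(irreversible) rate constants are identified from the parameters referenced
by the rate expression, with name-based forward/reverse hints as a
fallback.  Events, assignment rules, and non-mass-action kinetics are
rejected rather than silently approximated.

## Conservation laws

Moiety conservation laws are the nonnegative integer vectors γ with
γᵀS = 0.  The computation is deliberately exact: floating-point rank
decisions can both invent and lose laws on networks with hundreds of
species.  Two stages:

1. The dimension p of the left null space is n − rank(S), with rank
   computed in exact arithmetic (rational elimination for small matrices;
   modular elimination over two distinct 31-bit primes for large ones — the
   two ranks are compared and any disagreement falls back to rational
   elimination).
2. For every species i a small linear program (`scipy.optimize.linprog`,
   HiGHS) searches the polyhedron {γ ≥ 0, Sᵀγ = 0, γ_i ≥ 1} for the law of
   smallest total through that species.  The vertex solution is rationalized
   (denominator limit 10⁶), scaled to coprime integers, and re-verified
   γᵀS = 0 in integer arithmetic; anything that fails verification is
   discarded.  A greedy pass ordered by support size then keeps an
   independent subset of size p.

If fewer than p independent nonnegative generators exist (possible for
networks with unconstrained exchange stoichiometry), the function returns
what it found and raises a warning carrying the exact rational basis — it
never fails silently.  Generators are canonicalized (gcd 1, sorted by
support size then species order) so repeated runs give identical output.
Constant-pool species are excluded: each zero row would otherwise
contribute a trivial singleton law.

Species with zero coefficient in every generator ("uncovered") are exactly
the ones that exchange mass with the environment — degradation targets and
synthesis products — and they are the ones LoF must reach through a
generator pool instead of a conservation law.

## Equilibria

The equilibrium within a compatibility class is the asymptotic value of the
ODE solution.  Solver: BDF with analytic Jacobian, rtol 1e−8, atol 1e−12 nM.
"Asymptotic" is made operational by integrating on geometrically doubling
horizons starting at 10⁵ s (signaling networks of this stiffness settle
between 10⁴ and 10⁷ s) until both the normalized stationarity residual
‖S v‖∞ / max(1, ‖x‖∞) ≤ 1e−9 and the relative state change between
successive horizons ≤ 1e−8, with a hard cap at 10⁹ s.  Failure to meet the
criterion returns `converged=False` rather than a partial answer.  Small
negative undershoots from the integrator are clipped to zero and accounted;
more than n·1e−9 nM of total clipping triggers a warning.  Conservation
drift between the initial state and the equilibrium is reported when laws
are supplied; on all shipped fixtures it stays below 1e−6 relative.

## Mutations

LoF scales the initial concentrations of the protein and of every species
in the support of each containing conservation law by 1−degree.  Degree 1
is a projection onto the subspace where those moiety slots are empty; since
the totals are invariants of the dynamics, the post-equilibrium
concentrations of the whole support remain exactly zero — this is checked
by the test suite rather than assumed.  A protein covered by several laws
has all of them zeroed, with a warning, because partial zeroing would leave
the mutated protein reachable through the remaining moiety.  Partial
degrees interpolate linearly on totals; no other dose–response shape is
offered.

GoF multiplies the rate constants of the listed deactivation reactions by
1−degree.  The removal lists are user input, not inferred: which reactions
constitute "deactivation" of a protein is a biological judgment
(phosphatase binding and catalysis for a kinase, GAP-mediated hydrolysis
for a GTPase) that topology alone cannot make.  At degree 1 this is
equivalent to deleting the corresponding columns of S, so the package
verifies — by exact rank comparison of S with and without those columns —
that the left null space is unchanged.  A failed check means the list would
create a new conservation law (typical causes: including a reverse partner,
or a lone synthesis step) and raises an error naming the set.

Compositions apply all GoF removals to the network and all LoF projections
to the initial state, each sub-list in sorted protein order; because the
two act multiplicatively on disjoint data, the result is bit-identical
under permutation of the input list.  A protein cannot receive both kinds
at once.

## Drugs

A competitive inhibitor adds `target + Drug ⇌ complex` with constants
k1f = 0.5 (nM s)⁻¹ and k1r = 0.005 s⁻¹ by default — fast, nearly
stoichiometric binding; the ratio, not the absolute values, sets the final
profile.  The dose is α·c with c the conserved total of the target's
moiety evaluated at the pre-drug state; an absolute dose in nM is also
accepted.  The drugged network gains exactly one new law (Drug + complex),
which the trajectory tests verify is conserved.  Binding is to the free
target only; complexes containing the target are not drug-accessible.
Washout zeroes the binding constant and adds first-order degradation of
free drug, so the complex drains and the network relaxes back to the
drug-free (mutated) equilibrium; k_deg = 0 leaves free drug standing and is
flagged.

## Effect quantification

δ_i = (x̃ᵢᵉ − xᵢᵉ)/xᵢᵉ.  References below 1e−12 nM make δ undefined
(flagged, never reported as zero): the floor prevents division blow-up on
species that are numerically zero at the reference equilibrium, and
undefined entries count as unaffected in the affected-fraction percentage.
The significance threshold defaults to |δ| > 0.03.

Flux traces decompose a species' derivative into per-reaction signed
contributions (net stoichiometric coefficient times mass-action flux), with
reversible pairs summed into one net trace; the decomposition reproduces
the ODE right-hand side to 1e−6 relative at every sampled time, which is a
test invariant.  The bi-symmetric log transform sign(v)·log10(1 + |v|/C),
default C = 1/ln 10, is provided for displaying δ profiles spanning
[−1, 10⁴].

The titration restoration score counts species whose δ versus the
physiological equilibrium is within the significance threshold, excluding
the drug and its complex.  The contract is the *ranking* of doses, not the
absolute score: the score is an integer-valued, threshold-dependent
summary, and only its argmax over the α grid is meaningful.

## Synthetic fixtures: what they emulate and what they do not

All test networks are generated programmatically; none are stored as data
files.  They reproduce the structural motifs the method relies on:
bimolecular binding/unbinding with closed-form equilibria (`toy_binding`,
root of kf(c₁−x)(c₂−x) = kr·x), first-order toggles (`isomerization`),
Michaelis–Menten-style kinase/phosphatase cycles with explicit
enzyme–substrate complexes (`phospho_cycle`), a four-tier cascade shaped
like the Ras→Raf→MEK→ERK axis (`cascade`), a detailed-balance chain with
rate constants spanning six orders of magnitude for stiffness
(`stiff_chain`), degradation that breaks conservation coverage
(`degradation_chain`), a constant synthesis pool (`generator_pool`), and
seeded random networks assembled from motifs so a prescribed integer
conservation matrix holds by construction (`random_crn`).

Cascade defaults (substrate totals 100 nM, phosphatases 20 nM, upstream
pool 5 nM, activation 0.05 s⁻¹ against deactivation 0.5 s⁻¹, binding
0.01 (nM s)⁻¹, unbinding and catalysis 0.1 s⁻¹) were chosen so the resting
network keeps the cascade mostly inactive while a GoF of the upstream
toggle saturates it — the regime in which an inhibitor dose sweep has an
interior optimum (α = 0.75 with the default drug constants; underdosing
leaves the cascade hyperactive, overdosing suppresses it below the
physiological state).

What passing the fixture suite does **not** show: the fixtures have tens of
species, rate constants within a few orders of magnitude, and a single
stable equilibrium per class by construction.  Real calibrated networks are
an order of magnitude larger, stiffer, and their printed equilibrium values
can depend at the last digit on unreported integration horizons; the
full-network acceptance tests therefore carry 1–2% tolerances and require
the third-party SBML model under `data/`.

## Numerical choices and limitations

* Exact integer arithmetic for all conservation-law statements; no
  floating tolerance anywhere a law is asserted.
* LP vertex rationalization uses a denominator cap of 10⁶; integer
  verification makes a wrong rationalization harmless (the candidate is
  dropped).
* Negative solver undershoots are clipped at 0 with bookkeeping, never
  re-injected.
* Tie-break in the titration argmax: the smallest α among equal scores.
* No multistability or bifurcation analysis: the package assumes (and, on
  its fixtures, verifies) a unique equilibrium per compatibility class.
  No Michaelis–Menten aggregation, no compartments, no SBML events or
  rules, no pharmacokinetics beyond the washout toggle.
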