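# Methods

## Flux balance analysis and viability

All stages work on the steady-state flux polytope {v : S v = 0, a ≤ v ≤ b}.
Bounds are assembled from a single convention: absent reactions are pinned
to zero; irreversible present reactions carry [0, U]; reversible ones
[−U, U]; exchange reactions are oriented so positive flux is secretion
(always open, [0, U]) and negative flux is uptake (lower bound −U only for
metabolites importable in the environment at hand). U = 1000 flux units is
the generic capacity — "unlimited" nutrient supply realised as a large but
finite bound keeps every LP bounded.

A genotype is viable in an environment iff its maximal biomass flux exceeds
ε_viab = 10⁻⁶ (absolute, on the U = 1000 scale). A strict-positivity
criterion needs a tolerance under floating-point LP; 10⁻⁶ sits three orders
of magnitude above solver noise at the tolerances used and six below any
flux a functioning toy pathway carries. Viability over an environment set
is the conjunction over members. The zero vector is always feasible, so a
viability LP can never be infeasible; solver failures raise, they are never
reported as "not viable".

LPs are solved with GLPK through swiglpk. One problem object per analysis
context is kept alive and re-solved with a warm simplex basis after bound
or objective edits; primal and dual feasibility tolerances are set to 10⁻⁹
and recorded in every output manifest. The test suite cross-checks optima
against a dense scipy/HiGHS formulation and an independently assembled
cobra/GLPK model, so results do not hinge on one solver stack.

## Fully coupled sets

Two reactions are fully coupled when the ratio of their fluxes is fixed and
nonzero over the whole polytope. The implementation solves the two ratio
LPs (maximise and minimise v₁ subject to v₂ = 1) and declares coupling when
|R_max − R_min| ≤ 10⁻⁹·max(1, |R_max|) and |R_max| > 10⁻⁹. The zero-ratio
exclusion matters: a pair locked at ratio 0 means one reaction is silent
whenever the other runs, which is not mutual coupling. If v₂ = 1 is
infeasible and the column admits negative flux, the test re-normalises at
v₂ = −1 and negates the resulting ratios, making the test total for
reversible reactions.

Coupling analysis applies three conditions independent of any growth
environment: every exchange is open in both directions; the biomass
reaction is removed and replaced by one independent sink per precursor, so
that a fixed biomass stoichiometry cannot couple otherwise unrelated
biosynthetic routes; and blocked reactions (FVA interval collapsed onto
zero in both directions) are excluded first. Reported FCS members are the
genotype's metabolic reactions: exchange pseudo-reactions and sinks take
part in every LP but are boundary bookkeeping, not network modules, and
counting them would also break the elementary chain law (a k-step pathway
must be one FCS of size k).

Full coupling is an equivalence relation on unblocked reactions, so the
partition is built incrementally: each reaction is LP-tested against one
representative per existing class. Before any LP, a sound witness screen
runs: the optima collected during FVA are feasible points, and any witness
in which one reaction of a pair runs (|v| > 10⁻⁴) while the other is silent
(|v| < 10⁻⁷), or two witnesses with inconsistent ratios, disproves coupling
outright. The screen only ever skips LPs whose outcome is already decided
negatively; positive couplings are always LP-confirmed. An `exhaustive`
mode tests all O(n²) pairs and asserts transitivity on the instance — a
verification tool, not a different algorithm. M = 0 implies s = 0, sets are
disjoint and never singletons; the `FCSPartition` constructor enforces
these invariants on every output.

## MCMC sampling of viable genotypes

The proposal removes one uniformly chosen present swappable reaction and
adds one uniformly chosen absent swappable one; exchange and biomass
reactions are fixed present by default (configuration decides what is
swappable, the generator marks only metabolic reactions). The proposal is
symmetric and acceptance is the 0/1 viability indicator, so the stationary
distribution is uniform on the reachable viable set. Default chain
parameters mirror a full-scale study (burn-in 10⁵ attempted swaps, 10⁶
further swaps, every 1000th genotype saved); all scaled runs set them
explicitly, and the suite verifies uniformity directly against an
exhaustively enumerated viable set. Viability results are memoised by
genotype bit-pattern within a chain — rejected proposals repeat, and FBA
dominates the runtime. One counter-based generator (numpy PCG64) drives
each chain; its seed is stored in the sample's provenance.

Starting genotypes take the union, over required environments, of the
reactions carrying nonzero flux in one biomass-optimal distribution of the
full universe per environment, padded with uniformly chosen swappable
reactions to exactly n. The optimum used is the solver's returned vertex;
the union is viable by construction and padding cannot destroy viability
(monotonicity of the LP optimum in the feasible set), but the builder
retries with fresh padding a capped number of times to absorb degenerate
numerical cases.

Nested environment families follow the replicated-nesting scheme: one
shared chain of nested subsets above a pivot size, independent replicate
subsets at the pivot, and an own nested chain per replicate below it, so
that every smaller set is contained in its parent and replicate-to-
replicate variation is measurable.

## Scope distances

Network expansion iterates A(i) → A(i+1): a reaction fires at iteration
i+1 iff all its substrates lie in A(i), contributing its products.
Reversible reactions are split into two directed half-reactions and fire in
either direction (the firing iteration is the minimum over directions),
following the network-expansion literature. Only metabolic reactions
participate: environments enter through the seed set, so exchange columns
would otherwise trivially inject everything. Autocatalytic cofactor loops
cannot be bootstrapped by pure expansion; the configured cofactor seed
(part of the universe's metadata, declared by the generator for synthetic
universes) is added to every environment's seed. A reaction's scope
distance is the minimum firing iteration over the environment list.
Reactions that never fire carry an explicit "unreached" sentinel — never a
large stand-in number — and are dropped from distance statistics with their
count logged.

## Coherence statistics

Q of an FCS is the fraction of members whose annotation sets contain the
dominant pathway (ties broken lexicographically); unannotated members count
in the denominator but match nothing — the conservative reading. The
h-index of a merged FCS list is sup{x : fraction(Q ≥ x) ≥ x}, computed
exactly at the breakpoints of the cumulative curve as max over distinct q
of min(q, fraction(Q ≥ q)). The randomization test swaps entire annotation
sets between one member of each of two different FCSs with equal
multiplicity in the merged list, preserving per-pathway frequencies, FCS
sizes and multiplicities (asserted after every generated list);
multiplicity classes containing a single distinct FCS are skipped with a
log note. The p-value uses the add-one correction, (1 + exceedances) /
(1 + lists), and therefore never equals zero. Full-scale defaults are 1000
random lists of 10⁷ swaps; scaled analyses state their smaller values
explicitly in the results they report.

## Ensemble aggregation

Consensus sets R_V collect reactions appearing in the FCS partitions of at
least a threshold fraction (default 0.5, inclusive at the boundary) of an
ensemble's genotypes; R_hi \ R_lo isolates reactions responsible for
versatility-driven modules. Scope-distance samples are compared with a
two-sided two-sample Kolmogorov–Smirnov test (exact method when both
samples have ≤ 25 values, asymptotic otherwise) and a Welch t-test with
Satterthwaite degrees of freedom. Raw p-values are reported without
multiple-testing correction, as single planned comparisons. The empirical
percentile test for one observed network against an ensemble uses the same
add-one rank convention. All aggregation is a pure function of stored
samples; re-running it on a saved ensemble is byte-identical.

## The synthetic universe

The generator emulates the statistical structure of a nutrient-centred
reaction database at toy scale. Defaults — the package's standard study —
are 8 nutrients with linear catabolic chains of 3 reactions converging on a
hub metabolite; a 3-reaction biosynthetic core from hub to the first
biomass precursor (consuming ammonia at its last step); 2 redundant
two-reaction alternative routes to the same precursor, which is what gives
one phenotype many genotypes and the sampler something to walk on; a
two-reaction branch to a second precursor; one cofactor-regenerating loop
(a third route, invisible to scope expansion unless the cofactor is
seeded); a two-reaction futile cycle (steady-state flux without scope
reachability); 15 distractor reactions consuming unproducible metabolites
(blocked by construction); and two deep 6-reaction downstream pathways
ending in secreted products, which give the scope-distance distribution the
long tail a genome-scale database has. Every third nutrient chain has a
2:1 stoichiometric step so that non-unit coupling ratios are exercised.
Each element carries its own pathway annotation. Environments share a base
importable set (ammonia) plus one nutrient each, mirroring minimal-medium
design.

The generator returns a ground-truth record — the designed FCS partition of
the full universe (including the degenerate merge of chain and core when a
single nutrient feeds a single consumer route), per-reaction scope
distances, the combinational viability rule, and the blocked set — which
the tests use as an oracle against the LP-based analyses.

What the generator does not emulate: genome-scale size (77 reactions versus
thousands), cofactor ubiquity (real networks thread ATP/NADH through most
reactions), compartments, alternative optimal biomass compositions, and
annotation noise (synthetic modules are perfectly pathway-coherent, so
observed h-indices are 1 and the coherence test is an existence check of
the machinery rather than a calibration). Passing tests therefore show the
algorithms are correct on networks whose modular structure is known, not
that any particular biological network is modular.

## Scaled study sizes

The standard in-silico experiment samples ensembles of 100 genotypes
(burn-in 10³ attempted swaps, chain 10⁴, thinning 10²) at V_env ∈
{1, 2, 4, 8} over three replicate nested families, with genotypes of
n = 52 reactions (12 fixed boundary reactions plus 40 of the 65 swappable
ones). These sizes give standard errors on ⟨M⟩ and ⟨s⟩ far smaller than the
versatility effect while keeping a full run in the tens of seconds; the
uniformity check runs chains of 2·10⁵ attempted swaps against a 55-genotype
enumerated viable set, where expected counts per genotype (~360) make the
chi-square test well calibrated.

## Known limitations

* Full coupling is established by pairwise LPs with a relative tolerance;
  stoichiometries engineered to produce ratio differences below 10⁻⁹ would
  be merged.
* The transitivity shortcut assumes exact arithmetic transitivity of
  coupling; `exhaustive` mode exists to verify it on any instance.
* The MCMC sampler is uniform on the *reachable* component of the viable
  set; disconnected viable sets are sampled within the start's component
  only.
* Scope expansion treats reversibility directionally but ignores
  thermodynamics and stoichiometric yield, as the scope formalism does.
* GLPK warm starts make runs deterministic per platform, but bit-level
  reproducibility across different GLPK versions is not guaranteed.
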