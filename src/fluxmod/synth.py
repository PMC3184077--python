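"""Synthetic reaction universes with known ground truth.

The generator emulates, at toy scale, the statistical structure of a
genome-scale reaction database built around minimal media: every nutrient
gets its own linear catabolic pathway feeding a shared *hub* metabolite; a
core biosynthesis chain (plus redundant alternative routes, so that many
genotypes realise the same phenotype) turns hub carbon into biomass
precursors; optional motifs add a branch to a second precursor, a futile
two-reaction cycle, a cofactor-regenerating loop (which the scope algorithm
cannot bootstrap without seeding the cofactor), deep downstream pathways that
give the scope-distance distribution a long tail, and distractor reactions
that consume unproducible metabolites and are therefore blocked.

Each structural element carries its own pathway annotation, and
:class:`GroundTruth` records the expected FCS partition of the full-universe
genotype, the designed scope distance of every metabolic reaction, and the
combinational viability rule - which is what makes these universes usable as
oracles for the analysis modules.

Stoichiometry is unit except for a doubling step in every third nutrient
pathway, which exercises non-unit coupling ratios.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .fba_engine import FBASolver, is_viable
from .model_core import (
    AnnotationMap,
    Environment,
    Genotype,
    ReactionUniverse,
    ROLE_BIOMASS,
    ROLE_EXCHANGE,
    ROLE_METABOLIC,
)


class SynthConfigError(ValueError):
    """The requested configuration is contradictory."""


class EnumerationBoundError(ValueError):
    """The genotype space is too large for exhaustive enumeration."""


@dataclass(frozen=True)
class SynthConfig:
    """Shape of the generated universe.

    Defaults define the package's standard in-silico study: 8 nutrient
    pathways of length 3, a 3-reaction core with two redundant alternative
    routes, a branch to a second biomass precursor, one cofactor loop, a
    futile cycle, 15 blocked distractors and two deep 6-reaction downstream
    pathways.
    """

    n_nutrients: int = 8
    pathway_length: int = 3
    core_length: int = 3
    n_redundant_routes: int = 2
    n_distractors: int = 15
    n_deep_chains: int = 2
    deep_chain_length: int = 6
    with_branch: bool = True
    with_cycle: bool = True
    n_cofactors: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_nutrients < 1 or self.pathway_length < 1 or self.core_length < 1:
            raise SynthConfigError("need at least one nutrient, chain step and core step")
        for name in ("n_redundant_routes", "n_distractors", "n_deep_chains",
                     "deep_chain_length", "n_cofactors"):
            if getattr(self, name) < 0:
                raise SynthConfigError(f"{name} must be non-negative")
        if self.n_deep_chains > 0 and self.deep_chain_length < 1:
            raise SynthConfigError("deep chains need at least one reaction")


@dataclass
class GroundTruth:
    """Designed truths about a generated universe."""

    fcs_sets: tuple                  # expected FCS partition of the full genotype
    scope_distance: dict             # metabolic reaction -> iteration or None
    chain_for_nutrient: dict         # env label -> frozenset of chain reactions
    required_always: frozenset      # reactions every viable genotype needs
    routes: tuple                    # alternative reaction sets, one must be complete
    module_pathway: dict             # FCS frozenset -> designed pathway label
    cofactor_seed: frozenset
    blocked: frozenset               # reactions blocked in the full universe

    def viable(self, present, env_labels) -> bool:
        present = set(present)
        if not self.required_always <= present:
            return False
        for label in env_labels:
            if not self.chain_for_nutrient[label] <= present:
                return False
        if self.routes and not any(route <= present for route in self.routes):
            return False
        return True


class _Builder:
    def __init__(self):
        self.met_ids, self.met_ext = [], []
        self.rxn_ids, self.role, self.swap, self.rev = [], [], [], []
        self.cols = []
        self._met_index = {}

    def met(self, mid, external=False):
        if mid not in self._met_index:
            self._met_index[mid] = len(self.met_ids)
            self.met_ids.append(mid)
            self.met_ext.append(external)
        return mid

    def rxn(self, rid, stoich, role=ROLE_METABOLIC, swappable=True, reversible=False):
        self.rxn_ids.append(rid)
        self.role.append(role)
        self.swap.append(swappable and role == ROLE_METABOLIC)
        self.rev.append(reversible)
        self.cols.append({self._met_index[m]: float(c) for m, c in stoich.items()})
        return rid

    def build(self) -> ReactionUniverse:
        rows, cols, data = [], [], []
        for j, col in enumerate(self.cols):
            for i, v in col.items():
                rows.append(i)
                cols.append(j)
                data.append(v)
        S = sp.coo_matrix(
            (data, (rows, cols)), shape=(len(self.met_ids), len(self.rxn_ids))
        ).tocsc()
        universe = ReactionUniverse(
            metabolite_ids=self.met_ids,
            external=np.array(self.met_ext, dtype=bool),
            reaction_ids=self.rxn_ids,
            S=S,
            reversible=np.array(self.rev, dtype=bool),
            role=self.role,
            swappable=np.array(self.swap, dtype=bool),
        )
        universe.validate()
        return universe


def generate(config: SynthConfig):
    """Build (universe, annotations, environments, ground_truth) from a config."""
    rng = np.random.default_rng(config.seed)
    b = _Builder()
    L, cl = config.pathway_length, config.core_length
    annotations: dict[str, set] = {}
    fcs_sets, module_pathway = [], {}
    scope_dist: dict[str, int | None] = {}
    blocked: set[str] = set()

    def annotate(rid, label):
        annotations.setdefault(rid, set()).add(label)

    b.met("nh3_ext", external=True)
    b.rxn("EX_nh3", {"nh3_ext": -1}, role=ROLE_EXCHANGE, swappable=False)
    b.met("hub")

    # nutrient-specific catabolic chains
    environments, chain_for_nutrient = [], {}
    for k in range(1, config.n_nutrients + 1):
        label = f"catabolism-nut{k}"
        ext = b.met(f"nut{k}_ext", external=True)
        b.rxn(f"EX_nut{k}", {ext: -1}, role=ROLE_EXCHANGE, swappable=False)
        chain = []
        prev = ext
        for i in range(1, L + 1):
            nxt = "hub" if i == L else b.met(f"nut{k}_m{i}")
            coef_out = 2.0 if (k % 3 == 0 and i == 2 and L >= 3) else 1.0
            rid = b.rxn(f"R_nut{k}_{i}", {prev: -1, nxt: coef_out})
            annotate(rid, label)
            scope_dist[rid] = i
            chain.append(rid)
            prev = nxt
        if len(chain) >= 2:
            fcs_sets.append(frozenset(chain))
            module_pathway[frozenset(chain)] = label
        environments.append(
            Environment(label=f"nut{k}", importable=frozenset({ext, "nh3_ext"}))
        )
        chain_for_nutrient[f"nut{k}"] = frozenset(chain)

    # shared biosynthetic core: hub -> ... -> bm1 (consumes ammonia at the end)
    b.met("bm1")
    core = []
    prev = "hub"
    for i in range(1, cl + 1):
        last = i == cl
        nxt = "bm1" if last else b.met(f"core_m{i}")
        stoich = {prev: -1, nxt: 1}
        if last:
            stoich["nh3_ext"] = -1
        rid = b.rxn(f"R_core_{i}", stoich)
        annotate(rid, "core-biosynthesis")
        scope_dist[rid] = L + i
        core.append(rid)
        prev = nxt
    if len(core) >= 2:
        fcs_sets.append(frozenset(core))
        module_pathway[frozenset(core)] = "core-biosynthesis"
    routes = [frozenset(core)]

    # redundant alternative routes into bm1
    for r in range(1, config.n_redundant_routes + 1):
        mid = b.met(f"alt{r}_m")
        r1 = b.rxn(f"R_alt{r}_1", {"hub": -1, mid: 1})
        r2 = b.rxn(f"R_alt{r}_2", {mid: -1, "nh3_ext": -1, "bm1": 1})
        for rid in (r1, r2):
            annotate(rid, f"alternate-route-{r}")
        scope_dist[r1] = L + 1
        scope_dist[r2] = L + 2
        route = frozenset({r1, r2})
        fcs_sets.append(route)
        module_pathway[route] = f"alternate-route-{r}"
        routes.append(route)

    # cofactor-dependent routes: unusable by scope expansion unless seeded
    cofactor_seed = set()
    for c in range(1, config.n_cofactors + 1):
        cof, cofp = b.met(f"cof{c}"), b.met(f"cof{c}_p")
        mid = b.met(f"cof{c}_m")
        r1 = b.rxn(f"R_cof{c}_1", {"hub": -1, cof: -1, mid: 1, cofp: 1})
        r2 = b.rxn(f"R_cof{c}_2", {mid: -1, "bm1": 1})
        r3 = b.rxn(f"R_cof{c}_3", {cofp: -1, cof: 1})
        for rid in (r1, r2, r3):
            annotate(rid, f"cofactor-route-{c}")
        scope_dist[r1] = L + 1
        scope_dist[r2] = L + 2
        scope_dist[r3] = L + 2
        loop = frozenset({r1, r2, r3})
        fcs_sets.append(loop)
        module_pathway[loop] = f"cofactor-route-{c}"
        routes.append(loop)
        cofactor_seed.add(cof)

    # branch to the second biomass precursor
    precursors = {"bm1": 1.0}
    if config.with_branch:
        b.met("br_m1")
        b.met("bm2")
        r1 = b.rxn("R_branch_1", {"hub": -1, "br_m1": 1})
        r2 = b.rxn("R_branch_2", {"br_m1": -1, "bm2": 1})
        for rid in (r1, r2):
            annotate(rid, "branch-biosynthesis")
        scope_dist[r1] = L + 1
        scope_dist[r2] = L + 2
        branch = frozenset({r1, r2})
        fcs_sets.append(branch)
        module_pathway[branch] = "branch-biosynthesis"
        precursors["bm2"] = 1.0
        required_always = branch
    else:
        required_always = frozenset()

    # shortest route to bm1 determines where downstream pathways start
    route_lengths = [cl]
    if config.n_redundant_routes or config.n_cofactors:
        route_lengths.append(2)
    bm1_iter = L + min(route_lengths)

    # deep downstream pathways ending in a secreted product (scope background)
    for d in range(1, config.n_deep_chains + 1):
        label = f"deep-pathway-{d}"
        chain = []
        prev = "bm1"
        for i in range(1, config.deep_chain_length + 1):
            if i == config.deep_chain_length:
                nxt = b.met(f"deep{d}_end_ext", external=True)
            else:
                nxt = b.met(f"deep{d}_m{i}")
            rid = b.rxn(f"R_deep{d}_{i}", {prev: -1, nxt: 1})
            annotate(rid, label)
            scope_dist[rid] = bm1_iter + i
            chain.append(rid)
            prev = nxt
        b.rxn(f"EX_deep{d}", {f"deep{d}_end_ext": -1},
              role=ROLE_EXCHANGE, swappable=False)
        if len(chain) >= 2:
            fcs_sets.append(frozenset(chain))
            module_pathway[frozenset(chain)] = label

    # futile cycle: carries steady-state flux yet unreachable by expansion
    if config.with_cycle:
        b.met("cyc_a")
        b.met("cyc_b")
        r1 = b.rxn("R_cyc_1", {"cyc_a": -1, "cyc_b": 1})
        r2 = b.rxn("R_cyc_2", {"cyc_b": -1, "cyc_a": 1})
        for rid in (r1, r2):
            annotate(rid, "futile-cycle")
            scope_dist[rid] = None
        cycle = frozenset({r1, r2})
        fcs_sets.append(cycle)
        module_pathway[cycle] = "futile-cycle"

    # distractors: consume a metabolite nothing produces, hence blocked
    for i in range(1, config.n_distractors + 1):
        a, c = b.met(f"dis{i}_a"), b.met(f"dis{i}_b")
        rid = b.rxn(f"R_dis{i}", {a: -1, c: 1})
        annotate(rid, f"misc-{int(rng.integers(3))}")
        scope_dist[rid] = None
        blocked.add(rid)

    # biomass demand over all precursors
    b.rxn("BIOMASS", {m: -c for m, c in precursors.items()},
          role=ROLE_BIOMASS, swappable=False)

    # degenerate merge: with a single nutrient chain and a single hub
    # consumer, the hub has one producer and one consumer, so the chain and
    # the core are one fully coupled set
    hub_consumers = 1 + config.n_redundant_routes + config.n_cofactors \
        + (1 if config.with_branch else 0)
    if config.n_nutrients == 1 and hub_consumers == 1:
        chain = chain_for_nutrient["nut1"]
        merged = chain | frozenset(core)
        fcs_sets = [s for s in fcs_sets
                    if s != chain and s != frozenset(core)] + [merged]
        module_pathway.pop(chain, None)
        module_pathway.pop(frozenset(core), None)

    universe = b.build()
    truth = GroundTruth(
        fcs_sets=tuple(fcs_sets),
        scope_distance=scope_dist,
        chain_for_nutrient=chain_for_nutrient,
        required_always=required_always,
        routes=tuple(routes),
        module_pathway=module_pathway,
        cofactor_seed=frozenset(cofactor_seed),
        blocked=frozenset(blocked),
    )
    return universe, AnnotationMap(annotations), environments, truth


def linear_chain_universe(k: int, reversible: bool = False):
    """A single irreversible pathway of k metabolic reactions plus boundary plumbing."""
    if k < 1:
        raise SynthConfigError("chain needs at least one reaction")
    b = _Builder()
    b.met("A_ext", external=True)
    b.rxn("EX_A", {"A_ext": -1}, role=ROLE_EXCHANGE, swappable=False)
    prev = "A_ext"
    for i in range(1, k + 1):
        nxt = b.met("p" if i == k else f"m{i}")
        b.rxn(f"R{i}", {prev: -1, nxt: 1}, reversible=reversible)
        prev = nxt
    b.rxn("BIOMASS", {"p": -1}, role=ROLE_BIOMASS, swappable=False)
    return b.build()


def random_toy_universe(rng, n_reactions: int = 8, n_internal: int = 5,
                        n_external: int = 2, all_reversible: bool = False,
                        reversible_prob: float = 0.4):
    """A random small universe for oracle cross-checks.

    The biomass precursor is an external metabolite with its own exchange, so
    boundary convention choices cannot induce spurious couplings in
    all-reversible instances.
    """
    b = _Builder()
    externals = [b.met(f"x{i}_ext", external=True) for i in range(max(2, n_external))]
    internals = [b.met(f"m{i}") for i in range(max(2, n_internal))]
    for ext in externals:
        b.rxn(f"EX_{ext}", {ext: -1}, role=ROLE_EXCHANGE, swappable=False)
    pool = externals + internals
    for j in range(n_reactions):
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        mets = list(rng.choice(len(pool), size=min(n_sub + n_prod, len(pool)),
                               replace=False))
        subs, prods = mets[:n_sub], mets[n_sub:]
        if not prods:
            prods = [mets[-1]]
            subs = mets[:-1] or mets[:1]
        stoich = {}
        for i in subs:
            stoich[pool[i]] = -float(rng.choice([1, 1, 1, 2]))
        for i in prods:
            stoich[pool[i]] = stoich.get(pool[i], 0) + float(rng.choice([1, 1, 1, 2]))
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich or all(c > 0 for c in stoich.values()) \
                or all(c < 0 for c in stoich.values()):
            stoich = {pool[subs[0]]: -1.0, externals[0]: 1.0}
        rev = all_reversible or bool(rng.random() < reversible_prob)
        b.rxn(f"R{j}", stoich, reversible=rev)
    b.rxn("BIOMASS", {externals[0]: -1}, role=ROLE_BIOMASS, swappable=False)
    return b.build()


def enumerate_viable_genotypes(universe: ReactionUniverse, n: int, environments,
                               max_swappable: int = 25):
    """All viable genotypes with exactly n reactions, by exhaustive FBA testing."""
    swappable = np.nonzero(universe.swappable)[0]
    if len(swappable) > max_swappable:
        raise EnumerationBoundError(
            f"{len(swappable)} swappable reactions exceed the bound {max_swappable}"
        )
    n_fixed = int((~universe.swappable).sum())
    k = n - n_fixed
    if k < 0 or k > len(swappable):
        raise EnumerationBoundError(f"no genotype with n={n} exists")
    solver = FBASolver(universe)
    fixed = universe.fixed_pattern()
    viable = []
    for combo in itertools.combinations(range(len(swappable)), k):
        bits = fixed.copy()
        bits[swappable[list(combo)]] = True
        genotype = Genotype(bits)
        if is_viable(universe, genotype, environments, solver=solver):
            viable.append(genotype)
    return viable
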