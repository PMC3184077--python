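"""Independent oracles used to cross-check the package's implementations.

Everything here is deliberately built from first principles on a different
code path (dense matrices, scipy's HiGHS solver, the cobra modelling layer,
linear algebra, exhaustive scans) from the GLPK-based implementations it
checks.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from scipy.optimize import linprog

from fluxmod.model_core import ROLE_BIOMASS, ROLE_EXCHANGE, ROLE_METABOLIC

U = 1000.0


# ---------------------------------------------------------------------------
# dense-LP FBA oracle (scipy HiGHS)
# ---------------------------------------------------------------------------
def dense_bounds(universe, genotype, environment):
    n = universe.n_reactions
    lb, ub = np.zeros(n), np.zeros(n)
    for j in range(n):
        if not genotype.bits[j]:
            continue
        role = universe.role[j]
        if role == ROLE_EXCHANGE:
            ub[j] = U
            met = universe.exchanged_metabolite(j)
            if environment is not None and met in environment.importable:
                lb[j] = -U
        else:
            ub[j] = U
            if universe.reversible[j]:
                lb[j] = -U
    return lb, ub


def oracle_max_biomass(universe, genotype, environment) -> float:
    """Biomass maximum via a dense formulation solved with scipy/HiGHS."""
    S = universe.S.toarray()
    lb, ub = dense_bounds(universe, genotype, environment)
    c = np.zeros(universe.n_reactions)
    c[universe.biomass_index] = -1.0  # linprog minimises
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    assert res.status == 0, f"oracle LP failed: {res.message}"
    return -res.fun


def cobra_max_biomass(universe, genotype, environment) -> float:
    """Biomass maximum via an independently assembled cobra/GLPK model."""
    import cobra

    model = cobra.Model("oracle")
    mets = {mid: cobra.Metabolite(mid) for mid in universe.metabolite_ids}
    lb, ub = dense_bounds(universe, genotype, environment)
    reactions = []
    for j, rid in enumerate(universe.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound, rxn.upper_bound = lb[j], ub[j]
        col = universe.S.getcol(j).tocoo()
        rxn.add_metabolites({
            mets[universe.metabolite_ids[int(i)]]: float(v)
            for i, v in zip(col.row, col.data)
        })
        reactions.append(rxn)
    model.add_reactions(reactions)
    model.objective = universe.reaction_ids[universe.biomass_index]
    sol = model.optimize()
    assert sol.status == "optimal"
    return float(sol.objective_value)


# ---------------------------------------------------------------------------
# analysis-condition helpers shared by the coupling oracles
# ---------------------------------------------------------------------------
def analysis_matrix(universe, genotype):
    """Dense analysis system: present reactions minus biomass, plus sinks.

    Returns (A, lb, ub, ids, metabolic_mask); mirrors the coupling analysis
    conditions (open exchanges, per-precursor sinks) on an independent path.
    """
    bj = universe.biomass_index
    cols, lb, ub, ids, metabolic = [], [], [], [], []
    for j in genotype.present_indices():
        if j == bj:
            continue
        cols.append(universe.S.getcol(j).toarray().ravel())
        if universe.role[j] == ROLE_EXCHANGE:
            lb.append(-U)
        else:
            lb.append(-U if universe.reversible[j] else 0.0)
        ub.append(U)
        ids.append(universe.reaction_ids[j])
        metabolic.append(universe.role[j] == ROLE_METABOLIC)
    for met in sorted(universe.biomass_precursors):
        col = np.zeros(universe.n_metabolites)
        col[universe.metabolite_index[met]] = -1.0
        cols.append(col)
        lb.append(0.0)
        ub.append(U)
        ids.append(f"__sink__{met}")
        metabolic.append(False)
    return (np.column_stack(cols), np.array(lb), np.array(ub), ids,
            np.array(metabolic, dtype=bool))


def _classes_to_partition(ids, metabolic, classes):
    sets = set()
    for cls in classes:
        members = frozenset(ids[k] for k in cls if metabolic[k])
        if len(members) >= 2:
            sets.add(members)
    return sets


def _union_find_classes(nodes, coupled):
    parent = {a: a for a in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in nodes:
        for b in nodes:
            if a < b and coupled(a, b):
                parent[find(a)] = find(b)
    classes: dict = {}
    for a in nodes:
        classes.setdefault(find(a), []).append(a)
    return list(classes.values())


# ---------------------------------------------------------------------------
# null-space proportionality oracle (all-reversible instances)
# ---------------------------------------------------------------------------
def nullspace_partition(universe, genotype, tol=1e-8):
    """FCS partition of an all-reversible genotype from null-space row proportionality."""
    A, lb, ub, ids, metabolic = analysis_matrix(universe, genotype)
    K = scipy.linalg.null_space(A)
    if K.size == 0:
        return set()
    norms = np.linalg.norm(K, axis=1)
    unblocked = [k for k in range(len(ids)) if metabolic[k] and norms[k] > tol]

    def coupled(a, b):
        cos = abs(float(K[a] @ K[b]))
        return cos >= (1 - 1e-10) * norms[a] * norms[b]

    return _classes_to_partition(ids, metabolic,
                                 _union_find_classes(unblocked, coupled))


# ---------------------------------------------------------------------------
# Monte-Carlo flux-ratio oracle (general instances)
# ---------------------------------------------------------------------------
def montecarlo_partition(universe, genotype, rng, n_vertices=40, n_samples=10_000,
                         on_tol=1e-5, ratio_tol=1e-6):
    """Cluster reactions whose flux ratios have zero empirical variance across
    >= n_samples random feasible flux vectors (vertices + convex mixtures)."""
    A, lb, ub, ids, metabolic = analysis_matrix(universe, genotype)
    k = A.shape[1]
    vertices = []
    objectives = [rng.standard_normal(k) for _ in range(n_vertices)]
    # per-column extreme points guarantee every unblocked reaction is active
    # in at least one sampled vertex
    for j in range(k):
        for sign in (+1.0, -1.0):
            c = np.zeros(k)
            c[j] = sign
            objectives.append(c)
    for c in objectives:
        res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]),
                      bounds=list(zip(lb, ub)), method="highs")
        if res.status == 0:
            vertices.append(res.x)
    V = np.array(vertices)
    weights = rng.dirichlet(np.ones(len(V)), size=n_samples)
    samples = np.vstack([V, weights @ V])
    maxabs = np.abs(samples).max(axis=0)
    unblocked = [j for j in range(k) if metabolic[j] and maxabs[j] > on_tol]

    def coupled(a, b):
        va, vb = samples[:, a], samples[:, b]
        on_a, on_b = np.abs(va) > on_tol, np.abs(vb) > on_tol
        if np.any(on_a != on_b):
            return False
        both = on_a & on_b
        if not np.any(both):
            return False
        ratios = va[both] / vb[both]
        ref = ratios[0]
        return bool(np.all(np.abs(ratios - ref) <= ratio_tol * max(1.0, abs(ref))))

    return _classes_to_partition(ids, metabolic,
                                 _union_find_classes(unblocked, coupled))


# ---------------------------------------------------------------------------
# scope depth oracle for acyclic irreversible networks
# ---------------------------------------------------------------------------
def dag_firing_iterations(universe, seed_metabolites):
    """Firing iteration = 1 + longest substrate dependency depth, by memoised
    recursion over the (acyclic) metabolite dependency graph."""
    seed = frozenset(seed_metabolites)
    produced_by: dict = {m: [] for m in universe.metabolite_ids}
    consumes: dict = {}
    produces: dict = {}
    for j in range(universe.n_reactions):
        if universe.role[j] != ROLE_METABOLIC:
            continue
        rid = universe.reaction_ids[j]
        col = universe.S.getcol(j).tocoo()
        consumes[rid] = [universe.metabolite_ids[int(i)]
                         for i, v in zip(col.row, col.data) if v < 0]
        produces[rid] = [universe.metabolite_ids[int(i)]
                         for i, v in zip(col.row, col.data) if v > 0]
        for met in produces[rid]:
            produced_by[met].append(rid)
    met_depth: dict = {}
    rxn_iter: dict = {}

    def depth(met, stack):
        if met in seed:
            return 0
        if met in met_depth:
            return met_depth[met]
        if met in stack:
            return None  # cycle: unreachable in an acyclic instance anyway
        best = None
        for rid in produced_by[met]:
            it = fire(rid, stack | {met})
            if it is not None and (best is None or it < best):
                best = it
        met_depth[met] = best
        return best

    def fire(rid, stack):
        if rid in rxn_iter:
            return rxn_iter[rid]
        worst = 0
        for met in consumes[rid]:
            d = depth(met, stack)
            if d is None:
                return None
            worst = max(worst, d)
        rxn_iter[rid] = worst + 1
        return rxn_iter[rid]

    out = {}
    for rid in consumes:
        out[rid] = fire(rid, frozenset())
    return out


# ---------------------------------------------------------------------------
# dense scans
# ---------------------------------------------------------------------------
def grid_h_index(q_values, step=1e-4):
    """sup{x : fraction(Q >= x) >= x} by brute-force grid scan."""
    q = np.asarray(list(q_values), dtype=float)
    best = 0.0
    for x in np.arange(0.0, 1.0 + step, step):
        if np.count_nonzero(q >= x) / q.size >= x:
            best = x
    return best


def rank_p_value(values, observed):
    """Add-one upper-tail rank probability by explicit counting."""
    values = sorted(values)
    ge = sum(1 for v in values if v >= observed)
    return (1 + ge) / (1 + len(values))
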