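"""Flux-coupling analysis: pairwise full coupling, FCS partition, indices M and s.

Two reactions are *fully coupled* when the ratio of their steady-state fluxes
is fixed (and nonzero) across the entire flux polytope.  Following the
linear-programming test of Burgard and colleagues, the extreme ratios are

    Rmax = max v1   and   Rmin = min v1     s.t.  S v = 0, a <= v <= b, v2 = 1

and the pair is coupled iff Rmax = Rmin (to within a relative tolerance),
with a locked-at-zero ratio rejected: a zero ratio means reaction 1 is off
whenever reaction 2 runs, which is not mutual coupling.

Analysis conditions (applied inside :func:`fcs_partition` and
:func:`coupling_bounds`):

* every exchange reaction is open for both uptake and secretion, independent
  of any growth environment;
* the biomass reaction is removed and replaced by one independent sink per
  biomass precursor, so couplings are not induced by a fixed biomass
  stoichiometry; sink pseudo-reactions never appear in reported FCSs;
* blocked reactions are excluded before pairwise testing;
* reported FCS members are the genotype's metabolic reactions (exchange
  pseudo-reactions take part in every LP but are not counted as module
  members).

A *fully coupled set* (FCS) is a maximal set of mutually coupled reactions;
full coupling is an equivalence relation on unblocked reactions, so the FCSs
are its equivalence classes of size >= 2 and are pairwise disjoint.  M is the
number of reactions inside FCSs and s the number of FCSs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ._lp import INFEASIBLE, MAX_FLUX_BOUND, OPTIMAL, LinearSystem
from .fba_engine import FLUX_EPS, SolverError
from .model_core import Genotype, ReactionUniverse, ROLE_EXCHANGE, ROLE_METABOLIC

#: relative tolerance for Rmax == Rmin and for the nonzero-ratio requirement
COUPLING_EPS = 1e-9


@dataclass(frozen=True)
class CouplingBounds:
    """Extreme flux ratios v1/v2 under the normalisation |v2| = 1."""

    rmin: float
    rmax: float
    feasible: bool


@dataclass(frozen=True)
class FCSPartition:
    """Disjoint fully coupled sets (each of size >= 2) with indices M and s."""

    sets: tuple          # tuple of frozensets of reaction ids
    M: int
    s: int

    def __post_init__(self):
        seen = set()
        for fcs in self.sets:
            if len(fcs) < 2:
                raise ValueError("FCS partition contains a singleton set")
            if seen & fcs:
                raise ValueError("FCS partition sets overlap")
            seen |= fcs
        if self.M != len(seen) or self.s != len(self.sets):
            raise ValueError("inconsistent modularity indices")

    def member_reactions(self) -> frozenset:
        out = set()
        for fcs in self.sets:
            out |= fcs
        return frozenset(out)


def modularity_indices(partition: FCSPartition):
    """(M, s): reactions inside FCSs, and number of FCSs."""
    return partition.M, partition.s


class AnalysisSystem:
    """The coupling-analysis LP for one genotype: open exchanges, biomass sinks."""

    def __init__(self, universe: ReactionUniverse, genotype: Genotype):
        universe.check_genotype(genotype)
        U = MAX_FLUX_BOUND
        bj = universe.biomass_index
        cols, ids, lb, ub, metabolic = [], [], [], [], []
        for j in genotype.present_indices():
            if j == bj:
                continue
            cols.append(universe.S.getcol(j))
            ids.append(universe.reaction_ids[j])
            if universe.role[j] == ROLE_EXCHANGE:
                lb.append(-U)
                ub.append(U)
            else:
                lb.append(-U if universe.reversible[j] else 0.0)
                ub.append(U)
            metabolic.append(universe.role[j] == ROLE_METABOLIC)
        for met in sorted(universe.biomass_precursors):
            i = universe.metabolite_index[met]
            col = sp.csc_matrix(([-1.0], ([i], [0])),
                                shape=(universe.n_metabolites, 1))
            cols.append(col)
            ids.append(f"__sink__{met}")
            lb.append(0.0)
            ub.append(U)
            metabolic.append(False)
        self.ids = ids
        self.index = {rid: k for k, rid in enumerate(ids)}
        self.lb = np.array(lb)
        self.ub = np.array(ub)
        self.metabolic = np.array(metabolic, dtype=bool)
        self.system = LinearSystem(sp.hstack(cols, format="csc"), self.lb, self.ub, ids=ids)

    # -- flux variability over the analysis polytope --------------------
    def fva(self, eps: float = FLUX_EPS):
        """(mins, maxs, witnesses): per-column flux range plus every optimum found.

        The optimal vertices double as feasible-point witnesses for the
        coupling pre-screen: any feasible vector in which one reaction runs
        while another is silent disproves full coupling of that pair.
        """
        k = len(self.ids)
        mins = np.full(k, np.nan)
        maxs = np.full(k, np.nan)
        witnesses = []
        self.system.set_bounds(self.lb, self.ub)
        for j in range(k):
            for maximize in (True, False):
                self.system.set_objective({j: 1.0}, maximize=maximize)
                status, obj, x = self.system.solve()
                if status != OPTIMAL:
                    continue
                if maximize:
                    maxs[j] = obj
                else:
                    mins[j] = obj
                witnesses.append(x)
        return mins, maxs, witnesses

    def ratio_bounds(self, r1: str, r2: str) -> CouplingBounds:
        """Extreme ratios v_{r1}/v_{r2}, normalising v_{r2} = 1 (or -1 fallback)."""
        j1, j2 = self.index[r1], self.index[r2]
        if j1 == j2:
            raise ValueError("coupling requires two distinct reactions")
        for v2, allowed in ((1.0, self.ub[j2] >= 1.0), (-1.0, self.lb[j2] <= -1.0)):
            if not allowed:
                continue
            self.system.set_bounds(self.lb, self.ub)
            self.system.set_col_bounds(j2, v2, v2)
            self.system.set_objective({j1: 1.0}, maximize=True)
            s_hi, hi, _ = self.system.solve()
            self.system.set_objective({j1: 1.0}, maximize=False)
            s_lo, lo, _ = self.system.solve()
            self.system.set_col_bounds(j2, self.lb[j2], self.ub[j2])
            if s_hi == OPTIMAL and s_lo == OPTIMAL:
                if v2 > 0:
                    return CouplingBounds(rmin=lo, rmax=hi, feasible=True)
                return CouplingBounds(rmin=-hi, rmax=-lo, feasible=True)
            if s_hi not in (OPTIMAL, INFEASIBLE) or s_lo not in (OPTIMAL, INFEASIBLE):
                raise SolverError(f"coupling LP failed for pair ({r1}, {r2})")
        return CouplingBounds(rmin=np.nan, rmax=np.nan, feasible=False)


def coupling_bounds(universe: ReactionUniverse, genotype: Genotype,
                    r1: str, r2: str,
                    system: AnalysisSystem | None = None) -> CouplingBounds:
    system = system or AnalysisSystem(universe, genotype)
    return system.ratio_bounds(r1, r2)


def fully_coupled(bounds: CouplingBounds, eps: float = COUPLING_EPS) -> bool:
    """True iff the ratio is fixed and nonzero: |Rmax - Rmin| small, |Rmax| > eps."""
    if not bounds.feasible:
        return False
    scale = max(1.0, abs(bounds.rmax))
    return abs(bounds.rmax - bounds.rmin) <= eps * scale and abs(bounds.rmax) > eps


def _screen_compatible(V: np.ndarray, i: int, j: int,
                       strong: float = 1e-4, zero: float = 1e-7,
                       rtol: float = 1e-4) -> bool:
    """Cheap disproof of full coupling from feasible-point witnesses.

    ``V`` has one row per witness vector.  A witness with one flux clearly on
    and the other clearly off, or two witnesses with inconsistent ratios,
    rules the pair out; anything ambiguous is left to the LP test.
    """
    vi, vj = V[:, i], V[:, j]
    on_i, on_j = np.abs(vi) > strong, np.abs(vj) > strong
    off_i, off_j = np.abs(vi) < zero, np.abs(vj) < zero
    if np.any(on_i & off_j) or np.any(on_j & off_i):
        return False
    both = on_i & on_j
    if np.sum(both) >= 2:
        ratios = vi[both] / vj[both]
        ref = ratios[np.argmax(np.abs(ratios))]
        if np.any(np.abs(ratios - ref) > rtol * max(1.0, abs(ref))):
            return False
    return True


def fcs_partition(universe: ReactionUniverse, genotype: Genotype,
                  exhaustive: bool = False,
                  eps: float = COUPLING_EPS) -> FCSPartition:
    """Partition a genotype's unblocked metabolic reactions into FCSs.

    Default mode exploits transitivity: each reaction is tested by LP against
    one representative per existing class, after a sound witness-based
    pre-screen discards provably uncoupled candidates.  ``exhaustive=True``
    forces all O(n^2) LP pairs and asserts that coupling is transitive on the
    instance - a verification mode, not a different algorithm.
    """
    system = AnalysisSystem(universe, genotype)
    mins, maxs, witnesses = system.fva()
    unblocked = [
        k for k in range(len(system.ids))
        if system.metabolic[k]
        and not (np.isnan(mins[k]) and np.isnan(maxs[k]))
        and (maxs[k] > FLUX_EPS or mins[k] < -FLUX_EPS)
    ]
    order = sorted(unblocked)  # deterministic: universe column order
    classes: list[list[int]] = []
    if exhaustive:
        coupled = {}
        for a_pos, a in enumerate(order):
            for b in order[a_pos + 1:]:
                b_ = system.ratio_bounds(system.ids[a], system.ids[b])
                coupled[(a, b)] = fully_coupled(b_, eps=eps)
        # connected components of the coupling graph
        for a in order:
            for cls in classes:
                key = (min(cls[0], a), max(cls[0], a))
                if coupled.get(key, False):
                    cls.append(a)
                    break
            else:
                classes.append([a])
        for cls in classes:  # transitivity must hold within every class
            for x_pos, x in enumerate(cls):
                for y in cls[x_pos + 1:]:
                    assert coupled[(min(x, y), max(x, y))], \
                        "full coupling failed to be transitive"
    else:
        V = np.array(witnesses) if witnesses else np.zeros((0, len(system.ids)))
        for a in order:
            joined = False
            for cls in classes:
                rep = cls[0]
                if not _screen_compatible(V, a, rep):
                    continue
                if fully_coupled(system.ratio_bounds(system.ids[a], system.ids[rep]),
                                 eps=eps):
                    cls.append(a)
                    joined = True
                    break
            if not joined:
                classes.append([a])
    sets = tuple(
        frozenset(system.ids[k] for k in cls)
        for cls in classes if len(cls) >= 2
    )
    M = sum(len(fcs) for fcs in sets)
    return FCSPartition(sets=sets, M=M, s=len(sets))
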