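"""Network expansion (scope) and per-reaction scope distances from nutrients.

The scope of a seed set of metabolites is everything the network can build
from it by iterated forward closure: starting from A(0) = seed, a reaction
*fires* at iteration i+1 when all of its substrates are already in A(i), and
its products join A(i+1).  Reversible reactions are split into two directed
half-reactions, firing in either direction counts, and the reaction's firing
iteration is the minimum over the two directions.  The procedure terminates
once no new metabolite appears, after at most m iterations.

A reaction's *scope distance* from the nutrients of a list of environments is
the minimum, over environments, of its firing iteration with seed =
importable metabolites of that environment plus a configured cofactor seed
(the pragmatic fix for autocatalytic cofactor loops, which pure expansion
cannot bootstrap).  Reactions that never fire carry an explicit "unreached"
sentinel (``None``) and are excluded from distance statistics, with their
count reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .model_core import Environment, ReactionUniverse, ROLE_METABOLIC


@dataclass(frozen=True)
class ScopeResult:
    """Final scope, per-reaction firing iteration (fired reactions only)."""

    producible: frozenset
    firing_iteration: dict      # reaction_id -> iteration >= 1
    iterations: int
    considered: frozenset       # reactions the expansion could have fired

    @property
    def unreached(self) -> frozenset:
        return frozenset(r for r in self.considered if r not in self.firing_iteration)

    def distance(self, reaction_id: str):
        return self.firing_iteration.get(reaction_id)


@dataclass(frozen=True)
class ScopeDistanceTable:
    """Per-reaction minimum firing iteration over a list of environments."""

    distances: dict             # reaction_id -> int (reached reactions only)
    considered: frozenset

    @property
    def unreached(self) -> frozenset:
        return frozenset(r for r in self.considered if r not in self.distances)

    def reached_values(self, reactions: Iterable[str] | None = None):
        """Distance sample for statistics; unreached members are dropped."""
        pool = self.considered if reactions is None else reactions
        return [self.distances[r] for r in pool if r in self.distances]


def _directed_forms(universe: ReactionUniverse, j: int):
    col = universe.S.getcol(j).tocoo()
    subs = frozenset(universe.metabolite_ids[int(i)] for i, v in zip(col.row, col.data) if v < 0)
    prods = frozenset(universe.metabolite_ids[int(i)] for i, v in zip(col.row, col.data) if v > 0)
    forms = [(subs, prods)]
    if universe.reversible[j]:
        forms.append((prods, subs))
    return forms


def scope_expand(universe: ReactionUniverse, seed_metabolites) -> ScopeResult:
    """Iterate the expansion to its fixed point.

    Only metabolic reactions participate: exchanges are boundary bookkeeping
    (environments enter through the seed set) and the biomass pseudo-reaction
    has no biochemical products.
    """
    for met in seed_metabolites:
        if met not in universe.metabolite_index:
            raise KeyError(f"seed metabolite {met!r} not in universe")
    directed = {}
    for j in range(universe.n_reactions):
        if universe.role[j] == ROLE_METABOLIC:
            directed[universe.reaction_ids[j]] = _directed_forms(universe, j)
    current = frozenset(seed_metabolites)
    firing: dict[str, int] = {}
    iteration = 0
    while True:
        iteration += 1
        additions = set()
        for rid, forms in directed.items():
            for subs, prods in forms:
                if subs <= current:
                    if rid not in firing:
                        firing[rid] = iteration
                    additions |= prods
        nxt = current | additions
        if nxt == current:
            iteration -= 1  # the closing pass added nothing
            break
        current = nxt
    return ScopeResult(
        producible=current,
        firing_iteration=firing,
        iterations=iteration,
        considered=frozenset(directed),
    )


def scope_distances(universe: ReactionUniverse, environments,
                    cofactor_seed=frozenset()) -> ScopeDistanceTable:
    """Minimum firing iteration over environments, seeding each environment's
    importable metabolites together with the cofactor seed."""
    environments = list(environments)
    if not environments:
        raise ValueError("at least one environment is required")
    distances: dict[str, int] = {}
    considered: frozenset = frozenset()
    for env in environments:
        result = scope_expand(universe, env.importable | frozenset(cofactor_seed))
        considered = result.considered
        for rid, it in result.firing_iteration.items():
            if rid not in distances or it < distances[rid]:
                distances[rid] = it
    return ScopeDistanceTable(distances=distances, considered=considered)
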