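"""Flux balance analysis: biomass maximisation, viability, FVA, blocked reactions.

The steady-state flux polytope of a genotype G in environment E is

    {v : S v = 0,  a(G, E) <= v <= b(G, E)}

with bounds assembled as follows: absent reactions are pinned to zero;
irreversible present reactions carry [0, U]; reversible ones [-U, U];
exchange reactions always allow secretion [0, U] and additionally uptake
(lower bound -U) for metabolites importable in E.  U is the generic flux
capacity (1000), so "unlimited" nutrient supply stays a bounded LP.

A genotype is *viable* in an environment when its maximal biomass flux
exceeds ``VIABILITY_EPS``; viability over a set of environments is the
conjunction over its members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._lp import (
    FAILED,
    INFEASIBLE,
    MAX_FLUX_BOUND,
    OPTIMAL,
    LinearSystem,
)
from .model_core import Environment, Genotype, ReactionUniverse, ROLE_EXCHANGE

#: absolute biomass-flux threshold below which a genotype counts as non-viable
VIABILITY_EPS = 1e-6

#: |flux| below this is treated as zero in FVA / blocked-reaction calls
FLUX_EPS = 1e-6


class SolverError(RuntimeError):
    """The LP back-end failed on a problem that should be solvable."""


@dataclass(frozen=True)
class FluxProblem:
    """Objective and bounds of one FBA linear program over the universe's columns."""

    c: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    maximize: bool = True


@dataclass(frozen=True)
class FluxSolution:
    status: str
    Z: float
    v: np.ndarray | None


def _bound_templates(universe: ReactionUniverse, environment: Environment | None,
                     open_exchanges: bool):
    """Full-universe bound vectors for an environment (genotype applied later)."""
    cache = universe.__dict__.setdefault("_bound_template_cache", {})
    key = (environment, open_exchanges)
    hit = cache.get(key)
    if hit is not None:
        return hit
    U = MAX_FLUX_BOUND
    n = universe.n_reactions
    lb = np.zeros(n)
    ub = np.full(n, U)
    for j in range(n):
        if universe.role[j] == ROLE_EXCHANGE:
            if open_exchanges:
                lb[j] = -U
            elif environment is not None and \
                    universe.exchanged_metabolite(j) in environment.importable:
                lb[j] = -U
        elif universe.reversible[j]:
            lb[j] = -U
    cache[key] = (lb, ub)
    return lb, ub


def _environment_bounds(universe: ReactionUniverse, genotype: Genotype,
                        environment: Environment | None,
                        open_exchanges: bool = False):
    lb_t, ub_t = _bound_templates(universe, environment, open_exchanges)
    present = genotype.bits
    return np.where(present, lb_t, 0.0), np.where(present, ub_t, 0.0)


def build_problem(universe: ReactionUniverse, genotype: Genotype,
                  environment: Environment | None,
                  objective_mode="biomass") -> FluxProblem:
    """Assemble the FBA LP for a genotype in an environment.

    ``objective_mode`` is ``"biomass"`` or ``("single_flux", reaction_id, sign)``.
    """
    universe.check_genotype(genotype)
    lb, ub = _environment_bounds(universe, genotype, environment)
    c = np.zeros(universe.n_reactions)
    if objective_mode == "biomass":
        c[universe.biomass_index] = 1.0
    else:
        mode, rid, sign = objective_mode
        if mode != "single_flux":
            raise ValueError(f"unknown objective mode {objective_mode!r}")
        c[universe.reaction_index[rid]] = float(sign)
    return FluxProblem(c=c, lb=lb, ub=ub, maximize=True)


class FBASolver:
    """Reusable LP context for one universe; cheap to re-solve across genotypes."""

    def __init__(self, universe: ReactionUniverse):
        self.universe = universe
        n = universe.n_reactions
        self._system = LinearSystem(universe.S, np.zeros(n), np.zeros(n),
                                    ids=universe.reaction_ids)

    def solve(self, problem: FluxProblem, extract_vector: bool = True) -> FluxSolution:
        self._system.set_bounds(problem.lb, problem.ub)
        self._system.set_objective(problem.c, maximize=problem.maximize)
        status, obj, x = self._system.solve(extract_vector=extract_vector)
        if status == FAILED:
            raise SolverError("LP solver failed")
        if status != OPTIMAL:
            return FluxSolution(status=status, Z=np.nan, v=None)
        return FluxSolution(status=status, Z=float(obj), v=x)

    def max_biomass_value(self, genotype: Genotype, environment: Environment) -> float:
        """Objective-only biomass maximisation (the viability hot path)."""
        problem = build_problem(self.universe, genotype, environment, "biomass")
        solution = self.solve(problem, extract_vector=False)
        if solution.status == INFEASIBLE:
            raise SolverError("biomass LP reported infeasible although v=0 is feasible")
        return solution.Z


def max_biomass(universe: ReactionUniverse, genotype: Genotype,
                environment: Environment, solver: FBASolver | None = None) -> FluxSolution:
    """Maximal biomass flux of a genotype in one environment.

    The all-zero flux vector is always feasible, so the LP cannot be
    infeasible on valid input; solver failures surface as
    :class:`SolverError`, never as a silent zero.
    """
    solver = solver or FBASolver(universe)
    solution = solver.solve(build_problem(universe, genotype, environment, "biomass"))
    if solution.status == INFEASIBLE:
        raise SolverError("biomass LP reported infeasible although v=0 is feasible")
    return solution


def is_viable(universe: ReactionUniverse, genotype: Genotype,
              environments, solver: FBASolver | None = None,
              eps: float = VIABILITY_EPS) -> bool:
    """True iff maximal biomass flux exceeds ``eps`` in every listed environment."""
    environments = list(environments)
    if not environments:
        raise ValueError("at least one environment is required")
    solver = solver or FBASolver(universe)
    for env in environments:
        if solver.max_biomass_value(genotype, env) <= eps:
            return False
    return True


def flux_variability(universe: ReactionUniverse, genotype: Genotype,
                     open_exchanges: bool = True,
                     environment: Environment | None = None,
                     solver: FBASolver | None = None):
    """Per-present-reaction (min flux, max flux) over the steady-state polytope.

    Returns ``{reaction_id: (vmin, vmax)}``; solver failures on a single
    reaction are recorded as ``(nan, nan)`` rather than aborting the scan.
    """
    universe.check_genotype(genotype)
    solver = solver or FBASolver(universe)
    lb, ub = _environment_bounds(universe, genotype, environment,
                                 open_exchanges=open_exchanges)
    out = {}
    for j in genotype.present_indices():
        rid = universe.reaction_ids[j]
        lo = hi = np.nan
        try:
            c = np.zeros(universe.n_reactions)
            c[j] = 1.0
            sol = solver.solve(FluxProblem(c=c, lb=lb, ub=ub, maximize=True))
            hi = sol.Z
            sol = solver.solve(FluxProblem(c=c, lb=lb, ub=ub, maximize=False))
            lo = sol.Z
        except SolverError:
            pass
        out[rid] = (lo, hi)
    return out


def blocked_reactions(universe: ReactionUniverse, eps: float = FLUX_EPS) -> frozenset:
    """Reactions of the full universe that cannot carry flux in either direction.

    Computed with every exchange open for uptake and secretion; a reaction is
    blocked iff its FVA interval collapses onto zero (max <= eps and
    min >= -eps), which handles reversible reactions correctly.
    """
    ranges = flux_variability(universe, universe.full_genotype(), open_exchanges=True)
    return frozenset(
        rid for rid, (lo, hi) in ranges.items()
        if (np.isnan(lo) or lo >= -eps) and (np.isnan(hi) or hi <= eps)
        and not (np.isnan(lo) and np.isnan(hi))
    )
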