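"""MCMC sampling of viable genotypes at fixed reaction count.

The sampler performs a reaction-swap random walk on the space of genotypes
with exactly n reactions: each proposal removes one uniformly chosen present
swappable reaction and adds one uniformly chosen absent swappable reaction,
so the proposal distribution is symmetric and n is preserved.  A proposal is
accepted iff the new genotype is viable in every required environment
(Metropolis with a 0/1 acceptance indicator), hence the chain's stationary
distribution is uniform on the reachable viable set.

Default chain parameters mirror a full-scale study (burn-in 1e5 attempted
swaps, 1e6 further swaps, every 1000th genotype saved); scaled runs must set
them explicitly.  Viability calls are memoised by genotype key within a
chain, since rejected proposals repeat and FBA dominates the runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _version
from ._lp import FEASIBILITY_TOL, MAX_FLUX_BOUND
from .fba_engine import FBASolver, VIABILITY_EPS, is_viable, max_biomass
from .model_core import Environment, Genotype, ReactionUniverse


class SamplerError(RuntimeError):
    pass


class NoSwappableMoveError(SamplerError):
    """No present/absent swappable pair exists to propose."""


class NonViableStartError(SamplerError):
    """The chain's starting genotype fails the viability phenotype."""


class StartConstructionError(SamplerError):
    """A starting genotype could not be assembled within the retry cap."""


class NestedSetError(SamplerError):
    """The requested nested environment-set sizes are impossible."""


@dataclass(frozen=True)
class EnsembleSpec:
    """Chain configuration; the number of environments is the versatility V_env."""

    environments: tuple
    n: int
    burn_in: int = 100_000
    chain_length: int = 1_000_000
    thinning: int = 1_000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "environments", tuple(self.environments))
        if len(self.environments) < 1:
            raise ValueError("V_env must be at least 1")
        if self.thinning <= 0 or self.chain_length % self.thinning != 0:
            raise ValueError("thinning must divide chain_length")

    @property
    def v_env(self) -> int:
        return len(self.environments)


@dataclass
class EnsembleSample:
    spec: EnsembleSpec
    genotypes: list
    acceptance_count: int
    provenance: dict = field(default_factory=dict)

    @property
    def acceptance_rate(self) -> float:
        total = self.spec.burn_in + self.spec.chain_length
        return self.acceptance_count / total if total else 0.0


def propose_swap(genotype: Genotype, universe: ReactionUniverse, rng) -> Genotype:
    """Swap one present swappable reaction for one absent swappable reaction."""
    swappable = universe.swappable
    present = np.nonzero(genotype.bits & swappable)[0]
    absent = np.nonzero(~genotype.bits & swappable)[0]
    if len(present) == 0 or len(absent) == 0:
        raise NoSwappableMoveError("no swappable present/absent reaction pair")
    out = int(present[rng.integers(len(present))])
    inn = int(absent[rng.integers(len(absent))])
    bits = genotype.bits.copy()
    bits[out] = False
    bits[inn] = True
    return Genotype(bits)


def mcmc_chain(spec: EnsembleSpec, universe: ReactionUniverse,
               start: Genotype) -> EnsembleSample:
    """Run one reaction-swap chain and return the thinned post-burn-in sample."""
    universe.check_genotype(start)
    solver = FBASolver(universe)
    memo: dict[bytes, bool] = {}

    def viable(g: Genotype) -> bool:
        key = g.key()
        hit = memo.get(key)
        if hit is None:
            hit = is_viable(universe, g, spec.environments, solver=solver)
            memo[key] = hit
        return hit

    if not viable(start):
        raise NonViableStartError("starting genotype is not viable in all environments")
    rng = np.random.default_rng(spec.seed)
    current = start
    accepted = 0
    saved = []
    total = spec.burn_in + spec.chain_length
    for step in range(1, total + 1):
        proposal = propose_swap(current, universe, rng)
        if viable(proposal):
            current = proposal
            accepted += 1
        if step > spec.burn_in and (step - spec.burn_in) % spec.thinning == 0:
            saved.append(current)
    return EnsembleSample(
        spec=spec,
        genotypes=saved,
        acceptance_count=accepted,
        provenance={
            "seed": spec.seed,
            "viability_eps": VIABILITY_EPS,
            "flux_bound": MAX_FLUX_BOUND,
            "solver_tolerance": FEASIBILITY_TOL,
            "code_version": _version,
        },
    )


def build_start_genotype(universe: ReactionUniverse, environments, n: int,
                         rng, retries: int = 5) -> Genotype:
    """Assemble a viable genotype of exactly n reactions.

    Starts from the union, over environments, of reactions carrying nonzero
    flux in one biomass-optimal flux distribution of the full universe per
    environment, then pads with uniformly chosen absent swappable reactions.
    The union is viable by construction (each environment's optimum is
    supported on it) and padding cannot destroy viability, but degenerate
    numerical cases are retried with fresh padding up to ``retries`` times.
    """
    environments = list(environments)
    solver = FBASolver(universe)
    full = universe.full_genotype()
    support = universe.fixed_pattern().copy()
    for env in environments:
        sol = max_biomass(universe, full, env, solver=solver)
        if not sol.Z > VIABILITY_EPS:
            raise StartConstructionError(
                f"universe itself is not viable in environment {env.label!r}"
            )
        support |= np.abs(sol.v) > 1e-6
    if int(support.sum()) > n:
        raise StartConstructionError(
            f"nonzero-flux union has {int(support.sum())} reactions, more than n={n}"
        )
    for _ in range(retries):
        bits = support.copy()
        absent = np.nonzero(~bits & universe.swappable)[0]
        need = n - int(bits.sum())
        if need > len(absent):
            raise StartConstructionError("not enough swappable reactions to pad to n")
        if need:
            bits[rng.choice(absent, size=need, replace=False)] = True
        genotype = Genotype(bits)
        if is_viable(universe, genotype, environments, solver=solver):
            return genotype
    raise StartConstructionError("failed to build a viable start within the retry cap")


def build_nested_environment_sets(all_environments, sizes, replicates: int,
                                  pivot_size: int, rng):
    """Replicate-indexed nested environment families.

    A single nested chain is drawn for sizes above ``pivot_size``; at the
    pivot, ``replicates`` independent subsets are drawn from the next-larger
    set, and each replicate then continues as its own nested chain below the
    pivot.  Every smaller set is a subset of its parent.  Returns a list of
    ``replicates`` dicts mapping size -> tuple of environments.
    """
    all_environments = list(all_environments)
    sizes = list(sizes)
    if sorted(sizes, reverse=True) != sizes or len(set(sizes)) != len(sizes):
        raise NestedSetError("sizes must be strictly decreasing")
    if sizes and sizes[0] > len(all_environments):
        raise NestedSetError("largest size exceeds the number of environments")
    if pivot_size not in sizes:
        raise NestedSetError("pivot_size must be one of the sizes")
    if min(sizes) < 1 or replicates < 1:
        raise NestedSetError("sizes and replicates must be positive")

    order = {env.label: i for i, env in enumerate(all_environments)}

    def subset(parent, k):
        idx = rng.choice(len(parent), size=k, replace=False)
        chosen = [parent[i] for i in sorted(idx)]
        return tuple(sorted(chosen, key=lambda e: order[e.label]))

    shared: dict[int, tuple] = {}
    parent = tuple(all_environments)
    for size in sizes:
        if size < pivot_size:
            break
        if size == pivot_size:
            parent_at_pivot = parent
            break
        shared[size] = subset(parent, size)
        parent = shared[size]
    else:
        parent_at_pivot = parent

    below = [s for s in sizes if s <= pivot_size]
    families = []
    for _ in range(replicates):
        family = dict(shared)
        parent = parent_at_pivot
        for size in below:
            family[size] = subset(parent, size)
            parent = family[size]
        families.append(family)
    return families
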