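"""Headline analyses: modularity-versus-versatility curves, ensemble percentile
tests, consensus reaction sets and scope-distance comparisons.

The central experiment samples genotype ensembles at increasing environmental
versatility V_env (the number of minimal environments in which viability is
required), computes the FCS partition of every sampled genotype, and tracks
the ensemble means of the modularity indices M (reactions inside FCSs) and s
(number of FCSs).  Downstream, *consensus sets* R_V collect reactions that
appear in the FCSs of at least a threshold fraction (default one half) of an
ensemble's genotypes; the difference set R_hi \\ R_lo isolates the reactions
responsible for versatility-driven modules, whose scope distances are then
compared against the whole-universe background with two-sample
Kolmogorov-Smirnov and Welch t tests.

All aggregation is a pure function of the stored samples, so re-running it on
a saved ensemble is bit-identical.  Raw p-values are reported; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .flux_coupling import FCSPartition, fcs_partition
from .model_core import ReactionUniverse
from .sampler import EnsembleSample, EnsembleSpec, build_start_genotype, mcmc_chain

logger = logging.getLogger(__name__)


class EmptySampleError(ValueError):
    """A statistic was requested on an empty sample."""


@dataclass(frozen=True)
class ConsensusSet:
    """Reactions inside FCSs of at least ``threshold`` genotypes of an ensemble."""

    threshold: int
    reactions: frozenset


@dataclass(frozen=True)
class PercentileResult:
    percentile: float
    p: float


@dataclass(frozen=True)
class ScopeComparison:
    ks_statistic: float
    ks_p: float
    welch_t: float
    welch_p: float
    n_a: int
    n_b: int


@dataclass
class CurveCell:
    """One (replicate, V_env) ensemble with its per-genotype FCS partitions."""

    replicate: int
    v_env: int
    sample: EnsembleSample
    partitions: list


def versatility_curve(universe: ReactionUniverse, families, n: int,
                      burn_in: int, chain_length: int, thinning: int,
                      seed: int, start_retries: int = 5):
    """Run the M/s-versus-V_env experiment over replicate nested families.

    ``families`` comes from :func:`fluxmod.sampler.build_nested_environment_sets`.
    Returns (curve DataFrame, list of CurveCell).  A failing chain aborts its
    own (replicate, V_env) cell with a logged reason, not the whole run.
    """
    rows, cells = [], []
    root = np.random.SeedSequence(seed)
    n_cells = sum(len(f) for f in families)
    children = iter(root.spawn(n_cells + 1))
    start_rng = np.random.default_rng(next(children))
    for rep, family in enumerate(families):
        for size in sorted(family):
            child = next(children)
            envs = family[size]
            try:
                start = build_start_genotype(universe, envs, n, start_rng,
                                             retries=start_retries)
                spec = EnsembleSpec(
                    environments=envs, n=n, burn_in=burn_in,
                    chain_length=chain_length, thinning=thinning,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                sample = mcmc_chain(spec, universe, start)
                partitions = [fcs_partition(universe, g) for g in sample.genotypes]
            except Exception as exc:  # noqa: BLE001 - per-cell isolation
                logger.warning("cell (replicate=%d, V_env=%d) failed: %s",
                               rep, size, exc)
                continue
            Ms = np.array([p.M for p in partitions], dtype=float)
            ss = np.array([p.s for p in partitions], dtype=float)
            rows.append({
                "replicate": rep,
                "v_env": size,
                "mean_M": float(Ms.mean()),
                "mean_s": float(ss.mean()),
                "sem_M": float(Ms.std(ddof=1) / np.sqrt(len(Ms))) if len(Ms) > 1 else 0.0,
                "sem_s": float(ss.std(ddof=1) / np.sqrt(len(ss))) if len(ss) > 1 else 0.0,
                "ensemble_size": len(partitions),
                "acceptance_rate": sample.acceptance_rate,
            })
            cells.append(CurveCell(replicate=rep, v_env=size, sample=sample,
                                   partitions=partitions))
    curve = pd.DataFrame(
        rows, columns=["replicate", "v_env", "mean_M", "mean_s", "sem_M",
                       "sem_s", "ensemble_size", "acceptance_rate"],
    ).sort_values(["replicate", "v_env"], ignore_index=True)
    return curve, cells


def write_curve(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, sep="\t", index=False, float_format="%.10g")


def empirical_percentile_test(ensemble_values, observed: float) -> PercentileResult:
    """Where an observed value sits in an ensemble's distribution.

    p = (1 + #{ensemble >= observed}) / (1 + size), the add-one upper-tail
    rank probability; the percentile is the fraction of the ensemble strictly
    below the observed value, on a 0-100 scale.
    """
    values = np.asarray(list(ensemble_values), dtype=float)
    if values.size == 0:
        raise EmptySampleError("empty ensemble")
    ge = int(np.count_nonzero(values >= observed))
    p = (1 + ge) / (1 + values.size)
    percentile = 100.0 * np.count_nonzero(values < observed) / values.size
    return PercentileResult(percentile=float(percentile), p=float(p))


def consensus_reactions(partitions, threshold_fraction: float = 0.5) -> ConsensusSet:
    """Reactions appearing in the FCS partitions of >= fraction of genotypes."""
    partitions = list(partitions)
    if not partitions:
        raise EmptySampleError("no partitions")
    counts: dict[str, int] = {}
    for partition in partitions:
        for rid in partition.member_reactions():
            counts[rid] = counts.get(rid, 0) + 1
    threshold = threshold_fraction * len(partitions)
    members = frozenset(r for r, c in counts.items() if c >= threshold - 1e-9)
    return ConsensusSet(threshold=int(np.ceil(threshold - 1e-9)), reactions=members)


def compare_scope_distributions(distances_a, distances_b,
                                exact_limit: int = 25) -> ScopeComparison:
    """Two-sample K-S and Welch t tests on scope-distance samples.

    ``None`` entries (unreached reactions) are dropped with a logged count; a
    sample emptied by that filter is an error.
    """
    def clean(sample, name):
        values = [x for x in sample if x is not None]
        dropped = len(list(sample)) - len(values)
        if dropped:
            logger.info("dropped %d unreached reactions from sample %s", dropped, name)
        if not values:
            raise EmptySampleError(f"sample {name} is empty after unreached filtering")
        return np.asarray(values, dtype=float)

    a = clean(list(distances_a), "a")
    b = clean(list(distances_b), "b")
    method = "exact" if (len(a) <= exact_limit and len(b) <= exact_limit) else "asymp"
    ks = stats.ks_2samp(a, b, method=method)
    welch = stats.ttest_ind(a, b, equal_var=False)
    return ScopeComparison(
        ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue),
        welch_t=float(welch.statistic), welch_p=float(welch.pvalue),
        n_a=len(a), n_b=len(b),
    )
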