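"""Pathway coherence of fully coupled sets: Q, the h-index, and a swap test.

For one FCS, Q is the fraction of its reactions sharing the *dominant*
pathway annotation (the label contained in the annotation sets of the most
members; lexicographic tie-break).  Reactions without any annotation count in
the denominator but match no label - a conservative choice.

Over a merged list of FCSs pooled from an ensemble of genotypes, the h-index
is the largest h such that a fraction h of the FCSs have Q >= h, i.e. the
intersection of the cumulative Q distribution with the bisecting line.

Significance is assessed by an annotation-swap randomization: repeatedly pick
two different FCSs of equal multiplicity in the merged list, one member
reaction in each, and exchange their entire annotation sets.  This preserves
FCS sizes, multiplicities, and the frequency of every annotation in the list
while destroying the within-FCS association; the p-value for the observed
h-index uses the add-one correction, so it is never exactly zero.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .model_core import AnnotationMap

logger = logging.getLogger(__name__)


class EmptyFCSError(ValueError):
    """Q is undefined for an empty reaction set."""


class NoSwapPartnerError(ValueError):
    """No multiplicity class contains two distinct FCSs to swap between."""


@dataclass(frozen=True)
class MergedFCSList:
    """FCS multiset pooled over an ensemble: (reaction set, genotype index) entries."""

    entries: tuple       # tuple of (frozenset, int)
    multiplicity: dict   # canonical frozenset -> number of genotypes containing it

    def __len__(self):
        return len(self.entries)


@dataclass(frozen=True)
class CoherenceResult:
    q_values: tuple
    h: float
    p_value: float
    n_random_lists: int
    n_swaps: int
    random_h: tuple = ()


def merge_partitions(partitions) -> MergedFCSList:
    """Pool the FCSs of an ensemble of genotypes into one merged list."""
    entries = []
    counts: Counter = Counter()
    for g_idx, partition in enumerate(partitions):
        for fcs in partition.sets:
            entries.append((fcs, g_idx))
            counts[fcs] += 1
    return MergedFCSList(entries=tuple(entries), multiplicity=dict(counts))


def _q_from_sets(annotation_sets):
    """Q and dominant label for a list of per-member annotation sets."""
    counts: Counter = Counter()
    for labels in annotation_sets:
        counts.update(labels)
    if not counts:
        return 0.0, None
    best = max(counts.values())
    dominant = min(label for label, c in counts.items() if c == best)
    return best / len(annotation_sets), dominant


def q_statistic(fcs, annotations: AnnotationMap):
    """(Q, dominant pathway) of one FCS under a reaction->pathways annotation map."""
    fcs = frozenset(fcs)
    if not fcs:
        raise EmptyFCSError("cannot compute Q of an empty FCS")
    return _q_from_sets([annotations.get(rid) for rid in sorted(fcs)])


def h_index(q_values) -> float:
    """sup{x in [0,1] : fraction(Q >= x) >= x}.

    The cumulative curve of Q is a step function, so the supremum is attained
    at a breakpoint: h = max over distinct q of min(q, fraction(Q >= q)).
    """
    q_values = np.asarray(list(q_values), dtype=float)
    if q_values.size == 0:
        raise EmptyFCSError("h-index of an empty Q list")
    n = q_values.size
    best = 0.0
    for q in np.unique(q_values):
        frac = np.count_nonzero(q_values >= q) / n
        best = max(best, min(float(q), frac))
    return best


def _randomize_slots(slots, merged: MergedFCSList, eligible, n_swaps: int, rng):
    """Apply ``n_swaps`` annotation-exchange moves to a copy of ``slots``.

    One move picks a multiplicity class, two entries holding different FCSs
    within it, one member slot in each, and exchanges their whole annotation
    sets.
    """
    shuffled = [list(s) for s in slots]
    for _ in range(n_swaps):
        idxs = eligible[rng.integers(len(eligible))] if len(eligible) > 1 else eligible[0]
        while True:
            i = idxs[rng.integers(len(idxs))]
            j = idxs[rng.integers(len(idxs))]
            if merged.entries[i][0] != merged.entries[j][0]:
                break
        a = int(rng.integers(len(shuffled[i])))
        b = int(rng.integers(len(shuffled[j])))
        shuffled[i][a], shuffled[j][b] = shuffled[j][b], shuffled[i][a]
    return shuffled


def annotation_swap_randomization(merged: MergedFCSList, annotations: AnnotationMap,
                                  n_random_lists: int = 1000,
                                  n_swaps: int = 10_000_000,
                                  rng=None) -> CoherenceResult:
    """Randomization test for the h-index of a merged FCS list.

    Defaults mirror a full-scale analysis (1000 random lists, 1e7 swaps per
    list); scaled studies pass smaller values explicitly.
    """
    rng = rng if rng is not None else np.random.default_rng()
    slots = [
        [annotations.get(rid) for rid in sorted(fcs)]
        for fcs, _ in merged.entries
    ]
    observed_q = tuple(_q_from_sets(s)[0] for s in slots)
    observed_h = h_index(observed_q)

    # multiplicity classes usable for swap moves: >= 2 distinct FCSs
    by_mult: dict[int, list[int]] = {}
    for idx, (fcs, _) in enumerate(merged.entries):
        by_mult.setdefault(merged.multiplicity[fcs], []).append(idx)
    eligible = []
    for mult, idxs in sorted(by_mult.items()):
        distinct = {merged.entries[i][0] for i in idxs}
        if len(distinct) >= 2:
            eligible.append(idxs)
        else:
            logger.info("multiplicity class %d has a single FCS; skipped by the "
                        "swap sampler", mult)
    if not eligible:
        raise NoSwapPartnerError("no multiplicity class with two distinct FCSs")

    pooled = Counter()
    for s in slots:
        pooled.update(s)
    random_h = []
    for _ in range(n_random_lists):
        shuffled = _randomize_slots(slots, merged, eligible, n_swaps, rng)
        check = Counter()
        for s in shuffled:
            check.update(s)
        assert check == pooled, "swap moves failed to conserve annotations"
        assert [len(s) for s in shuffled] == [len(s) for s in slots]
        random_h.append(h_index([_q_from_sets(s)[0] for s in shuffled]))

    exceed = sum(1 for h in random_h if h >= observed_h - 1e-12)
    p_value = (1 + exceed) / (1 + n_random_lists)
    return CoherenceResult(
        q_values=observed_q,
        h=observed_h,
        p_value=p_value,
        n_random_lists=n_random_lists,
        n_swaps=n_swaps,
        random_h=tuple(random_h),
    )
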