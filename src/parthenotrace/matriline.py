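"""Maternal-genotype reconstruction and minimum-dam inference.

A set of parthenote offspring can share one dam only if, at every locus,
the union of their known alleles has size at most two (a terminal-fusion
parthenote is homozygous for one maternal allele, so each member pins at
most one allele per locus; failed loci pin nothing).  ``min_mothers``
finds the smallest partition of a parthenote collection into such
dam-compatible blocks by exact branch-and-bound search.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .errors import IncompatibleGroupError, UsageError
from .genotypes_io import LocusGenotype, MultilocusGenotype

#: largest input size for which the exact partition search is attempted
EXACT_SEARCH_LIMIT = 20


@dataclass(frozen=True)
class MaternalReconstruction:
    """Per-locus allele sets for an inferred dam plus her member offspring.

    ``allele_sets[locus]`` holds 0-2 known alleles; loci with fewer than
    two pinned alleles carry an implicit wildcard slot.
    """

    dam_label: str
    members: tuple[str, ...]
    allele_sets: Mapping[str, frozenset[int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        sets = {k: frozenset(v) for k, v in dict(self.allele_sets).items()}
        for locus, alleles in sets.items():
            if len(alleles) > 2:
                raise IncompatibleGroupError(
                    f"{self.dam_label}: {len(alleles)} alleles pinned at {locus}"
                )
        object.__setattr__(self, "allele_sets", sets)

    def wildcard(self, locus: str) -> bool:
        return len(self.allele_sets[locus]) < 2

    def to_genotype(self, role: str = "dam") -> MultilocusGenotype:
        """Render as a (possibly half-missing) multilocus genotype row."""
        genotypes = {}
        for locus, alleles in self.allele_sets.items():
            slots = sorted(alleles)
            genotypes[locus] = LocusGenotype(*slots) if slots else LocusGenotype()
        return MultilocusGenotype(self.dam_label, genotypes, role)

    def explains(self, offspring: MultilocusGenotype) -> bool:
        """Could this dam have produced the given parthenote?"""
        for locus, alleles in self.allele_sets.items():
            known = offspring.genotypes[locus].known_alleles
            if len(set(known) | alleles) > 2:
                return False
        return True


def _locus_sets(ind: MultilocusGenotype) -> dict[str, frozenset[int]]:
    return {
        locus: frozenset(g.known_alleles) for locus, g in ind.genotypes.items()
    }


def group_compatible(parthenotes: Iterable[MultilocusGenotype]) -> bool:
    """True iff every locus-wise union of known alleles has size <= 2."""
    union: dict[str, set[int]] = {}
    for ind in parthenotes:
        for locus, g in ind.genotypes.items():
            s = union.setdefault(locus, set())
            s.update(g.known_alleles)
            if len(s) > 2:
                return False
    return True


def reconstruct_dam(
    group: Sequence[MultilocusGenotype], label: str
) -> MaternalReconstruction:
    """Union the members' known alleles per locus into a dam reconstruction."""
    group = list(group)
    if not group:
        raise UsageError("cannot reconstruct a dam from an empty group")
    if not group_compatible(group):
        raise IncompatibleGroupError(
            f"group {[g.individual_id for g in group]} pins >2 alleles at some locus"
        )
    loci = list(group[0].genotypes)
    allele_sets = {
        locus: frozenset(
            a for ind in group for a in ind.genotypes[locus].known_alleles
        )
        for locus in loci
    }
    members = tuple(sorted(ind.individual_id for ind in group))
    return MaternalReconstruction(label, members, allele_sets)


# ---------------------------------------------------------------------------
# minimum number of dams
# ---------------------------------------------------------------------------


def _compatible_with_block(
    item: Mapping[str, frozenset[int]], block: Mapping[str, set[int]]
) -> bool:
    for locus, alleles in item.items():
        if len(block[locus] | alleles) > 2:
            return False
    return True


def _pairwise_compatible(
    a: Mapping[str, frozenset[int]], b: Mapping[str, frozenset[int]]
) -> bool:
    return all(len(a[locus] | b[locus]) <= 2 for locus in a)


def _greedy_partition(items, locus_sets, loci):
    """First-fit merging over id-sorted items; an upper bound on the minimum."""
    blocks: list[dict] = []
    for idx in range(len(items)):
        placed = False
        for block in blocks:
            if _compatible_with_block(locus_sets[idx], block["union"]):
                block["members"].append(idx)
                for locus in loci:
                    block["union"][locus] |= locus_sets[idx][locus]
                placed = True
                break
        if not placed:
            blocks.append(
                {
                    "members": [idx],
                    "union": {locus: set(locus_sets[idx][locus]) for locus in loci},
                }
            )
    return [tuple(b["members"]) for b in blocks]


def min_mothers(
    parthenotes: Iterable[MultilocusGenotype],
    *,
    exact_limit: int = EXACT_SEARCH_LIMIT,
    label_prefix: str = "Dam",
) -> tuple[int, list[MaternalReconstruction]]:
    """Minimum number of dams explaining a parthenote collection.

    Returns ``(k, reconstructions)`` where the partition into blocks is the
    minimum over all partitions into dam-compatible blocks, found by exact
    branch-and-bound up to ``exact_limit`` items.  Among minimum-size
    partitions the lexicographically smallest (comparing the sorted list of
    sorted member-id tuples) is returned, so the output is deterministic.
    Beyond ``exact_limit`` a greedy first-fit fallback runs with a warning
    and reports an upper bound.
    """
    items = sorted(parthenotes, key=lambda g: g.individual_id)
    if not items:
        return 0, []
    ids = [g.individual_id for g in items]
    if len(set(ids)) != len(ids):
        raise UsageError("duplicate offspring ids in parthenote collection")
    loci = list(items[0].genotypes)
    locus_sets = [_locus_sets(g) for g in items]
    n = len(items)

    if n > exact_limit:
        warnings.warn(
            f"min_mothers: {n} parthenotes exceeds the exact-search limit "
            f"({exact_limit}); greedy fallback reports an UPPER BOUND only",
            stacklevel=2,
        )
        best_partition = _greedy_partition(items, locus_sets, loci)
    else:
        best_partition = _exact_min_partition(locus_sets, ids, loci)

    blocks = sorted(tuple(sorted(ids[i] for i in blk)) for blk in best_partition)
    reconstructions = []
    by_id = {g.individual_id: g for g in items}
    for i, members in enumerate(blocks, start=1):
        reconstructions.append(
            reconstruct_dam([by_id[m] for m in members], f"{label_prefix} {i}")
        )
    return len(blocks), reconstructions


def _exact_min_partition(locus_sets, ids, loci):
    """Branch-and-bound over partitions with pairwise-incompatibility pruning."""
    n = len(ids)
    incompat = [
        [not _pairwise_compatible(locus_sets[i], locus_sets[j]) for j in range(n)]
        for i in range(n)
    ]

    greedy = _greedy_partition(ids, locus_sets, loci)
    best = {
        "k": len(greedy),
        "key": tuple(sorted(tuple(sorted(ids[i] for i in blk)) for blk in greedy)),
        "partition": [tuple(blk) for blk in greedy],
    }

    blocks: list[dict] = []

    def lower_bound(start: int) -> int:
        """Items that each force a new block and are mutually incompatible."""
        reps: list[int] = []
        for idx in range(start, n):
            if any(
                _compatible_with_block(locus_sets[idx], block["union"])
                for block in blocks
            ):
                continue
            if all(incompat[idx][r] for r in reps):
                reps.append(idx)
        return len(reps)

    def key_of() -> tuple:
        return tuple(
            sorted(tuple(sorted(ids[i] for i in block["members"])) for block in blocks)
        )

    def search(idx: int) -> None:
        k_now = len(blocks)
        if k_now + lower_bound(idx) > best["k"]:
            return
        if idx == n:
            key = key_of()
            if (k_now, key) < (best["k"], best["key"]):
                best["k"] = k_now
                best["key"] = key
                best["partition"] = [tuple(block["members"]) for block in blocks]
            return
        item = locus_sets[idx]
        for block in blocks:
            if _compatible_with_block(item, block["union"]):
                added = {
                    locus: item[locus] - block["union"][locus] for locus in loci
                }
                block["members"].append(idx)
                for locus in loci:
                    block["union"][locus] |= added[locus]
                search(idx + 1)
                block["members"].pop()
                for locus in loci:
                    block["union"][locus] -= added[locus]
        if len(blocks) + 1 <= best["k"]:
            blocks.append(
                {
                    "members": [idx],
                    "union": {locus: set(item[locus]) for locus in loci},
                }
            )
            search(idx + 1)
            blocks.pop()

    search(0)
    return best["partition"]


def largest_incompatible_subset(
    parthenotes: Sequence[MultilocusGenotype],
) -> list[str]:
    """Greedy pairwise-incompatible subset; its size lower-bounds min_mothers."""
    items = sorted(parthenotes, key=lambda g: g.individual_id)
    locus_sets = [_locus_sets(g) for g in items]
    chosen: list[int] = []
    for idx in range(len(items)):
        if all(not _pairwise_compatible(locus_sets[idx], locus_sets[c]) for c in chosen):
            chosen.append(idx)
    return [items[i].individual_id for i in chosen]
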