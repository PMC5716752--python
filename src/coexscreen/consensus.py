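"""Recurrence filtering within condition groups and cross-group consensus.

A gene is *recurrent* for a group if it appears in the same-sign list of
at least ``cutoff`` of the group's cohorts.  Recurrent sets are then
intersected across groups; region counts of the 2-4 way Venn
decomposition are reported alongside the consensus list at any level G.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from coexscreen.correlation_screen import SignedGeneLists

SIGNS = ("positive", "negative")

MAX_VENN_GROUPS = 4


class ConsensusError(ValueError):
    """Raised for invalid recurrence or intersection input."""


@dataclass(frozen=True)
class GroupRecurrenceSpec:
    """Recurrence cutoff for one condition group.

    ``cutoff`` is the minimum number of member cohorts (k_g of m_g) in
    which a gene must appear, within one sign, to be recurrent.
    """

    group_id: str
    cohort_ids: tuple[str, ...]
    cutoff: int

    def __post_init__(self) -> None:
        if len(set(self.cohort_ids)) != len(self.cohort_ids):
            raise ConsensusError(f"group {self.group_id!r}: duplicate cohort ids")
        if not 1 <= self.cutoff <= len(self.cohort_ids):
            raise ConsensusError(
                f"group {self.group_id!r}: cutoff {self.cutoff} outside "
                f"[1, {len(self.cohort_ids)}]"
            )

    @classmethod
    def from_fraction(
        cls, group_id: str, cohort_ids: Sequence[str], fraction: float
    ) -> "GroupRecurrenceSpec":
        """Build a spec with cutoff = ceil(fraction * m_g), clipped to [1, m_g]."""
        m = len(cohort_ids)
        cutoff = min(max(math.ceil(fraction * m), 1), m)
        return cls(group_id, tuple(cohort_ids), cutoff)


@dataclass
class RecurrentSets:
    """Per-sign recurrent genes of one group, with per-gene cohort counts."""

    group_id: str
    cutoff: int
    genes: dict[str, frozenset[str]]
    counts: dict[str, dict[str, int]]


@dataclass
class ConsensusResult:
    """Cross-group consensus per sign.

    ``recurrent_by_group[sign][group]`` is that group's recurrent set;
    ``group_count[sign][gene]`` counts the groups whose recurrent set
    holds the gene; ``venn_regions[sign]`` maps a frozenset-of-groups
    signature to the number of genes exactly in that signature;
    ``conflict_genes`` are genes recurrent positively in one group and
    negatively in another.
    """

    min_groups: int
    recurrent_by_group: dict[str, dict[str, frozenset[str]]]
    group_count: dict[str, dict[str, int]]
    venn_regions: dict[str, dict[frozenset[str], int]] | None
    conflict_genes: frozenset[str]

    def consensus_at(self, min_groups: int, sign: str) -> frozenset[str]:
        """Genes in at least ``min_groups`` groups' recurrent sets for ``sign``."""
        counts = self.group_count[sign]
        return frozenset(g for g, c in counts.items() if c >= min_groups)


def recurrence_filter(
    lists: Mapping[str, SignedGeneLists] | Iterable[SignedGeneLists],
    spec: GroupRecurrenceSpec,
) -> RecurrentSets:
    """Apply a group's recurrence cutoff to its cohorts' sign lists.

    Signs are processed independently: a gene is recurrent positively iff
    it is in the positive list of at least ``spec.cutoff`` member cohorts.

    Raises
    ------
    ConsensusError
        If a cohort named in the spec has no supplied list.
    """
    if not isinstance(lists, Mapping):
        lists = {sl.cohort_id: sl for sl in lists}
    missing = [c for c in spec.cohort_ids if c not in lists]
    if missing:
        raise ConsensusError(
            f"group {spec.group_id!r}: no sign lists for cohort(s) {missing}"
        )

    genes: dict[str, frozenset[str]] = {}
    counts: dict[str, dict[str, int]] = {}
    for sign in SIGNS:
        tally: dict[str, int] = {}
        for cohort_id in spec.cohort_ids:
            for gene in getattr(lists[cohort_id], sign):
                tally[gene] = tally.get(gene, 0) + 1
        counts[sign] = tally
        genes[sign] = frozenset(g for g, c in tally.items() if c >= spec.cutoff)
    return RecurrentSets(spec.group_id, spec.cutoff, genes, counts)


def venn_counts(sets: Mapping[str, frozenset[str] | set[str]]) -> dict[frozenset[str], int]:
    """Region counts of the Venn decomposition of 2-4 labeled sets.

    Returns a mapping from every nonempty subset-of-labels signature to
    the number of genes belonging to exactly that combination of sets.
    """
    labels = list(sets)
    if not 2 <= len(labels) <= MAX_VENN_GROUPS:
        raise ConsensusError(
            f"Venn region decomposition supports 2-{MAX_VENN_GROUPS} sets, "
            f"got {len(labels)}"
        )
    regions: dict[frozenset[str], int] = {}
    # initialise every nonempty signature at 0
    for mask in range(1, 1 << len(labels)):
        sig = frozenset(labels[i] for i in range(len(labels)) if mask >> i & 1)
        regions[sig] = 0
    universe = set().union(*sets.values())
    for gene in universe:
        sig = frozenset(lab for lab in labels if gene in sets[lab])
        regions[sig] += 1
    return regions


def consensus_intersect(
    recurrent: Sequence[RecurrentSets],
    min_groups: int = 0,
) -> ConsensusResult:
    """Intersect per-group recurrent sets across groups, per sign.

    ``min_groups`` defaults to the number of groups (full intersection).
    Venn region counts are computed when there are 2-4 groups; with more
    groups requesting regions is an error, but group counts still work.
    """
    if len(recurrent) < 2:
        raise ConsensusError("need at least 2 groups for a consensus")
    group_ids = [r.group_id for r in recurrent]
    if len(set(group_ids)) != len(group_ids):
        raise ConsensusError("duplicate group ids in consensus input")
    if min_groups == 0:
        min_groups = len(recurrent)
    if not 1 <= min_groups <= len(recurrent):
        raise ConsensusError(
            f"min_groups {min_groups} outside [1, {len(recurrent)}]"
        )

    recurrent_by_group: dict[str, dict[str, frozenset[str]]] = {}
    group_count: dict[str, dict[str, int]] = {}
    for sign in SIGNS:
        by_group = {r.group_id: r.genes[sign] for r in recurrent}
        recurrent_by_group[sign] = by_group
        counts: dict[str, int] = {}
        for gene_set in by_group.values():
            for gene in gene_set:
                counts[gene] = counts.get(gene, 0) + 1
        group_count[sign] = counts

    regions: dict[str, dict[frozenset[str], int]] | None = None
    if len(recurrent) <= MAX_VENN_GROUPS:
        regions = {
            sign: venn_counts(recurrent_by_group[sign]) for sign in SIGNS
        }

    pos_any = set(group_count["positive"])
    neg_any = set(group_count["negative"])
    conflicts = frozenset(pos_any & neg_any)

    return ConsensusResult(
        min_groups=min_groups,
        recurrent_by_group=recurrent_by_group,
        group_count=group_count,
        venn_regions=regions,
        conflict_genes=conflicts,
    )
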