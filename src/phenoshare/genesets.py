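"""Disease/phenotype gene sets: construction, Venn regions and projection.

A *gene set* here is a labeled collection of unique gene symbols tied to one
disease term (human) or one phenotype term (mouse).  Sets are built from
by-term co-occurrence summaries with a minimum-size threshold, mirroring the
"at least 3 genes" / "at least 10 genes" cutoffs used when drawing the
dendrograms, and can be compared by disjoint Venn regions or projected
through an annotation collection (e.g. a pathway GMT) for pathway-level
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence

from .errors import PreconditionError
from .records import CooccurrenceSummary, require_axis


@dataclass(frozen=True)
class GeneSet:
    """A labeled set of unique gene symbols."""

    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("gene set label must be non-empty")
        if not self.members:
            raise ValueError(f"gene set {self.label!r} must have at least one member")
        object.__setattr__(self, "members", frozenset(self.members))

    @property
    def size(self) -> int:
        return len(self.members)

    @classmethod
    def _allow_empty(cls, label: str, members: frozenset[str]) -> "GeneSet":
        # Projection through annotations may legitimately yield no labels;
        # everywhere else the size >= 1 invariant holds.
        obj = object.__new__(cls)
        object.__setattr__(obj, "label", label)
        object.__setattr__(obj, "members", frozenset(members))
        return obj


class GeneSetCollection:
    """An ordered collection of gene sets with unique labels."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: list[GeneSet] = list(sets)
        labels = [s.label for s in self.sets]
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise ValueError(f"duplicate gene set labels: {dupes}")
        self._by_label = {s.label: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, label: str) -> GeneSet:
        return self._by_label[label]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sets]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)

    def subset(self, labels: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(self._by_label[l] for l in labels)


def build_gene_sets(
    summaries: Iterable[CooccurrenceSummary],
    min_size: int = 1,
    min_count: int = 1,
) -> GeneSetCollection:
    """Build one gene set per term from by-term summaries.

    A gene enters its term's set when its co-occurrence count is at least
    ``min_count`` (default 1: any positive association admits a gene); a term
    survives when the resulting set has at least ``min_size`` members.
    """
    if min_size < 1 or min_count < 1:
        raise PreconditionError("min_size and min_count must both be >= 1")
    summaries = list(summaries)
    require_axis(summaries, "by_term")
    kept = []
    for s in summaries:
        members = frozenset(g for g, n in s.entries if n >= min_count)
        if len(members) >= min_size:
            kept.append(GeneSet(label=s.key, members=members))
    return GeneSetCollection(kept)


def venn_regions(sets: Sequence[GeneSet]) -> dict[frozenset[str], int]:
    """Count the disjoint Venn regions of 2 or 3 gene sets.

    Keys are frozensets of the labels whose sets contain the region (the
    region signature); values are exclusive member counts.  All 3 (pairwise)
    or 7 (triple) regions are present, zeros included, and the counts sum to
    the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise PreconditionError(f"venn_regions supports 2 or 3 sets, got {len(sets)}")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise PreconditionError("gene set labels must be distinct")
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(sets, r):
            inside = frozenset.intersection(*(s.members for s in combo))
            outside: set[str] = set()
            for s in sets:
                if s not in combo:
                    outside |= s.members
            regions[frozenset(s.label for s in combo)] = len(inside - outside)
    return regions


def project_to_annotations(
    gene_set: GeneSet,
    annotations: GeneSetCollection,
    min_shared: int = 1,
) -> GeneSet:
    """Project a gene set onto annotation-category labels.

    Returns a set whose "members" are the labels of annotation sets (e.g.
    pathways from a GMT file) sharing at least ``min_shared`` genes with the
    input, enabling pathway-level Venn comparison via :func:`venn_regions`.
    The projected set may be empty; it is returned with a ``label`` derived
    from the input even so, represented as a plain frozenset wrapper.
    """
    if len(annotations) == 0:
        raise PreconditionError("annotation collection is empty")
    if min_shared < 1:
        raise PreconditionError("min_shared must be >= 1")
    hits = frozenset(
        a.label for a in annotations if len(a.members & gene_set.members) >= min_shared
    )
    if not hits:
        return GeneSet._allow_empty(gene_set.label, frozenset())
    return GeneSet(label=gene_set.label, members=hits)
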