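"""Core record types for association data, phenotype annotations and summaries.

The human side of the pipeline is built from *association records*: one row
per (publication, gene, disease term) with a curated flag saying whether the
study reported a positive (Y) or negative (N) association, or no
determination at all.  The mouse side uses *phenotype annotations*: one row
per (gene, Mammalian Phenotype code) derived from mutant/knockout models,
with no replication semantics.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from .errors import PreconditionError

_MP_CODE_RE = re.compile(r"^MP:\d+$")


class Association(enum.Enum):
    """Curated study outcome for one association record."""

    Y = "Y"
    N = "N"
    UNKNOWN = ""

    @classmethod
    def from_token(cls, token: str) -> "Association":
        tok = token.strip().upper()
        if tok == "Y":
            return cls.Y
        if tok == "N":
            return cls.N
        if tok == "":
            return cls.UNKNOWN
        raise ValueError(f"unparseable association flag {token!r} (expected Y, N or blank)")


@dataclass(frozen=True)
class AssociationRecord:
    """One publication x gene x disease-term row of an association table."""

    gene_symbol: str
    gene_id: int | None
    term: str
    disease_class: str
    association: Association
    publication_id: str

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")

    @property
    def is_positive_annotated(self) -> bool:
        """True when the record is positively associated and carries a term."""
        return self.association is Association.Y and bool(self.term)


@dataclass(frozen=True)
class PhenotypeAnnotation:
    """One mouse gene annotated with one Mammalian Phenotype (MP) code."""

    mouse_gene_symbol: str
    mp_code: str
    allele_id: str | None = None
    publication_id: str | None = None

    def __post_init__(self) -> None:
        if not self.mouse_gene_symbol:
            raise ValueError("mouse_gene_symbol must be non-empty")
        if not _MP_CODE_RE.match(self.mp_code):
            raise ValueError(f"invalid MP code {self.mp_code!r} (expected MP:<digits>)")


@dataclass(frozen=True)
class OntologyTerm:
    """An ontology term: code, display name, and is_a parent codes."""

    mp_code: str
    name: str
    parent_codes: tuple[str, ...] = ()


class OrthologPair(NamedTuple):
    """A (mouse symbol, human symbol) orthology assertion."""

    mouse_symbol: str
    human_symbol: str


@dataclass(frozen=True)
class CooccurrenceSummary:
    """Counted counterparts for one key (a gene, or a disease/phenotype term).

    ``entries`` is ordered by count descending with alphabetical tie-break;
    every counterpart appears once and every count is >= 1.  ``axis`` records
    whether the key is a gene (``by_gene``) or a term (``by_term``) so that
    downstream joins can validate their inputs.
    """

    key: str
    entries: tuple[tuple[str, int], ...]
    axis: str  # "by_gene" | "by_term"

    def __post_init__(self) -> None:
        if self.axis not in ("by_gene", "by_term"):
            raise ValueError(f"axis must be 'by_gene' or 'by_term', got {self.axis!r}")
        seen: set[str] = set()
        for counterpart, count in self.entries:
            if count < 1:
                raise ValueError(f"count for {counterpart!r} must be >= 1")
            if counterpart in seen:
                raise ValueError(f"duplicate counterpart {counterpart!r} under key {self.key!r}")
            seen.add(counterpart)

    @classmethod
    def from_counts(cls, key: str, counts: Mapping[str, int], axis: str) -> "CooccurrenceSummary":
        """Build a summary, sorting by count descending then alphabetically."""
        ordered = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
        return cls(key=key, entries=ordered, axis=axis)

    @property
    def counterparts(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.entries)


def summaries_as_triples(summaries: Iterable[CooccurrenceSummary]) -> set[tuple[str, str, int]]:
    """Flatten summaries to (gene, term, count) triples regardless of axis.

    Useful for checking the transpose duality between by-gene and by-term
    summaries of the same record table.
    """
    triples: set[tuple[str, str, int]] = set()
    for s in summaries:
        for counterpart, count in s.entries:
            if s.axis == "by_gene":
                triples.add((s.key, counterpart, count))
            else:
                triples.add((counterpart, s.key, count))
    return triples


def require_axis(summaries: Iterable[CooccurrenceSummary], axis: str) -> None:
    """Raise :class:`PreconditionError` unless all summaries share ``axis``."""
    for s in summaries:
        if s.axis != axis:
            raise PreconditionError(
                f"expected {axis} summaries, got a {s.axis} summary for key {s.key!r}"
            )
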