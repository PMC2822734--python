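"""Cross-species joins of human disease and mouse phenotype summaries.

An ortholog table (mouse symbol <-> human symbol, many-to-many allowed)
bridges the two per-gene summary sets, producing one row per orthologous
gene pair that carries phenotype evidence in both species — the
shared-gene comparison table.  Orthology is taken strictly from the
supplied table; a case-insensitive symbol-equality fallback (Apoe <-> APOE)
exists behind a flag for users without a map, but symbol coincidence is
error-prone and the flag is off by default.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from dataclasses import dataclass

from .records import CooccurrenceSummary, OrthologPair, require_axis


@dataclass(frozen=True)
class CrossSpeciesRow:
    """One (mouse gene, human ortholog) pair with both species' term lists."""

    mouse_symbol: str
    human_symbol: str
    human_term_entries: tuple[tuple[str, int], ...]  # (MeSH term, count), count desc
    mouse_phenotype_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.mouse_symbol or not self.human_symbol:
            raise ValueError("both symbol fields must be non-empty")


def map_orthologs(
    mouse_genes: Iterable[str], pairs: Sequence[OrthologPair]
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """Map mouse symbols to their human ortholog symbols.

    Returns ``(mapping, unmapped)``: only mouse genes present in ``pairs``
    appear in the mapping (many-to-many preserved); the rest are reported
    in ``unmapped``.
    """
    table: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        table[p.mouse_symbol].add(p.human_symbol)
    mapping: dict[str, frozenset[str]] = {}
    unmapped: set[str] = set()
    for g in mouse_genes:
        if g in table:
            mapping[g] = frozenset(table[g])
        else:
            unmapped.add(g)
    return mapping, frozenset(unmapped)


def shared_gene_table(
    human_summaries: Sequence[CooccurrenceSummary],
    mouse_summaries: Sequence[CooccurrenceSummary],
    pairs: Sequence[OrthologPair],
    case_fallback: bool = False,
) -> list[CrossSpeciesRow]:
    """One row per (mouse gene, human ortholog) pair with evidence in both species.

    Both inputs must be by-gene summaries.  ``case_fallback=True``
    additionally matches a mouse gene to a human gene whose symbol equals
    it case-insensitively, for use when no ortholog map is available.
    """
    require_axis(human_summaries, "by_gene")
    require_axis(mouse_summaries, "by_gene")
    human_by_gene = {s.key: s for s in human_summaries if s.entries}
    mouse_by_gene = {s.key: s for s in mouse_summaries if s.entries}
    mapping, _ = map_orthologs(mouse_by_gene, pairs)
    if case_fallback:
        by_upper = defaultdict(set)
        for h in human_by_gene:
            by_upper[h.upper()].add(h)
        for g in mouse_by_gene:
            extra = by_upper.get(g.upper(), set())
            if extra:
                mapping[g] = frozenset(mapping.get(g, frozenset()) | extra)
    rows = []
    for mouse_gene in sorted(mapping):
        for human_gene in sorted(mapping[mouse_gene]):
            if human_gene not in human_by_gene:
                continue
            rows.append(
                CrossSpeciesRow(
                    mouse_symbol=mouse_gene,
                    human_symbol=human_gene,
                    human_term_entries=human_by_gene[human_gene].entries,
                    mouse_phenotype_terms=mouse_by_gene[mouse_gene].counterparts,
                )
            )
    return rows


def write_cross_table(rows: Sequence[CrossSpeciesRow], path) -> None:
    """Write the shared-gene table as TSV (terms ;-joined, counts in parens)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mouse_symbol\thuman_symbol\thuman_terms\tmouse_phenotypes\n")
        for r in rows:
            human = ";".join(f"{t}({n})" for t, n in r.human_term_entries)
            mouse = ";".join(r.mouse_phenotype_terms)
            fh.write(f"{r.mouse_symbol}\t{r.human_symbol}\t{human}\t{mouse}\n")
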