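"""Filtering and co-occurrence summarization of association records.

Only records that are (a) positively associated and (b) carry a disease
term enter the analysis.  Counting how often each (gene, term) pair
co-occurs across the retained records, then sorting counts in declining
order per gene (or per term), yields the GENE-to-disease and
DISEASE-to-gene summary tables that the rest of the pipeline consumes.

Human gene symbols are uppercased during counting (HUGO-style convention);
mouse symbols, which arrive via phenotype annotations rather than
association records, keep their case.  Mouse co-occurrence counts are
structural multiplicities only — mouse annotations come from individual
genetic models, not replicated population studies, so their counts carry
no replication-evidence semantics.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Mapping

from .errors import PhenoshareError, PreconditionError
from .records import (
    AssociationRecord,
    CooccurrenceSummary,
    OntologyTerm,
    PhenotypeAnnotation,
)


def filter_records(records: Iterable[AssociationRecord]) -> list[AssociationRecord]:
    """Keep records with a positive (Y) flag and a non-empty disease term.

    Input order is preserved; the operation is idempotent.
    """
    return [r for r in records if r.is_positive_annotated]


def count_cooccurrences(
    records: Iterable[AssociationRecord],
    axis: str = "by_gene",
    dedup_publications: bool = False,
    symbol_case: str = "upper",
) -> list[CooccurrenceSummary]:
    """Count gene x term co-occurrences over filtered records.

    ``by_gene`` gives one summary per unique gene listing its terms with
    counts; ``by_term`` is the exact transpose.  Each record contributes 1
    to its (gene, term) count even when the same publication appears twice;
    ``dedup_publications=True`` collapses duplicate
    (publication, gene, term) rows first.  ``symbol_case`` is ``"upper"``
    for human symbols or ``"preserve"``.

    Records that were not filtered (flag != Y or empty term) violate the
    contract and raise :class:`PreconditionError`.
    """
    if axis not in ("by_gene", "by_term"):
        raise ValueError(f"axis must be 'by_gene' or 'by_term', got {axis!r}")
    if symbol_case not in ("upper", "preserve"):
        raise ValueError("symbol_case must be 'upper' or 'preserve'")

    pair_counts: Counter[tuple[str, str]] = Counter()
    seen_rows: set[tuple[str, str, str]] = set()
    for r in records:
        if not r.is_positive_annotated:
            raise PreconditionError(
                f"record for gene {r.gene_symbol!r} is not positive+annotated; "
                "run filter_records first"
            )
        gene = r.gene_symbol.upper() if symbol_case == "upper" else r.gene_symbol
        if dedup_publications:
            row_key = (r.publication_id, gene, r.term)
            if row_key in seen_rows:
                continue
            seen_rows.add(row_key)
        pair_counts[(gene, r.term)] += 1

    grouped: dict[str, dict[str, int]] = defaultdict(dict)
    for (gene, term), count in pair_counts.items():
        if axis == "by_gene":
            grouped[gene][term] = count
        else:
            grouped[term][gene] = count
    return [
        CooccurrenceSummary.from_counts(key, counts, axis)
        for key, counts in sorted(grouped.items())
    ]


def annotate_mouse_phenotypes(
    annotations: Iterable[PhenotypeAnnotation],
    ontology: Mapping[str, OntologyTerm],
) -> list[CooccurrenceSummary]:
    """Per-gene summaries of mouse phenotypes with MP codes exchanged for names.

    Duplicate (gene, code) annotations collapse to one entry whose count is
    the occurrence multiplicity.  Every code must resolve in the ontology;
    unresolved codes should have been separated upstream
    (see :func:`phenoshare.io_formats.read_mouse_phenotypes`).
    """
    grouped: dict[str, Counter[str]] = defaultdict(Counter)
    for a in annotations:
        term = ontology.get(a.mp_code)
        if term is None:
            raise PhenoshareError(
                f"MP code {a.mp_code} for gene {a.mouse_gene_symbol} is not in the ontology"
            )
        grouped[a.mouse_gene_symbol][term.name] += 1
    return [
        CooccurrenceSummary.from_counts(gene, counts, "by_gene")
        for gene, counts in sorted(grouped.items())
    ]
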