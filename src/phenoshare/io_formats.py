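"""Readers and writers for every external format the pipeline touches.

Tab-delimited association-record tables and phenotype reports (the MGI
report style), an OBO 1.2 subset for the Mammalian Phenotype ontology, GMT
gene-set files, square PHYLIP distance matrices with a sidecar name map for
labels over the classic 10-character limit, Newick trees, two-column
ortholog maps, and the summary TSV used between pipeline stages.

All text is UTF-8.  Disease terms may contain commas and parentheses, so
record tables are delimited by tab only (configurable via the dialect).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .distance import DistanceMatrix
from .errors import FormatError, PreconditionError, RecordParseError
from .genesets import GeneSet, GeneSetCollection
from .records import (
    Association,
    AssociationRecord,
    CooccurrenceSummary,
    OntologyTerm,
    OrthologPair,
    PhenotypeAnnotation,
)
from .trees import PhyloTree

logger = logging.getLogger(__name__)

ASSOCIATION_COLUMNS = (
    "gene_symbol",
    "gene_id",
    "term",
    "disease_class",
    "association",
    "publication_id",
)


@dataclass
class TableDialect:
    """How a record table maps onto the canonical six columns.

    ``columns`` maps canonical names to the header names actually present in
    the file; parsing is order-free with respect to column position.
    """

    delimiter: str = "\t"
    columns: dict[str, str] = field(
        default_factory=lambda: {c: c for c in ASSOCIATION_COLUMNS}
    )


def _read_table(path, delimiter: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8"
    )


def read_association_table(path, dialect: TableDialect | None = None) -> list[AssociationRecord]:
    """Parse a tab-delimited association-record table.

    One record per data row; the association flag is parsed
    case-insensitively from {Y, N, blank}; an empty disease-term cell means
    "no annotation".  A missing mandatory column raises a
    :class:`FormatError` naming it; an unparseable flag raises a
    :class:`RecordParseError` with the 1-based file line number.
    """
    dialect = dialect or TableDialect()
    frame = _read_table(path, dialect.delimiter)
    for canonical in ASSOCIATION_COLUMNS:
        actual = dialect.columns[canonical]
        if actual not in frame.columns:
            raise FormatError(f"missing mandatory column {actual!r} ({canonical})")
    records = []
    col = dialect.columns
    for row_idx, row in enumerate(frame.itertuples(index=False)):
        line_number = row_idx + 2  # header occupies line 1
        data = dict(zip(frame.columns, row))
        try:
            flag = Association.from_token(data[col["association"]])
        except ValueError as exc:
            raise RecordParseError(f"line {line_number}: {exc}", line_number) from exc
        gene_id_text = data[col["gene_id"]].strip()
        records.append(
            AssociationRecord(
                gene_symbol=data[col["gene_symbol"]].strip(),
                gene_id=int(gene_id_text) if gene_id_text else None,
                term=data[col["term"]].strip(),
                disease_class=data[col["disease_class"]].strip(),
                association=flag,
                publication_id=data[col["publication_id"]].strip(),
            )
        )
    return records


def write_association_table(records, path, dialect: TableDialect | None = None) -> None:
    dialect = dialect or TableDialect()
    col = dialect.columns
    frame = pd.DataFrame(
        {
            col["gene_symbol"]: [r.gene_symbol for r in records],
            col["gene_id"]: ["" if r.gene_id is None else str(r.gene_id) for r in records],
            col["term"]: [r.term for r in records],
            col["disease_class"]: [r.disease_class for r in records],
            col["association"]: [r.association.value for r in records],
            col["publication_id"]: [r.publication_id for r in records],
        }
    )
    frame.to_csv(path, sep=dialect.delimiter, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# OBO ontology subset + phenotype report


def read_obo(path) -> dict[str, OntologyTerm]:
    """Parse an OBO file into a code -> term map.

    Only ``id``, ``name`` and ``is_a`` are consumed; everything else the
    ontology carries is ignored, since the pipeline uses it solely for the
    code -> name mapping (plus shallow parentage).  Parents referencing
    codes absent from the file are kept in ``parent_codes`` and flagged as
    dangling by the absence of their own entry in the returned map.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # malformed stanza
        raise FormatError(f"malformed OBO file {path}: {exc}") from exc
    ontology: dict[str, OntologyTerm] = {}
    for code, data in graph.nodes(data=True):
        if "name" not in data:
            continue  # node materialized only as a dangling is_a target
        parents = tuple(data.get("is_a", ()))
        ontology[code] = OntologyTerm(mp_code=code, name=data["name"], parent_codes=parents)
    return ontology


@dataclass
class ReportSchema:
    """Column names of a gene-phenotype report table (MGI .rpt style).

    The exact historical layouts of the MGI reports vary, so the reader is
    schema-configurable rather than hard-coded.
    """

    delimiter: str = "\t"
    gene_column: str = "mouse_gene_symbol"
    mp_column: str = "mp_code"
    allele_column: str | None = "allele_id"
    publication_column: str | None = "publication_id"


def read_phenotype_report(path, schema: ReportSchema | None = None) -> list[PhenotypeAnnotation]:
    schema = schema or ReportSchema()
    frame = _read_table(path, schema.delimiter)
    for required in (schema.gene_column, schema.mp_column):
        if required not in frame.columns:
            raise FormatError(f"missing mandatory column {required!r} in phenotype report")
    annotations = []
    for _, row in frame.iterrows():
        allele = row[schema.allele_column] if schema.allele_column in frame.columns else ""
        pub = (
            row[schema.publication_column]
            if schema.publication_column in frame.columns
            else ""
        )
        annotations.append(
            PhenotypeAnnotation(
                mouse_gene_symbol=str(row[schema.gene_column]).strip(),
                mp_code=str(row[schema.mp_column]).strip(),
                allele_id=str(allele).strip() or None,
                publication_id=str(pub).strip() or None,
            )
        )
    return annotations


def read_mouse_phenotypes(
    obo_path, phenogeno_path, schema: ReportSchema | None = None
) -> tuple[dict[str, OntologyTerm], list[PhenotypeAnnotation], list[PhenotypeAnnotation]]:
    """Read the ontology and the gene-phenotype report together.

    Returns ``(ontology, resolved, unresolved)`` where ``unresolved``
    collects annotations whose MP code has no entry in the ontology.
    """
    ontology = read_obo(obo_path)
    annotations = read_phenotype_report(phenogeno_path, schema=schema)
    resolved = [a for a in annotations if a.mp_code in ontology]
    unresolved = [a for a in annotations if a.mp_code not in ontology]
    return ontology, resolved, unresolved


# ---------------------------------------------------------------------------
# GMT gene sets


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    """Write a collection as GMT: label TAB description TAB member..."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            if "\t" in s.label:
                raise PreconditionError(f"gene set label contains a tab: {s.label!r}")
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.label}\t{description}\t{members}\n")


def read_gmt(path) -> GeneSetCollection:
    sets = []
    labels_seen: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {line_no}: GMT lines need label, description and >= 1 member"
                )
            label, _description, *members = fields
            labels_seen.append(label)
            sets.append(GeneSet(label=label, members=frozenset(m for m in members if m)))
    dupes = sorted({l for l in labels_seen if labels_seen.count(l) > 1})
    if dupes:
        raise FormatError(f"duplicate gene set labels in GMT file: {dupes}")
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# PHYLIP square distance matrix (+ sidecar name map)

_PHYLIP_WIDTH = 10


def _phylip_tokens(labels: list[str]) -> tuple[list[str], bool]:
    """Stable unique tokens of <= 10 characters; flags whether any changed."""
    sanitized = [re.sub(r"[^0-9A-Za-z_.-]", "_", l) for l in labels]
    fits = all(len(s) <= _PHYLIP_WIDTH for s in sanitized)
    if fits and sanitized == labels and len(set(sanitized)) == len(sanitized):
        return labels, False
    width = len(str(len(labels)))
    tokens = [
        f"{s[: _PHYLIP_WIDTH - width - 1]}_{i:0{width}d}" for i, s in enumerate(sanitized)
    ]
    return tokens, True


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".names")


def write_phylip_matrix(matrix: DistanceMatrix, path) -> None:
    """Write a square PHYLIP distance matrix.

    Labels that cannot be used verbatim (longer than 10 characters, clashing
    after sanitization, or containing whitespace) are replaced by stable
    unique tokens; the token -> full label map goes to a ``<path>.names``
    sidecar so that long disease names survive the round trip.
    """
    if not np.allclose(matrix.values, matrix.values.T, atol=1e-12):
        raise PreconditionError("matrix must be symmetric")
    tokens, mapped = _phylip_tokens(matrix.labels)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"    {len(matrix)}\n")
        for token, row in zip(tokens, matrix.values):
            cells = " ".join(f"{v:.10f}" for v in row)
            fh.write(f"{token:<{_PHYLIP_WIDTH}} {cells}\n")
    if mapped:
        with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
            for token, label in zip(tokens, matrix.labels):
                fh.write(f"{token}\t{label}\n")


def read_phylip_matrix(path) -> DistanceMatrix:
    """Read a square PHYLIP matrix, restoring labels from the sidecar if present."""
    with open(path, encoding="utf-8") as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    try:
        count = int(lines[0].strip())
    except (IndexError, ValueError) as exc:
        raise FormatError("first PHYLIP line must be the taxon count") from exc
    rows = lines[1:]
    if len(rows) != count:
        raise FormatError(f"declared {count} rows but found {len(rows)}")
    labels, values = [], []
    for line in rows:
        token = line[:_PHYLIP_WIDTH].strip()
        cells = line[_PHYLIP_WIDTH:].split()
        if len(cells) != count:
            raise FormatError(
                f"row {token!r} has {len(cells)} values, expected {count}"
            )
        labels.append(token)
        values.append([float(c) for c in cells])
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        mapping = {}
        with open(sidecar, encoding="utf-8") as fh:
            for line in fh:
                token, _, label = line.rstrip("\n").partition("\t")
                mapping[token] = label
        labels = [mapping.get(t, t) for t in labels]
    return DistanceMatrix(labels, np.array(values))


# ---------------------------------------------------------------------------
# Newick trees

_NEEDS_QUOTE = re.compile(r"[\s(),:;'\[\]]")


def _quote(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize an unrooted tree as Newick with fixed-precision lengths.

    The tree is written rooted at an internal node; child order is
    deterministic (by smallest leaf label beneath each child).  Negative
    branch lengths are serialized verbatim with a warning.
    """
    graph = tree.graph
    if any(l < 0 for _, _, l in graph.edges(data="length")):
        warnings.warn("tree contains negative branch lengths", stacklevel=2)
    internal = [n for n in graph.nodes if graph.degree(n) > 1]
    root = internal[0] if internal else next(iter(graph.nodes))

    def min_leaf(node, parent) -> str:
        if graph.degree(node) == 1:
            return graph.nodes[node]["label"]
        return min(
            min_leaf(child, node) for child in graph.neighbors(node) if child != parent
        )

    def render(node, parent) -> str:
        if graph.degree(node) == 1 and parent is not None:
            return _quote(graph.nodes[node]["label"])
        children = sorted(
            (c for c in graph.neighbors(node) if c != parent),
            key=lambda c: min_leaf(c, node),
        )
        parts = [
            f"{render(c, node)}:{graph.edges[node, c]['length']:.{precision}f}"
            for c in children
        ]
        return "(" + ",".join(parts) + ")"

    return render(root, None) + ";"


def write_newick(tree: PhyloTree, path, precision: int = 6) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(newick_string(tree, precision=precision) + "\n")


def read_newick(path=None, data: str | None = None) -> PhyloTree:
    """Parse a Newick tree (via dendropy) into an unrooted PhyloTree."""
    import dendropy

    kwargs = {"path": str(path)} if path is not None else {"data": data}
    try:
        dtree = dendropy.Tree.get(schema="newick", preserve_underscores=True, **kwargs)
    except Exception as exc:
        raise FormatError(f"could not parse Newick input: {exc}") from exc
    dtree.deroot()  # collapse a degree-2 root so the tree is unrooted
    graph = nx.Graph()
    ids: dict = {}
    for k, node in enumerate(dtree.preorder_node_iter()):
        ids[node] = k
        if node.taxon is not None:
            graph.add_node(k, label=node.taxon.label)
        else:
            graph.add_node(k)
        if node.parent_node is not None:
            length = node.edge.length if node.edge.length is not None else 0.0
            graph.add_edge(ids[node.parent_node], k, length=float(length))
    return PhyloTree(graph)


# ---------------------------------------------------------------------------
# Ortholog map


def read_ortholog_table(path, delimiter: str = "\t") -> list[OrthologPair]:
    """Read a two-column (mouse, human) symbol table, deduplicated.

    Rows with an empty cell are skipped; the skip count is logged.  Original
    case is preserved — many-to-many mappings are allowed.
    """
    pairs: list[OrthologPair] = []
    seen: set[OrthologPair] = set()
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(delimiter)
            if len(cells) < 2 or not cells[0].strip() or not cells[1].strip():
                skipped += 1
                continue
            pair = OrthologPair(cells[0].strip(), cells[1].strip())
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if skipped:
        logger.warning("skipped %d ortholog rows with empty cells", skipped)
    return pairs


def write_ortholog_table(pairs, path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(f"{p.mouse_symbol}{delimiter}{p.human_symbol}\n")


# ---------------------------------------------------------------------------
# Summary TSV (key, counterpart, count) used between CLI stages


def write_summary(summaries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("axis\tkey\tcounterpart\tcount\n")
        for s in summaries:
            for counterpart, count in s.entries:
                fh.write(f"{s.axis}\t{s.key}\t{counterpart}\t{count}\n")


def read_summary(path) -> list[CooccurrenceSummary]:
    frame = _read_table(path, "\t")
    for required in ("axis", "key", "counterpart", "count"):
        if required not in frame.columns:
            raise FormatError(f"missing mandatory column {required!r} in summary table")
    out = []
    for (axis, key), group in frame.groupby(["axis", "key"], sort=False):
        counts = dict(zip(group["counterpart"], group["count"].astype(int)))
        out.append(CooccurrenceSummary.from_counts(key, counts, axis))
    return out
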