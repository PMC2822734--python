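"""Synthetic association and phenotype data with planted group structure.

The generator emulates the shape of curated association archives: a large
table of (gene, disease term, publication) records of which only a minority
are flagged positive (Y) and carry a standardized disease term, plus a
mouse-style phenotype ontology and gene-annotation report.  Disease terms
are organised into K groups, each owning a disjoint pool of "core" genes;
a term draws each core gene of its group with probability ``p_in`` and each
background gene (genes outside every core) with probability ``p_bg``, so
terms of the same group share genes the way clinically related diseases do.
Replication counts per (gene, term) pair follow a heavy-tailed Zipf law,
mirroring the skewed publication-frequency pattern of real summaries (a few
gene-disease pairs replicated dozens of times, most seen once).

Because the planted grouping is returned as ground truth, every pipeline
stage — filtering, summarization, set building, distances, trees, Ward
clustering, cross-species joins — can be tested end-to-end without any
database download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .errors import PreconditionError
from .records import Association, AssociationRecord, OrthologPair
from .trees import PhyloTree

_ZIPF_CAP = 100  # truncate the heavy tail; real replication counts top out ~70


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    Defaults are the planted-recovery study conditions: 5 groups of 8 terms
    with 30-gene disjoint cores in a 600-gene universe, within-group share
    0.6, background share 0.02.  Noise fractions default to the gross
    proportions of the emulated archive (roughly 29% of records flagged,
    26% positive with a term annotation), so that filtering has real work.
    """

    seed: int = 0
    n_genes: int = 600
    n_terms: int = 40
    n_groups: int = 5
    core_genes_per_group: int = 30
    p_in: float = 0.6
    p_bg: float = 0.02
    count_law: float | None = 1.5  # Zipf exponent; None => every count is 1
    frac_flag_Y: float = 0.26
    frac_flag_N: float = 0.03
    frac_mesh_missing: float = 0.06
    n_classes: int = 8

    def __post_init__(self) -> None:
        for name in ("p_in", "p_bg", "frac_flag_Y", "frac_flag_N", "frac_mesh_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PreconditionError(f"{name}={v} is not a probability")
        if self.frac_flag_Y + self.frac_flag_N > 1.0:
            raise PreconditionError("frac_flag_Y + frac_flag_N must be <= 1")
        if self.n_groups > self.n_terms:
            raise PreconditionError("n_groups cannot exceed n_terms")
        if self.n_groups * self.core_genes_per_group > self.n_genes:
            raise PreconditionError(
                "core pools exceed the gene universe: "
                f"{self.n_groups} x {self.core_genes_per_group} > {self.n_genes}"
            )
        if self.count_law is not None and self.count_law <= 1.0:
            raise PreconditionError("count_law (Zipf exponent) must be > 1")


@dataclass
class GroundTruth:
    """Planted structure retained alongside generated data."""

    term_to_group: dict[str, int]
    group_cores: dict[int, frozenset[str]]
    genes_used: frozenset[str]  # genes appearing in positive+annotated records

    def to_jsonable(self) -> dict:
        return {
            "term_to_group": dict(self.term_to_group),
            "group_cores": {str(g): sorted(c) for g, c in self.group_cores.items()},
            "genes_used": sorted(self.genes_used),
        }


def _human_gene(i: int) -> str:
    return f"GENE{i:04d}"


def _mouse_gene(i: int) -> str:
    return f"Gene{i:04d}"


def _term_name(group: int, idx: int) -> str:
    return f"Disease {group + 1}-{idx + 1}"


def _mp_term_name(group: int, idx: int) -> str:
    return f"abnormal phenotype {group + 1}-{idx + 1}"


def _draw_count(rng: np.random.Generator, exponent: float | None) -> int:
    if exponent is None:
        return 1
    return int(min(rng.zipf(exponent), _ZIPF_CAP))


def _planted_pairs(config: SyntheticConfig, rng: np.random.Generator):
    """Yield (term_index, group, gene_index) for every planted gene draw."""
    per_group = np.array_split(np.arange(config.n_terms), config.n_groups)
    cores = {
        g: np.arange(g * config.core_genes_per_group, (g + 1) * config.core_genes_per_group)
        for g in range(config.n_groups)
    }
    background = np.arange(config.n_groups * config.core_genes_per_group, config.n_genes)
    term_group = {int(t): g for g, idx in enumerate(per_group) for t in idx}
    assignments = []
    for g, term_indices in enumerate(per_group):
        for t in term_indices:
            core_hits = cores[g][rng.random(len(cores[g])) < config.p_in]
            bg_hits = background[rng.random(len(background)) < config.p_bg]
            for gene in np.concatenate([core_hits, bg_hits]):
                assignments.append((int(t), g, int(gene)))
    return assignments, cores, term_group


def simulate_gad_records(
    config: SyntheticConfig,
) -> tuple[list[AssociationRecord], GroundTruth]:
    """Generate an association-record table with planted disease groups.

    Positive signal records carry flag Y and the term; distractor records
    (flag N or no flag) are appended so that Y records make up
    ``frac_flag_Y`` of the table, and ``frac_mesh_missing`` of all records
    lose their term annotation.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    assignments, cores, term_group = _planted_pairs(config, rng)

    pub_counter = 0
    records: list[AssociationRecord] = []
    genes_used: set[str] = set()

    def make_record(gene_idx: int, term_idx: int, group: int, flag: Association):
        nonlocal pub_counter
        pub_counter += 1
        missing = rng.random() < config.frac_mesh_missing
        term = "" if missing else _term_name(group, term_idx)
        if flag is Association.Y and term:
            genes_used.add(_human_gene(gene_idx))
        return AssociationRecord(
            gene_symbol=_human_gene(gene_idx),
            gene_id=gene_idx + 1,
            term=term,
            disease_class=f"Class {group % config.n_classes + 1}",
            association=flag,
            publication_id=f"PMID{pub_counter:07d}",
        )

    signal_flag = Association.Y
    if config.frac_flag_Y == 0.0:
        # no record in the table may be flagged Y
        signal_flag = Association.N if config.frac_flag_N > 0 else Association.UNKNOWN

    for term_idx, group, gene_idx in assignments:
        for _ in range(_draw_count(rng, config.count_law)):
            records.append(make_record(gene_idx, term_idx, group, signal_flag))

    n_signal = len(records)
    if 0.0 < config.frac_flag_Y < 1.0 and n_signal:
        n_noise = round(n_signal * (1.0 - config.frac_flag_Y) / config.frac_flag_Y)
        rest = 1.0 - config.frac_flag_Y
        n_negative = round(n_noise * config.frac_flag_N / rest) if rest > 0 else 0
        for k in range(n_noise):
            gene_idx = int(rng.integers(config.n_genes))
            term_idx = int(rng.integers(config.n_terms))
            flag = Association.N if k < n_negative else Association.UNKNOWN
            records.append(make_record(gene_idx, term_idx, term_group.get(term_idx, 0), flag))

    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    truth = GroundTruth(
        term_to_group={_term_name(g, t): g for t, g in term_group.items()},
        group_cores={
            g: frozenset(_human_gene(int(i)) for i in idx) for g, idx in cores.items()
        },
        genes_used=frozenset(genes_used),
    )
    return records, truth


def simulate_mgi_files(config: SyntheticConfig) -> tuple[str, str, GroundTruth]:
    """Generate MP-style ontology text and a gene-phenotype report.

    The ontology has one root, ``n_classes`` top-level phenotype classes and
    one leaf term per synthetic phenotype; the report annotates mouse genes
    to leaf MP codes with the same planted group logic as the association
    table (no replication counts — mouse annotations are structural).
    Returns ``(obo_text, report_text, truth)``, both parseable by
    :mod:`phenoshare.io_formats`.
    """
    rng = np.random.default_rng([config.seed, 2])
    assignments, cores, term_group = _planted_pairs(config, rng)

    root_code = "MP:0000001"
    class_code = lambda c: f"MP:{c + 2:07d}"  # noqa: E731 - tiny local naming helper
    leaf_code = lambda t: f"MP:{t + 1000001:07d}"  # noqa: E731

    stanzas = [
        "format-version: 1.2",
        "ontology: synthetic-mp",
        "",
        "[Term]",
        f"id: {root_code}",
        "name: mammalian phenotype",
    ]
    for c in range(config.n_classes):
        stanzas += [
            "",
            "[Term]",
            f"id: {class_code(c)}",
            f"name: phenotype class {c + 1}",
            f"is_a: {root_code} ! mammalian phenotype",
        ]
    for t in range(config.n_terms):
        g = term_group.get(t, t % config.n_groups)
        c = g % config.n_classes
        stanzas += [
            "",
            "[Term]",
            f"id: {leaf_code(t)}",
            f"name: {_mp_term_name(g, t)}",
            f"is_a: {class_code(c)} ! phenotype class {c + 1}",
        ]
    obo_text = "\n".join(stanzas) + "\n"

    lines = ["mouse_gene_symbol\tmp_code\tallele_id\tpublication_id"]
    genes_used: set[str] = set()
    seen_pairs: set[tuple[int, int]] = set()
    for term_idx, group, gene_idx in assignments:
        if (term_idx, gene_idx) in seen_pairs:
            continue
        seen_pairs.add((term_idx, gene_idx))
        genes_used.add(_mouse_gene(gene_idx))
        lines.append(
            f"{_mouse_gene(gene_idx)}\t{leaf_code(term_idx)}\t"
            f"Allele{gene_idx:04d}\tMGIREF{term_idx:04d}"
        )
    report_text = "\n".join(lines) + "\n"

    truth = GroundTruth(
        term_to_group={_mp_term_name(g, t): g for t, g in term_group.items()},
        group_cores={
            g: frozenset(_mouse_gene(int(i)) for i in idx) for g, idx in cores.items()
        },
        genes_used=frozenset(genes_used),
    )
    return obo_text, report_text, truth


def simulate_ortholog_map(config: SyntheticConfig, coverage: float = 1.0) -> list[OrthologPair]:
    """Map a ``coverage`` fraction of mouse genes to their human counterparts.

    Synthetic orthology is the case transform Gene#### <-> GENE####; the
    mapped subset is drawn with the config seed, so the ground truth of any
    cross-species join is computable exactly.
    """
    if not 0.0 <= coverage <= 1.0:
        raise PreconditionError("coverage must be in [0, 1]")
    rng = np.random.default_rng([config.seed, 3])
    n_mapped = round(coverage * config.n_genes)
    chosen = sorted(rng.choice(config.n_genes, size=n_mapped, replace=False))
    return [OrthologPair(_mouse_gene(int(i)), _human_gene(int(i))) for i in chosen]


def random_binary_tree(
    n_leaves: int,
    rng: np.random.Generator,
    length_low: float = 0.1,
    length_high: float = 2.0,
    labels: list[str] | None = None,
) -> PhyloTree:
    """A random unrooted binary tree with uniform branch lengths.

    Grown by random edge subdivision (every unrooted binary topology is
    reachable); used to exercise tree reconstruction on exactly additive
    distance matrices.
    """
    if n_leaves < 3:
        raise PreconditionError("need at least 3 leaves")
    if labels is None:
        labels = [f"L{i:02d}" for i in range(n_leaves)]
    graph = nx.Graph()
    center = "int0"
    graph.add_node(center)
    for i in range(3):
        graph.add_node(labels[i], label=labels[i])
        graph.add_edge(labels[i], center)
    next_internal = 1
    for i in range(3, n_leaves):
        edges = sorted(graph.edges, key=str)
        u, v = edges[rng.integers(len(edges))]
        mid = f"int{next_internal}"
        next_internal += 1
        graph.remove_edge(u, v)
        graph.add_edge(u, mid)
        graph.add_edge(mid, v)
        graph.add_node(labels[i], label=labels[i])
        graph.add_edge(labels[i], mid)
    for u, v in graph.edges:
        graph.edges[u, v]["length"] = float(rng.uniform(length_low, length_high))
    return PhyloTree(graph)


PRESETS: dict[str, SyntheticConfig] = {
    # the planted-recovery study conditions (also the dataclass defaults)
    "planted": SyntheticConfig(),
    # a fast preset for end-to-end pipeline runs
    "small": SyntheticConfig(
        n_genes=300, n_terms=20, n_groups=4, core_genes_per_group=15
    ),
}


def preset(name: str, seed: int | None = None) -> SyntheticConfig:
    if name not in PRESETS:
        raise PreconditionError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    if seed is not None:
        cfg = SyntheticConfig(**{**asdict(cfg), "seed": seed})
    return cfg
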