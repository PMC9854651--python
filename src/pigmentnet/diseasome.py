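"""Curation of gene-disease associations and the bipartite diseasome.

The diseasome is a bipartite network whose two node sets are genes and
disease/phenotype names; each curated association contributes one link.
Disease identity is the exact trimmed name string, so disease subtypes
(e.g. different types of the same syndrome) are distinct nodes.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import (
    AssociationRecord,
    AssociationTable,
    GeneCatalog,
    NetworkClass,
    PhenotypeClass,
    SOURCE_PRECEDENCE,
)

logger = logging.getLogger(__name__)


def _best_source(sources) -> "Source":
    for s in SOURCE_PRECEDENCE:
        if s in sources:
            return s
    raise ValueError("empty source set")


def curate(raw: AssociationTable, catalog: GeneCatalog) -> AssociationTable:
    """Curate a raw association table against an official symbol catalog.

    Records whose gene is absent from the catalog are removed; duplicate
    (gene, disease) pairs from different sources are merged into one
    association that records every contributing source. Conflicting
    phenotype-class annotations for the same pair are resolved by source
    precedence (curated review > literature appendix > OpenTargets) with
    a logged warning.
    """
    if catalog.size == 0:
        raise ConfigurationError("gene catalog is empty")
    kept: dict[tuple[str, str], list[AssociationRecord]] = defaultdict(list)
    n_unmatched = 0
    for rec in raw.records:
        if rec.gene not in catalog.symbols:
            n_unmatched += 1
            continue
        kept[(rec.gene, rec.disease)].append(rec)
    records: list[AssociationRecord] = []
    for (gene, disease) in sorted(kept):
        group = kept[(gene, disease)]
        sources = frozenset().union(*(r.all_sources for r in group))
        classes = {r.phenotype_class for r in group}
        if len(classes) > 1:
            by_src = {r.source: r.phenotype_class for r in group}
            winner = by_src[_best_source(by_src)]
            logger.warning(
                "conflicting classes %s for (%s, %s); keeping %s by source precedence",
                sorted(c.value for c in classes), gene, disease, winner.value,
            )
        else:
            winner = next(iter(classes))
        notes = [r.omim_note for r in group if r.omim_note]
        records.append(
            AssociationRecord(
                gene=gene,
                disease=disease,
                phenotype_class=winner,
                source=_best_source(sources),
                omim_note="; ".join(dict.fromkeys(notes)) or None,
                all_sources=sources,
            )
        )
    table = AssociationTable(records=tuple(records))
    logger.info(
        "curation: %d raw records -> %d associations (%d genes, %d diseases); "
        "%d unmatched-gene records removed",
        raw.n_associations, table.n_associations,
        len(table.genes), len(table.diseases), n_unmatched,
    )
    return table


def classify_diseases(table: AssociationTable) -> dict[PhenotypeClass, int]:
    """Partition the unique diseases of a curated table into the four classes.

    Returns a count per phenotype class; the counts sum to the number of
    unique diseases. If records disagree on a disease's class the source
    precedence rule decides, with a warning.
    """
    by_disease: dict[str, dict] = defaultdict(dict)
    for rec in table.records:
        by_disease[rec.disease][rec.source] = rec.phenotype_class
    counts: Counter = Counter({c: 0 for c in PhenotypeClass})
    for disease, by_src in by_disease.items():
        classes = set(by_src.values())
        if len(classes) > 1:
            winner = by_src[_best_source(by_src)]
            logger.warning(
                "disease %r carries classes %s; keeping %s by source precedence",
                disease, sorted(c.value for c in classes), winner.value,
            )
        else:
            winner = next(iter(classes))
        counts[winner] += 1
    return dict(counts)


def disease_classes(table: AssociationTable) -> dict[str, PhenotypeClass]:
    """Map each unique disease to its (precedence-resolved) phenotype class."""
    by_disease: dict[str, dict] = defaultdict(dict)
    for rec in table.records:
        by_disease[rec.disease][rec.source] = rec.phenotype_class
    return {
        d: (by_src[_best_source(by_src)] if len(set(by_src.values())) > 1
            else next(iter(by_src.values())))
        for d, by_src in by_disease.items()
    }


def assign_gene_classes(table: AssociationTable) -> dict[str, NetworkClass]:
    """Assign each gene a single network class.

    A gene linked only to diseases of one phenotype class gets that class;
    a gene whose diseases span two or more classes is labeled MULTIPLE.
    """
    gene_classes: dict[str, set[PhenotypeClass]] = defaultdict(set)
    for rec in table.records:
        gene_classes[rec.gene].add(rec.phenotype_class)
    out: dict[str, NetworkClass] = {}
    for gene, classes in gene_classes.items():
        if len(classes) == 1:
            out[gene] = NetworkClass(next(iter(classes)).value)
        else:
            out[gene] = NetworkClass.MULTIPLE
    return out


def gene_class_counts(assignment: dict[str, NetworkClass]) -> dict[NetworkClass, int]:
    """Count genes per exclusive class (MULTIPLE included, NONE never occurs)."""
    counts = Counter(assignment.values())
    return {c: counts.get(c, 0) for c in NetworkClass if c is not NetworkClass.NONE}


def build_diseasome(table: AssociationTable) -> nx.Graph:
    """Build the bipartite diseasome graph from a curated table.

    Gene nodes carry ``kind='gene'``; disease nodes carry ``kind='disease'``
    and their ``phenotype_class``. Exactly one link per association.
    """
    overlap = table.genes & table.diseases
    if overlap:
        raise ValidationError(
            f"gene and disease names collide, cannot build bipartite graph: {sorted(overlap)[:5]}"
        )
    dclasses = disease_classes(table)
    g = nx.Graph()
    for gene in sorted(table.genes):
        g.add_node(gene, kind="gene", bipartite=0)
    for disease in sorted(table.diseases):
        g.add_node(disease, kind="disease", bipartite=1,
                   phenotype_class=dclasses[disease].value)
    for rec in table.records:
        g.add_edge(rec.gene, rec.disease)
    return g


@dataclass(frozen=True)
class UpsetCounts:
    """Number of genes linked to exactly this subset of the queried diseases."""

    intersection_pattern: frozenset[str]
    gene_count: int


def upset_counts(diseasome: nx.Graph, disease_subset: list[str]) -> list[UpsetCounts]:
    """Exclusive intersection counts over a subset of diseases.

    For every gene linked to at least one disease of the subset, its
    pattern is the exact set of subset diseases it links to; patterns
    partition the covered genes, so counts sum to the number of genes
    linked to >=1 subset disease. Results are sorted by decreasing count,
    ties by pattern size then lexically.
    """
    for d in disease_subset:
        if d not in diseasome or diseasome.nodes[d].get("kind") != "disease":
            raise ValidationError(f"unknown disease in upset query: {d!r}")
    subset = list(dict.fromkeys(disease_subset))
    patterns: Counter = Counter()
    for disease in subset:
        for gene in diseasome.neighbors(disease):
            pattern = frozenset(d for d in subset if diseasome.has_edge(gene, d))
            patterns[(gene, pattern)] = 1
    agg: Counter = Counter()
    for (_, pattern) in patterns:
        agg[pattern] += 1
    return [
        UpsetCounts(intersection_pattern=p, gene_count=c)
        for p, c in sorted(
            agg.items(), key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0])))
        )
    ]


def upset_frame(counts: list[UpsetCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pattern": ["|".join(sorted(c.intersection_pattern)) for c in counts],
            "n_diseases": [len(c.intersection_pattern) for c in counts],
            "gene_count": [c.gene_count for c in counts],
        }
    )
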