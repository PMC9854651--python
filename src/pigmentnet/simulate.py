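"""Seeded synthetic generators for every pipeline input kind.

The generators emulate the structure of the study inputs — a curated
gene-disease association table over four phenotype classes, an official
symbol catalog, a STRING-style scored PPI edge table with planted module
structure and a background interactome, a three-level functional
annotation with GMT term sets, and triplicate LFQ intensity tables for
two cell lines with planted differential proteins. Planted structure is
returned as ground truth so every downstream stage can be scored without
external data.

All generators are pure functions of (spec, seed): identical inputs give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    AssociationRecord,
    AssociationTable,
    GeneCatalog,
    PhenotypeClass,
    ScoredEdge,
    ScoredEdgeTable,
    Source,
    TermSet,
    write_gmt,
)
from .enrichment import LEVEL3_CLASSES

_CLASS_ORDER = (PhenotypeClass.HYPER, PhenotypeClass.HYPO,
                PhenotypeClass.MIXED, PhenotypeClass.PHENOTYPE)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults reproduce the scale of the real inputs: 174 diseases split
    73/55/40/6 over the four phenotype classes, one-plus-Poisson(0.6)
    genes per disease (~278 associations), modest within-class gene
    sharing (~243 unique genes), a 4x10-block PPI among disease proteins
    with high-confidence scores inside blocks and sub-threshold scores
    between them, a background interactome for expansion, and triplicate
    LFQ intensities with 10 proteins planted at 3-fold between lines.
    """

    # diseasome
    n_diseases: int = 174
    class_mixture: tuple[float, float, float, float] = (73 / 174, 55 / 174, 40 / 174, 6 / 174)
    association_lambda: float = 0.6  # genes per disease = 1 + Poisson(lambda)
    share_within: float = 0.10   # P(reuse a gene already used in the same class)
    share_across: float = 0.025  # P(reuse a gene from another class)
    n_unmatched: int = 5         # raw records with catalog-absent genes
    n_duplicate_sources: int = 5  # raw (gene, disease) pairs repeated from a 2nd source
    catalog_extra: int = 500     # catalog symbols beyond the used genes

    # PPI
    n_modules: int = 4
    module_size: int = 10
    within_module_edge_prob: float = 0.9
    between_module_edge_prob: float = 0.02
    score_above: tuple[float, float] = (0.70, 0.999)
    score_below: tuple[float, float] = (0.15, 0.699)
    background_size: int = 60
    background_attach_prob: float = 0.25  # background-to-member high-confidence edges
    background_internal_prob: float = 0.08

    # expression
    cell_lines: tuple[str, str] = ("A375", "FM55")
    n_replicates: int = 3
    noise_sigma: float = 0.1
    planted_fold: float = 3.0
    n_planted_differential: int = 10
    dropout_rate: float = 0.05
    log_intensity_mean: float = 16.0  # natural-log scale of base intensities
    log_intensity_sigma: float = 1.0

    rng_seed: int = 7

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise ConfigurationError("rng_seed is mandatory")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ConfigurationError("class_mixture must sum to 1")
        for p in (self.share_within, self.share_across,
                  self.within_module_edge_prob, self.between_module_edge_prob,
                  self.background_attach_prob, self.background_internal_prob,
                  self.dropout_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability outside [0,1]: {p}")
        if self.n_modules < 1:
            raise ConfigurationError("n_modules must be >= 1")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    disease_classes: dict[str, str] = field(default_factory=dict)
    disease_genes: dict[str, list[str]] = field(default_factory=dict)
    curated_counts: dict[str, int] = field(default_factory=dict)
    class_counts: dict[str, int] = field(default_factory=dict)
    gene_class_counts: dict[str, int] = field(default_factory=dict)
    modules: list[list[str]] = field(default_factory=list)
    background_proteins: list[str] = field(default_factory=list)
    planted_differential: list[str] = field(default_factory=list)
    enriched_terms: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _allocate_class_counts(n: int, mixture: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n diseases to the four classes."""
    raw = [n * m for m in mixture]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def gen_associations(spec: SyntheticSpec) -> tuple[AssociationTable, GeneCatalog, GroundTruth]:
    """Generate a raw association table, a symbol catalog, and ground truth.

    The raw table includes a few records with catalog-absent genes and a
    few duplicated (gene, disease) pairs from a second source, so curation
    has real work to do; ground truth records the post-curation expected
    counts.
    """
    rng = np.random.default_rng(spec.rng_seed)
    counts = _allocate_class_counts(spec.n_diseases, spec.class_mixture)
    diseases: list[tuple[str, PhenotypeClass]] = []
    i = 0
    for cls, n_cls in zip(_CLASS_ORDER, counts):
        for _ in range(n_cls):
            i += 1
            diseases.append((f"Disease {i:03d} ({cls.value.lower()})", cls))
    max_assoc = spec.n_diseases * (1 + 12)
    if max_assoc <= 0:
        raise ConfigurationError("infeasible spec: no gene-disease pairs possible")

    used_by_class: dict[PhenotypeClass, list[str]] = {c: [] for c in _CLASS_ORDER}
    gene_counter = 0
    records: list[AssociationRecord] = []
    disease_genes: dict[str, list[str]] = {}
    sources = [Source.YAMAGUCHI, Source.OPENTARGETS, Source.BAXTER]
    for disease, cls in diseases:
        k = 1 + int(rng.poisson(spec.association_lambda))
        genes: list[str] = []
        while len(genes) < k:
            r = rng.random()
            same_pool = [g for g in used_by_class[cls] if g not in genes]
            other_pool = [g for c, pool in used_by_class.items() if c != cls
                          for g in pool if g not in genes]
            if r < spec.share_within and same_pool:
                g = same_pool[int(rng.integers(len(same_pool)))]
            elif r < spec.share_within + spec.share_across and other_pool:
                g = other_pool[int(rng.integers(len(other_pool)))]
            else:
                gene_counter += 1
                g = f"PG{gene_counter:04d}"
            genes.append(g)
            if g not in used_by_class[cls]:
                used_by_class[cls].append(g)
        disease_genes[disease] = sorted(genes)
        for g in genes:
            src = sources[int(rng.integers(len(sources)))]
            records.append(AssociationRecord(gene=g, disease=disease,
                                             phenotype_class=cls, source=src))

    curated = list(records)
    # duplicated pairs from a second source (merged away by curation)
    n_dup = min(spec.n_duplicate_sources, len(curated))
    for j in rng.choice(len(curated), size=n_dup, replace=False):
        rec = curated[int(j)]
        alt = next(s for s in sources if s != rec.source)
        records.append(AssociationRecord(gene=rec.gene, disease=rec.disease,
                                         phenotype_class=rec.phenotype_class,
                                         source=alt))
    # catalog-absent genes (dropped by curation)
    for j in range(spec.n_unmatched):
        disease, cls = diseases[int(rng.integers(len(diseases)))]
        records.append(AssociationRecord(gene=f"FAKE{j + 1}", disease=disease,
                                         phenotype_class=cls,
                                         source=Source.OPENTARGETS))

    real_genes = sorted({r.gene for r in curated})
    catalog = GeneCatalog.from_symbols(
        real_genes + [f"BG{j:05d}" for j in range(1, spec.catalog_extra + 1)]
    )
    gene_class_sets: dict[str, set[str]] = {}
    for r in curated:
        gene_class_sets.setdefault(r.gene, set()).add(r.phenotype_class.value)
    gene_class_counts: dict[str, int] = {c.value: 0 for c in _CLASS_ORDER}
    gene_class_counts["MULTIPLE"] = 0
    for classes in gene_class_sets.values():
        key = next(iter(classes)) if len(classes) == 1 else "MULTIPLE"
        gene_class_counts[key] += 1
    truth = GroundTruth(
        disease_classes={d: c.value for d, c in diseases},
        disease_genes=disease_genes,
        curated_counts={
            "n_associations": len({(r.gene, r.disease) for r in curated}),
            "n_genes": len(real_genes),
            "n_diseases": spec.n_diseases,
        },
        class_counts={c.value: n for c, n in zip(_CLASS_ORDER, counts)},
        gene_class_counts=gene_class_counts,
    )
    return AssociationTable(records=tuple(records)), catalog, truth


def gen_ppi(
    spec: SyntheticSpec, genes: Sequence[str] | None = None
) -> tuple[ScoredEdgeTable, GroundTruth]:
    """Generate a scored edge table with planted block structure.

    Module members (taken from ``genes`` or synthesized) are wired with
    probability ``within_module_edge_prob`` at scores above the 0.700
    confidence threshold; between-module pairs with probability
    ``between_module_edge_prob`` at sub-threshold scores, so filtering at
    0.700 retains exactly the within-module edges. A background
    interactome of extra proteins is attached with high-confidence edges
    for expansion tests.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    n_members = spec.n_modules * spec.module_size
    if genes is None:
        members = [f"PG{j:04d}" for j in range(1, n_members + 1)]
    else:
        if len(genes) < n_members:
            raise ConfigurationError(
                f"need {n_members} genes for {spec.n_modules} modules, got {len(genes)}"
            )
        members = sorted(genes)[:n_members]
    modules = [members[m * spec.module_size:(m + 1) * spec.module_size]
               for m in range(spec.n_modules)]
    module_of = {g: m for m, mod in enumerate(modules) for g in mod}
    lo_hi = spec.score_above
    lo_lo = spec.score_below
    edges: list[ScoredEdge] = []
    for a_i in range(len(members)):
        for b_i in range(a_i + 1, len(members)):
            a, b = members[a_i], members[b_i]
            same = module_of[a] == module_of[b]
            p = spec.within_module_edge_prob if same else spec.between_module_edge_prob
            if rng.random() < p:
                band = lo_hi if same else lo_lo
                edges.append(ScoredEdge(a, b, float(rng.uniform(*band))))
    background = [f"XP{j:04d}" for j in range(1, spec.background_size + 1)]
    for bp in background:
        for m in members:
            if rng.random() < spec.background_attach_prob:
                edges.append(ScoredEdge(bp, m, float(rng.uniform(*lo_hi))))
    for i in range(len(background)):
        for j in range(i + 1, len(background)):
            if rng.random() < spec.background_internal_prob:
                band = lo_hi if rng.random() < 0.5 else lo_lo
                edges.append(ScoredEdge(background[i], background[j],
                                        float(rng.uniform(*band))))
    truth = GroundTruth(modules=[list(m) for m in modules],
                        background_proteins=background)
    return ScoredEdgeTable.from_edges(edges), truth


def gen_annotation(spec: SyntheticSpec, genes: Sequence[str]) -> pd.DataFrame:
    """Assign each gene one functional class per level (three nested levels)."""
    rng = np.random.default_rng(spec.rng_seed + 2)
    genes = sorted({g for g in genes})
    l3 = [LEVEL3_CLASSES[int(rng.integers(len(LEVEL3_CLASSES)))] for _ in genes]
    l2 = [f"{c} / group {int(rng.integers(1, 5))}" for c in l3]
    l1 = [f"{c} / class {int(rng.integers(1, 6))}" for c in l2]
    return pd.DataFrame({"gene": genes, "class_l1": l1, "class_l2": l2, "class_l3": l3})


def gen_term_sets(
    spec: SyntheticSpec,
    universe: Sequence[str],
    planted_sets: Sequence[Sequence[str]] = (),
    n_random_terms: int = 40,
) -> tuple[list[TermSet], GroundTruth]:
    """GMT-style term sets: planted (truly enriched) sets plus random terms."""
    rng = np.random.default_rng(spec.rng_seed + 3)
    universe = sorted({g for g in universe})
    terms: list[TermSet] = []
    enriched: list[str] = []
    for i, members in enumerate(planted_sets, start=1):
        tid = f"WP:PLANTED{i:02d}"
        terms.append(TermSet(term_id=tid, name=f"planted module set {i}",
                             source="WP", genes=frozenset(members)))
        enriched.append(tid)
    tags = ("MF", "BP", "WP", "HP")
    for i in range(1, n_random_terms + 1):
        size = int(rng.integers(5, max(6, len(universe) // 4)))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        tag = tags[int(rng.integers(len(tags)))]
        terms.append(TermSet(term_id=f"{tag}:RAND{i:03d}", name=f"random set {i}",
                             source=tag, genes=frozenset(str(m) for m in members)))
    return terms, GroundTruth(enriched_terms=enriched)


def gen_expression(
    spec: SyntheticSpec, proteins: Sequence[str]
) -> tuple["ExpressionTable", GroundTruth]:
    """Generate triplicate LFQ intensities for two cell lines.

    Each protein gets a log-normal base intensity shared by both lines;
    replicates add multiplicative noise exp(N(0, sigma)); the planted
    proteins are multiplied by ``planted_fold`` in the second cell line;
    a ``dropout_rate`` fraction of replicate measurements is zeroed
    (not quantified).
    """
    from .expression import ExpressionTable

    rng = np.random.default_rng(spec.rng_seed + 4)
    proteins = sorted({p for p in proteins})
    if spec.n_planted_differential > len(proteins):
        raise ConfigurationError("more planted differentials than proteins")
    planted_idx = rng.choice(len(proteins), size=spec.n_planted_differential,
                             replace=False)
    planted = sorted(proteins[int(i)] for i in planted_idx)
    planted_set = set(planted)
    base = np.exp(rng.normal(spec.log_intensity_mean, spec.log_intensity_sigma,
                             size=len(proteins)))
    line_a, line_b = spec.cell_lines
    rep_cols = [f"rep{r}" for r in range(1, spec.n_replicates + 1)]
    rows = []
    for p_i, prot in enumerate(proteins):
        for line in (line_a, line_b):
            mu = base[p_i] * (spec.planted_fold
                              if (line == line_b and prot in planted_set) else 1.0)
            vals = mu * np.exp(rng.normal(0.0, spec.noise_sigma,
                                          size=spec.n_replicates))
            drop = rng.random(spec.n_replicates) < spec.dropout_rate
            vals = np.where(drop, 0.0, vals)
            rows.append({"protein": prot, "cell_line": line,
                         **{c: float(v) for c, v in zip(rep_cols, vals)}})
    table = ExpressionTable(data=pd.DataFrame(rows))
    return table, GroundTruth(planted_differential=planted)


@dataclass(frozen=True)
class SimulatedPaths:
    """File locations of one simulated dataset."""

    associations: Path
    catalog: Path
    ppi_edges: Path
    annotation: Path
    terms: Path
    expression: Path
    ground_truth: Path


def write_all(spec: SyntheticSpec, outdir: str | Path) -> SimulatedPaths:
    """Generate every input kind and write it under ``outdir``.

    The PPI modules are planted among the curated disease genes; term
    sets include one truly-enriched set per planted module; expression
    covers disease proteins plus the background interactome. A combined
    ground-truth JSON is written alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw, catalog, truth_a = gen_associations(spec)
    genes = sorted({r.gene for r in raw.records if r.gene in catalog.symbols})
    ppi, truth_p = gen_ppi(spec, genes=genes)
    annotation = gen_annotation(spec, genes)
    terms, truth_t = gen_term_sets(spec, universe=genes,
                                   planted_sets=truth_p.modules)
    proteins = sorted(set(genes) | set(truth_p.background_proteins))
    expr, truth_e = gen_expression(spec, proteins)

    paths = SimulatedPaths(
        associations=outdir / "associations.tsv",
        catalog=outdir / "catalog.tsv",
        ppi_edges=outdir / "ppi_edges.tsv",
        annotation=outdir / "annotation.tsv",
        terms=outdir / "terms.gmt",
        expression=outdir / "expression.tsv",
        ground_truth=outdir / "ground_truth.json",
    )
    raw.to_tsv(paths.associations)
    catalog.to_tsv(paths.catalog)
    ppi.to_tsv(paths.ppi_edges)
    annotation.to_csv(paths.annotation, sep="\t", index=False)
    write_gmt(terms, paths.terms)
    expr.to_tsv(paths.expression)
    combined = GroundTruth(
        disease_classes=truth_a.disease_classes,
        disease_genes=truth_a.disease_genes,
        curated_counts=truth_a.curated_counts,
        class_counts=truth_a.class_counts,
        gene_class_counts=truth_a.gene_class_counts,
        modules=truth_p.modules,
        background_proteins=truth_p.background_proteins,
        planted_differential=truth_e.planted_differential,
        enriched_terms=truth_t.enriched_terms,
    )
    combined.to_json(paths.ground_truth)
    return paths
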