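"""Shared data types and file readers/writers.

All tabular inputs are tab-delimited UTF-8 with a header row. Gene symbols
are canonicalized (upper case, surrounding whitespace stripped) on ingest,
matching the convention of official HGNC symbols. Networks are undirected
:class:`networkx.Graph` objects whose edges carry a ``score`` attribute
(combined interaction confidence in [0, 1]) and whose nodes carry a
``network_class`` and a ``provenance`` attribute.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)


class PhenotypeClass(str, Enum):
    """The four disease/phenotype groups of the pigmentation diseasome."""

    HYPER = "HYPER"
    HYPO = "HYPO"
    MIXED = "MIXED"
    PHENOTYPE = "PHENOTYPE"


class NetworkClass(str, Enum):
    """Per-protein class label used on PPI networks.

    MULTIPLE marks genes whose linked diseases span more than one
    phenotype class; NONE marks proteins added during network expansion
    that are not linked to any pigmentation disorder.
    """

    HYPER = "HYPER"
    HYPO = "HYPO"
    MIXED = "MIXED"
    PHENOTYPE = "PHENOTYPE"
    MULTIPLE = "MULTIPLE"
    NONE = "NONE"


class Source(str, Enum):
    """Provenance of a gene-disease association."""

    YAMAGUCHI = "YAMAGUCHI"
    OPENTARGETS = "OPENTARGETS"
    BAXTER = "BAXTER"


#: Precedence used when the same (gene, disease) pair carries conflicting
#: phenotype-class annotations from different sources: the curated review
#: classification wins, then the literature appendix, then OpenTargets.
SOURCE_PRECEDENCE = (Source.YAMAGUCHI, Source.BAXTER, Source.OPENTARGETS)


def canonical_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexically ordered endpoint pair for an undirected edge."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GeneCatalog:
    """Catalog of official protein-coding gene symbols."""

    symbols: frozenset[str]

    def __post_init__(self) -> None:
        for s in self.symbols:
            if not s or s != canonical_symbol(s):
                raise ValidationError(f"catalog symbol not canonical: {s!r}")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in self.symbols

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "GeneCatalog":
        return cls(frozenset(canonical_symbol(s) for s in symbols if s.strip()))

    @classmethod
    def from_tsv(cls, path: str | Path, column: str = "symbol") -> "GeneCatalog":
        df = _read_tsv(path)
        if column not in df.columns:
            raise FormatError(f"catalog file {path} lacks required column {column!r}")
        return cls.from_symbols(df[column].astype(str))

    def to_tsv(self, path: str | Path, column: str = "symbol") -> None:
        pd.DataFrame({column: sorted(self.symbols)}).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AssociationRecord:
    """A single curated gene-disease association."""

    gene: str
    disease: str
    phenotype_class: PhenotypeClass
    source: Source
    omim_note: str | None = None
    all_sources: frozenset[Source] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.all_sources:
            object.__setattr__(self, "all_sources", frozenset({self.source}))


@dataclass(frozen=True)
class AssociationTable:
    """An edge list of the diseasome: curated gene-disease associations."""

    records: tuple[AssociationRecord, ...]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(r.gene for r in self.records)

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(r.disease for r in self.records)

    @property
    def n_associations(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene for r in self.records],
                "disease": [r.disease for r in self.records],
                "class": [r.phenotype_class.value for r in self.records],
                "source": [r.source.value for r in self.records],
                "all_sources": [
                    ";".join(sorted(s.value for s in r.all_sources))
                    for r in self.records
                ],
                "omim_note": [r.omim_note or "" for r in self.records],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


DEFAULT_ASSOCIATION_DIALECT: Mapping[str, str] = {
    "gene": "gene",
    "disease": "disease",
    "class": "class",
    "source": "source",
}


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty input file: {path}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"empty input file: {path}")
    return df


def read_association_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> AssociationTable:
    """Read a gene-disease association TSV.

    ``dialect`` maps the logical column names ``gene``, ``disease``,
    ``class`` and ``source`` to the actual header names of the file, so
    arbitrarily laid-out supplementary tables can be ingested without
    editing them. Rows with a blank gene or disease are dropped with a
    warning; an unknown class or source string raises
    :class:`ValidationError` naming the row.
    """
    colmap = dict(DEFAULT_ASSOCIATION_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = _read_tsv(path)
    for logical, actual in colmap.items():
        if logical in ("gene", "disease", "class", "source") and actual not in df.columns:
            raise FormatError(
                f"association file {path} lacks required column {actual!r} (for {logical})"
            )
    note_col = colmap.get("omim_note")
    records: list[AssociationRecord] = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        gene = canonical_symbol(str(row[colmap["gene"]]))
        disease = str(row[colmap["disease"]]).strip()
        if not gene or not disease:
            n_dropped += 1
            logger.warning("dropping malformed association row %d of %s", i, path)
            continue
        cls_raw = str(row[colmap["class"]]).strip().upper()
        src_raw = str(row[colmap["source"]]).strip().upper()
        try:
            cls = PhenotypeClass(cls_raw)
        except ValueError as exc:
            raise ValidationError(
                f"unknown phenotype class {cls_raw!r} in row {i} of {path}"
            ) from exc
        try:
            src = Source(src_raw)
        except ValueError as exc:
            raise ValidationError(
                f"unknown source {src_raw!r} in row {i} of {path}"
            ) from exc
        note = str(row[note_col]).strip() if note_col and note_col in df.columns else None
        records.append(
            AssociationRecord(gene=gene, disease=disease, phenotype_class=cls,
                              source=src, omim_note=note or None)
        )
    if n_dropped:
        logger.warning("dropped %d malformed rows from %s", n_dropped, path)
    return AssociationTable(records=tuple(records))


@dataclass(frozen=True)
class ScoredEdge:
    """An undirected PPI edge with a combined confidence score in [0, 1].

    Endpoints are stored in canonical lexical order.
    """

    protein_a: str
    protein_b: str
    score: float

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValidationError(f"self-loop edge: {self.protein_a}")
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"edge score outside [0,1]: {self.score}")
        a, b = canonical_pair(self.protein_a, self.protein_b)
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class ScoredEdgeTable:
    """Deduplicated table of scored undirected edges (max score on collision)."""

    edges: tuple[ScoredEdge, ...]

    @classmethod
    def from_edges(cls, edges: Iterable[ScoredEdge]) -> "ScoredEdgeTable":
        best: dict[tuple[str, str], ScoredEdge] = {}
        for e in edges:
            prev = best.get(e.pair)
            if prev is None or e.score > prev.score:
                best[e.pair] = e
        return cls(edges=tuple(best[p] for p in sorted(best)))

    @property
    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.protein_a)
            out.add(e.protein_b)
        return frozenset(out)

    def filter(self, threshold: float) -> "ScoredEdgeTable":
        if not 0.0 <= threshold <= 1.0:
            raise ConfigurationError(f"score threshold outside [0,1]: {threshold}")
        return ScoredEdgeTable(tuple(e for e in self.edges if e.score >= threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_a": [e.protein_a for e in self.edges],
                "protein_b": [e.protein_b for e in self.edges],
                "combined_score": [e.score for e in self.edges],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


class ScoreDialect(str, Enum):
    """How confidence scores are encoded in an edge table.

    UNIT_INTERVAL: real scores already in [0, 1].
    STRING_0_1000: integer combined scores 0-1000 as exported by STRING;
    divided by 1000 on ingest.
    """

    UNIT_INTERVAL = "UNIT_INTERVAL"
    STRING_0_1000 = "STRING_0_1000"


def read_scored_edges(
    path: str | Path,
    score_dialect: ScoreDialect | str = ScoreDialect.UNIT_INTERVAL,
    dialect: Mapping[str, str] | None = None,
) -> ScoredEdgeTable:
    """Read a scored edge TSV (columns protein_a, protein_b, combined_score).

    Self-loops are dropped with a warning; duplicate canonical pairs keep
    the maximum score; a score outside the declared dialect range raises
    :class:`FormatError` carrying the offending row number.
    """
    score_dialect = ScoreDialect(score_dialect)
    colmap = {"protein_a": "protein_a", "protein_b": "protein_b",
              "combined_score": "combined_score"}
    if dialect:
        colmap.update(dialect)
    df = _read_tsv(path)
    for logical, actual in colmap.items():
        if actual not in df.columns:
            raise FormatError(
                f"edge file {path} lacks required column {actual!r} (for {logical})"
            )
    edges: list[ScoredEdge] = []
    n_self = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        a = canonical_symbol(str(row[colmap["protein_a"]]))
        b = canonical_symbol(str(row[colmap["protein_b"]]))
        try:
            raw = float(row[colmap["combined_score"]])
        except ValueError as exc:
            raise FormatError(f"non-numeric score in row {i} of {path}") from exc
        if score_dialect is ScoreDialect.STRING_0_1000:
            if not 0 <= raw <= 1000:
                raise FormatError(
                    f"score {raw} outside 0-1000 in row {i} of {path}"
                )
            score = raw / 1000.0
        else:
            if not 0.0 <= raw <= 1.0:
                raise FormatError(
                    f"score {raw} outside [0,1] in row {i} of {path}"
                )
            score = raw
        if a == b:
            n_self += 1
            logger.warning("dropping self-loop %s-%s in row %d of %s", a, b, i, path)
            continue
        edges.append(ScoredEdge(a, b, score))
    if n_self:
        logger.warning("dropped %d self-loops from %s", n_self, path)
    return ScoredEdgeTable.from_edges(edges)


# ---------------------------------------------------------------------------
# Networks

@dataclass
class PPINetwork:
    """A labeled, score-weighted, undirected PPI network.

    ``graph`` nodes carry ``network_class`` (a :class:`NetworkClass` value
    string) and ``provenance`` ("SEED" or "ADDED"); edges carry ``score``.
    ``unconnected_seeds`` records seed proteins that had no surviving edge
    and are therefore not nodes of the network, but are still reported.
    """

    graph: nx.Graph
    unconnected_seeds: frozenset[str] = frozenset()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str, float]]:
        return {
            (*canonical_pair(u, v), round(float(d["score"]), 6))
            for u, v, d in self.graph.edges(data=True)
        }


def new_network_graph() -> nx.Graph:
    return nx.Graph()


def _node_rows(graph: nx.Graph) -> list[dict]:
    rows = []
    for n in sorted(graph.nodes):
        d = graph.nodes[n]
        row = {"node": n,
               "network_class": d.get("network_class", NetworkClass.NONE.value),
               "provenance": d.get("provenance", "SEED")}
        for k, v in sorted(d.items()):
            if k not in row:
                row[k] = v
        rows.append(row)
    return rows


def write_network(network: PPINetwork | nx.Graph, basepath: str | Path,
                  formats: Iterable[str] = ("sif", "graphml", "csv")) -> dict[str, Path]:
    """Write a network to Cytoscape-friendly files.

    ``basepath`` is a path without extension; for each requested format a
    file is written next to it: ``<base>.sif`` (interaction type ``pp``)
    plus a ``<base>.edges.tsv`` companion holding the scores the SIF
    format cannot carry, ``<base>.graphml`` with score/class attributes,
    and ``<base>.nodes.csv`` with one row per node.
    """
    graph = network.graph if isinstance(network, PPINetwork) else network
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    formats = {f.lower() for f in formats}
    unknown = formats - {"sif", "graphml", "csv"}
    if unknown:
        raise ConfigurationError(f"unknown network formats: {sorted(unknown)}")
    edges = sorted(
        (*canonical_pair(u, v), float(d.get("score", 1.0)))
        for u, v, d in graph.edges(data=True)
    )
    try:
        if "sif" in formats:
            sif = basepath.with_suffix(".sif")
            with open(sif, "w", encoding="utf-8") as fh:
                covered = set()
                for a, b, _ in edges:
                    fh.write(f"{a}\tpp\t{b}\n")
                    covered.update((a, b))
                for n in sorted(set(graph.nodes) - covered):
                    fh.write(f"{n}\n")
            companion = basepath.parent / (basepath.name + ".edges.tsv")
            with open(companion, "w", encoding="utf-8", newline="") as fh:
                w = csv.writer(fh, delimiter="\t")
                w.writerow(["protein_a", "protein_b", "score"])
                for a, b, s in edges:
                    w.writerow([a, b, f"{s:.6f}"])
            written["sif"] = sif
            written["sif_edges"] = companion
        if "graphml" in formats:
            gml = basepath.with_suffix(".graphml")
            export = nx.Graph()
            for n in sorted(graph.nodes):
                d = graph.nodes[n]
                attrs = {k: v for k, v in d.items() if v is not None}
                attrs.setdefault("network_class", NetworkClass.NONE.value)
                attrs.setdefault("provenance", "SEED")
                export.add_node(n, **attrs)
            for a, b, s in edges:
                export.add_edge(a, b, score=s)
            nx.write_graphml(export, gml)
            written["graphml"] = gml
        if "csv" in formats:
            nodecsv = basepath.parent / (basepath.name + ".nodes.csv")
            rows = _node_rows(graph)
            if rows:
                pd.DataFrame(rows).to_csv(nodecsv, index=False)
            else:
                Path(nodecsv).write_text("node,network_class,provenance\n",
                                         encoding="utf-8")
            written["csv"] = nodecsv
    except OSError as exc:
        raise PigmentNetIOError(f"cannot write network files at {basepath}: {exc}") from exc
    return written


class PigmentNetIOError(FormatError):
    """Raised when network files cannot be written or read."""


def read_graphml(path: str | Path) -> PPINetwork:
    graph = nx.read_graphml(path)
    out = nx.Graph()
    for n, d in graph.nodes(data=True):
        out.add_node(str(n), **d)
    for u, v, d in graph.edges(data=True):
        out.add_edge(str(u), str(v), score=float(d.get("score", 1.0)))
    return PPINetwork(graph=out)


def read_sif(path: str | Path, edge_scores: str | Path | None = None) -> PPINetwork:
    """Read a SIF file, optionally with the companion score TSV."""
    scores: dict[tuple[str, str], float] = {}
    if edge_scores is not None:
        sdf = _read_tsv(edge_scores)
        for row in sdf.itertuples(index=False):
            scores[canonical_pair(str(row.protein_a), str(row.protein_b))] = float(row.score)
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                graph.add_node(parts[0])
            elif len(parts) >= 3:
                a, _, b = parts[0], parts[1], parts[2]
                graph.add_edge(a, b, score=scores.get(canonical_pair(a, b), 1.0))
    return PPINetwork(graph=graph)


# ---------------------------------------------------------------------------
# GMT term sets

@dataclass(frozen=True)
class TermSet:
    """A named gene set from a GMT file (term id, name, source tag, members)."""

    term_id: str
    name: str
    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"term {self.term_id} has an empty member set")


def read_gmt(path: str | Path) -> list[TermSet]:
    """Read a GMT file: ``term_id <TAB> description <TAB> gene ...`` per line.

    A term id of the form ``TAG:rest`` yields source tag ``TAG`` (e.g. MF,
    BP, WP, HP); otherwise the tag is ``NA``.
    """
    terms: list[TermSet] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {i} of {path} has fewer than 3 fields")
            term_id, name = parts[0], parts[1]
            source = term_id.split(":", 1)[0] if ":" in term_id else "NA"
            genes = frozenset(canonical_symbol(g) for g in parts[2:] if g.strip())
            if not genes:
                raise FormatError(f"GMT line {i} of {path} has no member genes")
            terms.append(TermSet(term_id=term_id, name=name, source=source, genes=genes))
    return terms


def write_gmt(terms: Sequence[TermSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class Config:
    """Pipeline-wide tunable parameters.

    score_threshold
        Minimum combined confidence for a PPI edge to be kept (inclusive).
    mcl_inflation
        MCL inflation exponent; larger values give finer clusters.
    fdr_alpha
        BH-adjusted significance threshold for over-representation calls.
    fold_change_threshold
        Ratio of LFQ means above which (strictly) a protein is called
        differentially expressed between cell lines.
    expansion_edge_target
        Expansion stops at the first state with more edges than this.
    rng_seed
        Seed for all stochastic components (synthetic data generation).
    """

    score_threshold: float = 0.700
    mcl_inflation: float = 2.5
    fdr_alpha: float = 0.05
    fold_change_threshold: float = 2.0
    expansion_edge_target: int = 2000
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 < self.score_threshold <= 1.0:
            raise ConfigurationError("score_threshold must be in (0, 1]")
        if self.mcl_inflation <= 1.0:
            raise ConfigurationError("mcl_inflation must be > 1")
        if not 0.0 < self.fdr_alpha <= 1.0:
            raise ConfigurationError("fdr_alpha must be in (0, 1]")
        if self.fold_change_threshold <= 0:
            raise ConfigurationError("fold_change_threshold must be positive")
        if self.expansion_edge_target < 0:
            raise ConfigurationError("expansion_edge_target must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "Config":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def with_overrides(self, **overrides) -> "Config":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})
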