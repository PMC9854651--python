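"""Functional class profiling and hypergeometric over-representation analysis.

Class profiling assigns each gene a single functional class from a
three-level annotation (321 fine classes, merged to 58 groups, merged to
15 top-level groups) and reports per-class counts and percentages for a
gene list. Over-representation analysis (ORA) tests a query gene set's
overlap with annotated term sets against a background universe using the
upper-tail hypergeometric distribution, with Benjamini-Hochberg control
of the false discovery rate across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, FormatError, ValidationError
from .io import TermSet, _read_tsv, canonical_symbol

logger = logging.getLogger(__name__)

#: The fixed top-level (level 3) functional class vocabulary.
LEVEL3_CLASSES: tuple[str, ...] = (
    "Signaling",
    "Metabolism",
    "Protein translation, folding, modification and degradation",
    "Transcription",
    "Unknown",
    "Cytoskeleton",
    "Organelles",
    "Other",
    "Immune system and Inflammation",
    "Chromatin organization and DNA repair",
    "Neuronal System, synapses, channels",
    "ECM organization",
    "Cell junction and adhesion",
    "Developmental",
    "DNA Replication",
)

_LEVEL_COLUMNS = {1: "class_l1", 2: "class_l2", 3: "class_l3"}


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene -> three-level functional class TSV.

    Required columns: gene, class_l1, class_l2, class_l3 (one class per
    gene per level). Gene symbols are canonicalized; a duplicated gene
    raises :class:`ValidationError`.
    """
    df = _read_tsv(path)
    required = ["gene", "class_l1", "class_l2", "class_l3"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"annotation file {path} lacks required column {col!r}")
    df = df[required].copy()
    df["gene"] = df["gene"].map(canonical_symbol)
    dup = df["gene"][df["gene"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"annotation file {path} has duplicate genes: {sorted(set(dup))[:5]}"
        )
    return df


def class_profile(
    genes: Iterable[str],
    annotation: pd.DataFrame,
    level: int = 3,
) -> pd.DataFrame:
    """Per-class gene counts and percentages for one gene list.

    Genes missing from the annotation fall into class ``Unknown``. Counts
    sum to the number of (unique) genes; percentages to 100 up to
    rounding. Returns columns class, count, percent sorted by decreasing
    count then class name.
    """
    if level not in _LEVEL_COLUMNS:
        raise ConfigurationError(f"annotation level must be 1, 2 or 3, got {level}")
    col = _LEVEL_COLUMNS[level]
    genes = sorted({canonical_symbol(g) for g in genes})
    if not genes:
        return pd.DataFrame(columns=["class", "count", "percent"])
    lookup = dict(zip(annotation["gene"], annotation[col]))
    assigned = [lookup.get(g, "Unknown") for g in genes]
    counts = pd.Series(assigned).value_counts()
    out = pd.DataFrame({"class": counts.index, "count": counts.values})
    out["percent"] = 100.0 * out["count"] / len(genes)
    return out.sort_values(["count", "class"], ascending=[False, True],
                           ignore_index=True)


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation statistics.

    k genes of the n-gene query fall in the term's K annotated genes out
    of the N-gene universe; p is the upper-tail hypergeometric
    probability P(X >= k).
    """

    term_id: str
    term_name: str
    source: str
    overlap: int
    query_size: int
    term_size: int
    universe_size: int
    p_value: float
    adjusted_p: float
    significant: bool


def hypergeometric_pvalue(k: int, n_query: int, k_term: int, n_universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when ``n_query`` genes are drawn without
    replacement from a universe of ``n_universe`` containing ``k_term``
    term members.
    """
    if not (0 <= k <= min(n_query, k_term)):
        raise ValidationError(
            f"impossible overlap k={k} for n={n_query}, K={k_term}, N={n_universe}"
        )
    return float(hypergeom.sf(k - 1, n_universe, k_term, n_query))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, aligned to input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def hypergeometric_ora(
    query: Iterable[str],
    terms: Sequence[TermSet],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation analysis of a query gene set against term sets.

    Terms are intersected with the universe first; terms left empty are
    not tested. The query must be a subset of the universe. Results carry
    BH-adjusted p-values across all tested terms and are sorted by
    adjusted p, then raw p, then term id; ``significant`` marks
    adjusted_p <= alpha.
    """
    universe_set = frozenset(canonical_symbol(g) for g in universe)
    if not universe_set:
        raise ConfigurationError("universe is empty")
    query_set = frozenset(canonical_symbol(g) for g in query)
    offenders = sorted(query_set - universe_set)
    if offenders:
        raise ValidationError(f"query genes outside the universe: {offenders[:10]}")
    if not query_set:
        logger.warning("empty query; returning no enrichment results")
        return []
    n_universe = len(universe_set)
    n_query = len(query_set)
    tested: list[tuple[TermSet, int, int, float]] = []
    for t in terms:
        members = t.genes & universe_set
        if not members:
            continue
        k = len(query_set & members)
        p = hypergeometric_pvalue(k, n_query, len(members), n_universe)
        tested.append((t, k, len(members), p))
    if not tested:
        return []
    adjusted = benjamini_hochberg([p for *_, p in tested])
    results = [
        EnrichmentResult(
            term_id=t.term_id,
            term_name=t.name,
            source=t.source,
            overlap=k,
            query_size=n_query,
            term_size=size,
            universe_size=n_universe,
            p_value=p,
            adjusted_p=adj,
            significant=bool(adj <= alpha),
        )
        for (t, k, size, p), adj in zip(tested, adjusted)
    ]
    return sorted(results, key=lambda r: (r.adjusted_p, r.p_value, r.term_id))


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "source": [r.source for r in results],
            "overlap": [r.overlap for r in results],
            "query_size": [r.query_size for r in results],
            "term_size": [r.term_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "significant": [r.significant for r in results],
        }
    )
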