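"""Label-free quantification (LFQ) overlay on PPI networks.

Ingests per-replicate LFQ intensity tables for two melanoma cell lines,
decides which proteins count as detected per line, computes detection
coverage against reference gene lists/networks, calls differential
proteins by fold change of mean intensities, and attaches abundance
attributes to network nodes for Cytoscape-style visualization.

Intensities are arbitrary units as produced by LFQ normalization; a zero
(or missing) intensity means "not quantified in that replicate". No
replicate-level statistical test is applied: differential calls are by
fold change alone, mirroring common exploratory proteomics practice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .io import PPINetwork, _read_tsv, canonical_symbol
from .ppi import round_half_up

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionTable:
    """Long-format LFQ table: one row per (protein, cell line).

    ``data`` columns: protein, cell_line, then one column per replicate
    (any names); replicate intensities are non-negative, 0 = not
    quantified.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("protein", "cell_line"):
            if col not in self.data.columns:
                raise FormatError(f"expression table lacks column {col!r}")
        if not self.replicate_columns:
            raise FormatError("expression table has no replicate intensity columns")
        vals = self.data[list(self.replicate_columns)].to_numpy(dtype=float)
        if (vals < 0).any() or np.isnan(vals).any():
            raise FormatError("replicate intensities must be non-negative (0 = missing)")

    @property
    def replicate_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in ("protein", "cell_line"))

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["cell_line"].unique()))

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_columns)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_expression_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> ExpressionTable:
    """Read an LFQ TSV (protein, cell_line, rep columns), canonicalizing symbols."""
    df = _read_tsv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("protein", "cell_line"):
        if col not in df.columns:
            raise FormatError(f"expression file {path} lacks required column {col!r}")
    rep_cols = [c for c in df.columns if c not in ("protein", "cell_line")]
    df = df.copy()
    df["protein"] = df["protein"].map(canonical_symbol)
    for c in rep_cols:
        df[c] = pd.to_numeric(df[c], errors="raise").fillna(0.0)
    return ExpressionTable(data=df)


def detect(table: ExpressionTable, min_replicates: int = 2) -> dict[str, frozenset[str]]:
    """Detected protein sets per cell line.

    A protein counts as detected in a cell line iff it was quantified
    (intensity > 0) in at least ``min_replicates`` replicates there.
    """
    if not 1 <= min_replicates <= table.n_replicates:
        raise ConfigurationError(
            f"min_replicates={min_replicates} outside 1..{table.n_replicates}"
        )
    reps = list(table.replicate_columns)
    out: dict[str, frozenset[str]] = {}
    for line, sub in table.data.groupby("cell_line"):
        nonzero = (sub[reps].to_numpy(dtype=float) > 0).sum(axis=1)
        out[str(line)] = frozenset(sub.loc[nonzero >= min_replicates, "protein"])
    return out


def coverage(detected: Iterable[str], reference: Iterable[str]) -> int:
    """Percent of the reference list found in the detected set (nearest integer)."""
    ref = {canonical_symbol(g) for g in reference}
    if not ref:
        raise ConfigurationError("reference gene list is empty")
    det = {canonical_symbol(g) for g in detected}
    return round_half_up(100.0 * len(det & ref) / len(ref))


@dataclass(frozen=True)
class OverlayAttributes:
    """Per-protein abundance summary across two cell lines.

    ``fold_change`` is the ratio of the larger to the smaller mean (>= 1
    by construction); ``direction`` names the higher cell line.
    ``status`` is "both", "exclusive_<line>" or "absent"; only proteins
    detected in both lines receive ratio-based differential calls.
    """

    protein: str
    mean_by_line: tuple[tuple[str, float], ...]
    detected_by_line: tuple[tuple[str, bool], ...]
    status: str
    fold_change: float | None
    direction: str | None
    differential: bool


def _replicate_mean(values: np.ndarray) -> float:
    """Mean over quantified (non-zero) replicates; 0.0 when none."""
    nz = values[values > 0]
    return float(nz.mean()) if nz.size else 0.0


def fold_changes(
    table: ExpressionTable,
    line_a: str,
    line_b: str,
    threshold: float = 2.0,
    min_replicates: int = 2,
) -> list[OverlayAttributes]:
    """Fold-change calls between two cell lines.

    Means are taken over quantified replicates only. For proteins
    detected in both lines, fold_change = max(mean_a, mean_b) /
    min(mean_a, mean_b) and the protein is differential iff fold_change
    is strictly greater than ``threshold``. Proteins detected in exactly
    one line are flagged exclusive and excluded from ratio calls.
    """
    lines = set(table.data["cell_line"].unique())
    for line in (line_a, line_b):
        if line not in lines:
            raise ConfigurationError(f"cell line {line!r} absent from expression table")
    if threshold <= 0:
        raise ConfigurationError("fold-change threshold must be positive")
    detected = detect(table, min_replicates=min_replicates)
    reps = list(table.replicate_columns)
    means: dict[str, dict[str, float]] = {line_a: {}, line_b: {}}
    for line in (line_a, line_b):
        sub = table.data[table.data["cell_line"] == line]
        for prot, vals in zip(sub["protein"], sub[reps].to_numpy(dtype=float)):
            means[line][prot] = _replicate_mean(vals)
    proteins = sorted(set(means[line_a]) | set(means[line_b]))
    out: list[OverlayAttributes] = []
    for prot in proteins:
        ma = means[line_a].get(prot, 0.0)
        mb = means[line_b].get(prot, 0.0)
        da = prot in detected.get(line_a, frozenset())
        db = prot in detected.get(line_b, frozenset())
        if da and db:
            status = "both"
            lo, hi = sorted((ma, mb))
            fc = hi / lo if lo > 0 else math.inf
            direction = line_a if ma >= mb else line_b
            diff = fc > threshold
        else:
            status = ("exclusive_" + (line_a if da else line_b)) if (da or db) else "absent"
            fc, direction, diff = None, None, False
        out.append(
            OverlayAttributes(
                protein=prot,
                mean_by_line=((line_a, ma), (line_b, mb)),
                detected_by_line=((line_a, da), (line_b, db)),
                status=status,
                fold_change=fc,
                direction=direction,
                differential=diff,
            )
        )
    return out


def overlay_frame(attrs: Sequence[OverlayAttributes]) -> pd.DataFrame:
    rows = []
    for a in attrs:
        row: dict = {"protein": a.protein, "status": a.status,
                     "fold_change": a.fold_change if a.fold_change is not None else "",
                     "direction": a.direction or "",
                     "differential": a.differential}
        for line, m in a.mean_by_line:
            row[f"mean_{line}"] = m
            row[f"log10_{line}"] = math.log10(m) if m > 0 else ""
        for line, d in a.detected_by_line:
            row[f"detected_{line}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def attach_to_network(
    network: PPINetwork,
    attrs: Sequence[OverlayAttributes],
    log_base: float = 10.0,
) -> PPINetwork:
    """Attach abundance attributes to network nodes (in place; returns network).

    Nodes gain per-line mean LFQ, log-transformed LFQ and detected flags;
    proteins absent from the expression table keep no abundance
    attributes (never a fabricated zero or -inf), and undetected means of
    0 carry no log value.
    """
    if log_base <= 1:
        raise ConfigurationError("log base must be > 1")
    by_protein = {a.protein: a for a in attrs}
    for node in network.graph.nodes:
        a = by_protein.get(node)
        if a is None:
            continue
        d = network.graph.nodes[node]
        for line, m in a.mean_by_line:
            d[f"lfq_{line}"] = m
            if m > 0:
                d[f"log_lfq_{line}"] = math.log(m, log_base)
        for line, flag in a.detected_by_line:
            d[f"detected_{line}"] = bool(flag)
        if a.fold_change is not None and math.isfinite(a.fold_change):
            d["fold_change"] = a.fold_change
            d["differential"] = a.differential
            d["direction"] = a.direction
    return network
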