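"""End-to-end pipeline: curation -> diseasome -> PPI -> clustering ->
enrichment -> expansion -> LFQ overlay, with a reproducible run manifest.

Every stage writes plain-text outputs (TSV/SIF/GraphML/JSON) under one run
directory so results are inspectable and loadable into Cytoscape. Summary
tables are deterministic given inputs and configuration; the manifest
additionally records input digests and a config snapshot.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

from . import __version__
from .diseasome import (
    assign_gene_classes,
    build_diseasome,
    classify_diseases,
    curate,
    gene_class_counts,
    upset_counts,
    upset_frame,
)
from .enrichment import class_profile, enrichment_frame, hypergeometric_ora, read_annotation
from .errors import ConfigurationError
from .io import (
    Config,
    GeneCatalog,
    NetworkClass,
    read_association_table,
    read_gmt,
    read_scored_edges,
    write_network,
)
from .expression import (
    attach_to_network,
    coverage,
    detect,
    fold_changes,
    overlay_frame,
    read_expression_table,
)
from .mcl import cluster_network, cluster_summary
from .ppi import (
    categorize_edges,
    connectivity_summary,
    edge_categories_frame,
    expand_network,
    induced_subnetwork,
)

logger = logging.getLogger(__name__)

STAGES = ("curate", "diseasome", "ppi", "cluster", "enrich", "expand", "overlay")


class StageError(ConfigurationError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: Config,
    inputs: Mapping[str, str | Path],
    outdir: str | Path,
    skip: tuple[str, ...] = (),
    score_dialect: str = "UNIT_INTERVAL",
) -> dict:
    """Run all stages in dependency order and return the manifest dict.

    ``inputs`` maps the keys ``associations``, ``catalog``, ``ppi_edges``,
    ``annotation``, ``terms`` and ``expression`` to file paths. A stage in
    ``skip`` is marked skipped in the manifest (stages that depend on it
    are skipped as well). Any stage failure raises with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    required = {"associations", "catalog", "ppi_edges", "annotation", "terms",
                "expression"}
    missing = sorted(required - set(inputs))
    if missing:
        raise ConfigurationError(f"missing pipeline inputs: {missing}")
    inputs = {k: Path(v) for k, v in inputs.items()}
    for key, p in inputs.items():
        if not p.exists():
            raise ConfigurationError(f"input --{key.replace('_', '-')} not found: {p}")
    manifest: dict = {
        "tool": "pigmentnet",
        "version": __version__,
        "config": config.as_dict(),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "stages": {},
        "started": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    skip = tuple(skip)
    unknown = set(skip) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages to skip: {sorted(unknown)}")

    def record(stage: str, outputs: dict[str, Path], summary: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {k: str(v) for k, v in outputs.items()},
            **({"summary": summary} if summary else {}),
        }

    def skipped(stage: str) -> bool:
        if stage in skip:
            manifest["stages"][stage] = {"status": "skipped"}
            return True
        return False

    state: dict = {}
    try:
        stage = "curate"
        if not skipped(stage):
            raw = read_association_table(inputs["associations"])
            catalog = GeneCatalog.from_tsv(inputs["catalog"])
            curated = curate(raw, catalog)
            out = outdir / "curated.tsv"
            curated.to_tsv(out)
            state["curated"] = curated
            record(stage, {"curated": out}, {
                "n_associations": curated.n_associations,
                "n_genes": len(curated.genes),
                "n_diseases": len(curated.diseases),
            })

        stage = "diseasome"
        if "curated" in state and not skipped(stage):
            curated = state["curated"]
            graph = build_diseasome(curated)
            class_counts = classify_diseases(curated)
            gclasses = assign_gene_classes(curated)
            state["gene_classes"] = gclasses
            counts_out = outdir / "disease_class_counts.tsv"
            with open(counts_out, "w", encoding="utf-8") as fh:
                fh.write("class\tn_diseases\n")
                for cls, n in sorted(class_counts.items(), key=lambda kv: kv[0].value):
                    fh.write(f"{cls.value}\t{n}\n")
            gcounts_out = outdir / "gene_class_counts.tsv"
            with open(gcounts_out, "w", encoding="utf-8") as fh:
                fh.write("class\tn_genes\n")
                for cls, n in sorted(gene_class_counts(gclasses).items(),
                                     key=lambda kv: kv[0].value):
                    fh.write(f"{cls.value}\t{n}\n")
            # upset over the four best-connected diseases
            top = sorted(curated.diseases,
                         key=lambda d: (-graph.degree(d), d))[:4]
            upset_out = outdir / "upset.tsv"
            upset_frame(upset_counts(graph, top)).to_csv(upset_out, sep="\t",
                                                         index=False)
            sif_out = outdir / "diseasome.sif"
            with open(sif_out, "w", encoding="utf-8") as fh:
                for gene, disease in sorted(graph.edges()):
                    fh.write(f"{gene}\tgd\t{disease}\n")
            record(stage, {"disease_class_counts": counts_out,
                           "gene_class_counts": gcounts_out,
                           "upset": upset_out, "sif": sif_out})

        stage = "ppi"
        if "curated" in state and not skipped(stage):
            edges = read_scored_edges(inputs["ppi_edges"], score_dialect=score_dialect)
            state["edges"] = edges
            seeds = sorted(state["curated"].genes)
            network = induced_subnetwork(edges, seeds, config.score_threshold,
                                         classes=state.get("gene_classes"))
            state["network"], state["seeds"] = network, seeds
            conn = connectivity_summary(network, seeds)
            files = write_network(network, outdir / "ppi_network")
            conn_out = outdir / "connectivity.tsv"
            with open(conn_out, "w", encoding="utf-8") as fh:
                fh.write("n_nodes\tn_edges\tconnected_fraction_pct\tcomponent_sizes\n")
                fh.write(f"{network.n_nodes}\t{network.n_edges}\t"
                         f"{conn.connected_fraction}\t"
                         f"{','.join(map(str, conn.component_sizes))}\n")
            record(stage, {**files, "connectivity": conn_out}, {
                "n_nodes": network.n_nodes, "n_edges": network.n_edges,
                "connected_fraction_pct": conn.connected_fraction,
            })

        stage = "cluster"
        if "network" in state and not skipped(stage):
            assignment = cluster_network(state["network"],
                                         inflation=config.mcl_inflation)
            state["clusters"] = assignment
            membership = assignment.membership()
            clusters_out = outdir / "clusters.tsv"
            with open(clusters_out, "w", encoding="utf-8") as fh:
                fh.write("node\tcluster_id\n")
                for node in sorted(membership):
                    fh.write(f"{node}\t{membership[node]}\n")
            summary_out = outdir / "cluster_summary.tsv"
            cluster_summary(assignment, state.get("gene_classes")).to_csv(
                summary_out, sep="\t", index=False, float_format="%.4f")
            record(stage, {"clusters": clusters_out, "summary": summary_out}, {
                "n_clusters": len(assignment.clusters),
                "largest_cluster": max((len(c) for c in assignment.clusters),
                                       default=0),
                "converged": assignment.converged,
            })

        stage = "enrich"
        if "network" in state and not skipped(stage):
            annotation = read_annotation(inputs["annotation"])
            terms = read_gmt(inputs["terms"])
            universe = sorted(annotation["gene"])
            query = sorted(set(state["network"].graph.nodes) & set(universe))
            results = hypergeometric_ora(query, terms, universe,
                                         alpha=config.fdr_alpha)
            enr_out = outdir / "enrichment.tsv"
            enrichment_frame(results).to_csv(enr_out, sep="\t", index=False,
                                             float_format="%.6g")
            gclasses = state.get("gene_classes", {})
            profiles = []
            for cls in (NetworkClass.HYPER, NetworkClass.HYPO):
                members = sorted(g for g, c in gclasses.items() if c is cls)
                prof = class_profile(members, annotation, level=3)
                prof.insert(0, "gene_set", f"exclusive_{cls.value}")
                profiles.append(prof)
            prof_out = outdir / "class_profiles.tsv"
            import pandas as pd
            (pd.concat(profiles, ignore_index=True) if profiles
             else pd.DataFrame()).to_csv(prof_out, sep="\t", index=False,
                                         float_format="%.4f")
            record(stage, {"enrichment": enr_out, "class_profiles": prof_out}, {
                "n_terms_tested": len(results),
                "n_significant": sum(r.significant for r in results),
            })

        stage = "expand"
        if "network" in state and not skipped(stage):
            expanded = expand_network(
                state["network"], state["edges"], config.score_threshold,
                config.expansion_edge_target, classes=state.get("gene_classes"))
            state["expanded"] = expanded
            files = write_network(expanded, outdir / "expanded_network")
            cats = categorize_edges(expanded)
            cats_out = outdir / "edge_categories.tsv"
            edge_categories_frame(cats).to_csv(cats_out, sep="\t", index=False)
            record(stage, {**files, "edge_categories": cats_out}, {
                "n_nodes": expanded.n_nodes, "n_edges": expanded.n_edges,
            })

        stage = "overlay"
        if "expanded" in state and not skipped(stage):
            expr = read_expression_table(inputs["expression"])
            lines = expr.cell_lines
            if len(lines) < 2:
                raise ConfigurationError("overlay needs two cell lines")
            line_a, line_b = lines[0], lines[1]
            detected = detect(expr)
            attrs = fold_changes(expr, line_a, line_b,
                                 threshold=config.fold_change_threshold)
            overlay_out = outdir / "overlay.tsv"
            overlay_frame(attrs).to_csv(overlay_out, sep="\t", index=False,
                                        float_format="%.6g")
            annotated = attach_to_network(state["expanded"], attrs)
            files = write_network(annotated, outdir / "quantitative_network",
                                  formats=("graphml", "csv"))
            seeds = state.get("seeds", [])
            cov_out = outdir / "coverage.tsv"
            with open(cov_out, "w", encoding="utf-8") as fh:
                fh.write("cell_line\tn_detected\tcoverage_seeds_pct\t"
                         "coverage_expanded_pct\n")
                for line in (line_a, line_b):
                    det = detected[line]
                    fh.write(
                        f"{line}\t{len(det)}\t"
                        f"{coverage(det, seeds) if seeds else ''}\t"
                        f"{coverage(det, annotated.graph.nodes)}\n")
            n_diff = sum(a.differential for a in attrs)
            record(stage, {**files, "overlay": overlay_out, "coverage": cov_out}, {
                "n_detected": {line: len(detected[line]) for line in (line_a, line_b)},
                "n_differential": n_diff,
            })
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest["finished"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    def _jsonable(o):
        if hasattr(o, "item"):  # numpy scalars
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return manifest
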