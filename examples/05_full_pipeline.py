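"""The whole pipeline in one call, with a reproducible run manifest.

Writes a full synthetic input set, runs curation -> diseasome -> PPI ->
MCL -> enrichment -> expansion -> LFQ overlay, and prints each stage's
summary. All outputs are plain TSV/SIF/GraphML files under the run
directory; manifest.json records input digests and the config snapshot.

Equivalent shell usage:
    pigmentnet simulate --seed 7 --outdir sim/
    pigmentnet report --indir sim/ --outdir run/ --edge-target 300
"""

import tempfile
from pathlib import Path

from pigmentnet import Config, SyntheticSpec, run_pipeline, write_all

spec = SyntheticSpec(rng_seed=7)
config = Config(rng_seed=7, expansion_edge_target=300)

with tempfile.TemporaryDirectory() as tmp:
    sim = write_all(spec, Path(tmp) / "sim")
    manifest = run_pipeline(config, {
        "associations": sim.associations,
        "catalog": sim.catalog,
        "ppi_edges": sim.ppi_edges,
        "annotation": sim.annotation,
        "terms": sim.terms,
        "expression": sim.expression,
    }, Path(tmp) / "run")
    for stage, info in manifest["stages"].items():
        summary = info.get("summary", "")
        print(f"{stage:<10s} {info['status']:<4s} {summary}")
print("\nEach stage wrote its summary table(s); rerunning with the same seed "
      "and config reproduces them byte for byte.")
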