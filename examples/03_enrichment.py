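"""Functional class profiles and over-representation analysis.

Profiles the exclusive hyper- vs hypopigmentation gene sets over the
15-class top-level functional vocabulary, then tests the PPI network's
genes against GMT term sets with the hypergeometric upper tail and
Benjamini-Hochberg FDR control at 0.05.
"""

from pigmentnet import (
    NetworkClass,
    SyntheticSpec,
    assign_gene_classes,
    class_profile,
    curate,
    gen_annotation,
    gen_associations,
    gen_ppi,
    gen_term_sets,
    hypergeometric_ora,
    induced_subnetwork,
)

spec = SyntheticSpec(rng_seed=7)
raw, catalog, _ = gen_associations(spec)
table = curate(raw, catalog)
genes = sorted(table.genes)
annotation = gen_annotation(spec, genes)
classes = assign_gene_classes(table)

for cls in (NetworkClass.HYPER, NetworkClass.HYPO):
    members = sorted(g for g, c in classes.items() if c is cls)
    prof = class_profile(members, annotation, level=3)
    top = prof.head(3)
    print(f"exclusive {cls.value} genes ({len(members)}), top classes:")
    for _, row in top.iterrows():
        print(f"  {row['class']:<55s} {row['percent']:5.1f}%")

edges, ppi_truth = gen_ppi(spec, genes=genes)
net = induced_subnetwork(edges, genes, 0.700)
terms, term_truth = gen_term_sets(spec, universe=genes,
                                  planted_sets=ppi_truth.modules)
results = hypergeometric_ora(sorted(net.graph.nodes), terms, genes, alpha=0.05)
print(f"\nORA: {sum(r.significant for r in results)} of {len(results)} terms "
      "significant at BH-adjusted p <= 0.05")
for r in results[:4]:
    print(f"  {r.term_id:<14s} k={r.overlap:>2d}/K={r.term_size:<3d} "
          f"p={r.p_value:.2e} adj={r.adjusted_p:.2e}")
print("\nThe planted module term sets rank first because the network's genes "
      "are exactly their members; random terms stay non-significant.")
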