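"""Build a pigmentation diseasome from (synthetic) association tables.

Generates a study-scale gene-disease association table, curates it against
the official symbol catalog, and reports the counts a diseasome analysis
starts from: associations, unique genes, unique diseases, the four-way
phenotype class partition, and gene overlap between the best-connected
diseases.
"""

from pigmentnet import (
    SyntheticSpec,
    curate,
    build_diseasome,
    classify_diseases,
    assign_gene_classes,
    gene_class_counts,
    upset_counts,
    gen_associations,
)

spec = SyntheticSpec(rng_seed=7)
raw, catalog, truth = gen_associations(spec)
table = curate(raw, catalog)

print(f"curated: {table.n_associations} associations, "
      f"{len(table.genes)} genes, {len(table.diseases)} diseases")
print("disease classes:", {c.value: n for c, n in classify_diseases(table).items()})
print("gene classes:   ", {c.value: n
                           for c, n in gene_class_counts(assign_gene_classes(table)).items()})

graph = build_diseasome(table)
top4 = sorted(table.diseases, key=lambda d: (-graph.degree(d), d))[:4]
print(f"\ngene overlap among the 4 best-connected diseases:")
for c in upset_counts(graph, top4):
    names = ", ".join(sorted(c.intersection_pattern))
    print(f"  exactly {{{names}}}: {c.gene_count} genes")
print("\nEach line counts genes linked to exactly that subset of the four "
      "diseases; mostly-singleton patterns mean diseases rarely share genes.")
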