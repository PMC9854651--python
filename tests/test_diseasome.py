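"""Curation, disease/gene classification, the bipartite diseasome and
exclusive intersection (upset) counts."""

import itertools

import pytest

from pigmentnet.diseasome import (
    assign_gene_classes,
    build_diseasome,
    classify_diseases,
    curate,
    disease_classes,
    gene_class_counts,
    upset_counts,
)
from pigmentnet.errors import ConfigurationError, ValidationError
from pigmentnet.io import (
    AssociationRecord,
    AssociationTable,
    GeneCatalog,
    NetworkClass,
    PhenotypeClass,
    Source,
)


def rec(gene, disease, cls, src=Source.YAMAGUCHI):
    return AssociationRecord(gene=gene, disease=disease,
                             phenotype_class=PhenotypeClass(cls), source=src)


class TestCurate:
    def test_unmatched_gene_removed(self):
        raw = AssociationTable(records=(rec("TYR", "Vitiligo", "HYPO"),
                                        rec("FAKE1", "Vitiligo", "HYPO")))
        cat = GeneCatalog.from_symbols(["TYR"])
        out = curate(raw, cat)
        assert out.genes == {"TYR"} and out.n_associations == 1

    def test_duplicate_pair_merged_recording_both_sources(self):
        raw = AssociationTable(records=(
            rec("TYR", "Vitiligo", "HYPO", Source.YAMAGUCHI),
            rec("TYR", "Vitiligo", "HYPO", Source.OPENTARGETS)))
        out = curate(raw, GeneCatalog.from_symbols(["TYR"]))
        assert out.n_associations == 1
        assert out.records[0].all_sources == {Source.YAMAGUCHI, Source.OPENTARGETS}
        assert out.records[0].source is Source.YAMAGUCHI  # precedence

    def test_conflicting_class_resolved_by_source_precedence(self):
        raw = AssociationTable(records=(
            rec("TYR", "Vitiligo", "HYPER", Source.OPENTARGETS),
            rec("TYR", "Vitiligo", "HYPO", Source.BAXTER)))
        out = curate(raw, GeneCatalog.from_symbols(["TYR"]))
        assert out.records[0].phenotype_class is PhenotypeClass.HYPO

    def test_empty_catalog_is_configuration_error(self):
        raw = AssociationTable(records=(rec("TYR", "Vitiligo", "HYPO"),))
        with pytest.raises(ConfigurationError):
            curate(raw, GeneCatalog(frozenset()))

    def test_synthetic_paper_scale_counts_match_ground_truth(self, sim_dir,
                                                             curated_table):
        from pigmentnet.simulate import GroundTruth
        truth = GroundTruth.from_json(sim_dir.ground_truth)
        assert curated_table.n_associations == truth.curated_counts["n_associations"]
        assert len(curated_table.genes) == truth.curated_counts["n_genes"]
        assert len(curated_table.diseases) == truth.curated_counts["n_diseases"]


class TestClassification:
    def test_counts_partition_unique_diseases(self, curated_table):
        counts = classify_diseases(curated_table)
        assert sum(counts.values()) == len(curated_table.diseases)

    def test_planted_class_counts_recovered(self, curated_table):
        counts = classify_diseases(curated_table)
        assert {c.value: n for c, n in counts.items()} == {
            "HYPER": 73, "HYPO": 55, "MIXED": 40, "PHENOTYPE": 6}

    def test_single_disease_single_class(self):
        t = AssociationTable(records=(rec("TYR", "Vitiligo", "HYPO"),))
        counts = classify_diseases(t)
        assert counts[PhenotypeClass.HYPO] == 1
        assert sum(counts.values()) == 1

    def test_empty_table_all_zero(self):
        counts = classify_diseases(AssociationTable(records=()))
        assert all(v == 0 for v in counts.values())

    def test_gene_spanning_classes_is_multiple(self):
        t = AssociationTable(records=(rec("KIT", "Mastocytosis", "HYPER"),
                                      rec("KIT", "Piebaldism", "HYPO")))
        assert assign_gene_classes(t)["KIT"] is NetworkClass.MULTIPLE

    def test_gene_with_one_class_keeps_it(self):
        t = AssociationTable(records=(rec("TYR", "D1", "HYPO"),
                                      rec("TYR", "D2", "HYPO"),
                                      rec("TYR", "D3", "HYPO")))
        assert assign_gene_classes(t)["TYR"] is NetworkClass.HYPO

    def test_exclusive_counts_plus_multiple_cover_all_genes(self, curated_table):
        counts = gene_class_counts(assign_gene_classes(curated_table))
        assert sum(counts.values()) == len(curated_table.genes)


class TestDiseasome:
    def test_node_and_link_counts(self, curated_table):
        g = build_diseasome(curated_table)
        assert g.number_of_nodes() == (len(curated_table.genes)
                                       + len(curated_table.diseases))
        assert g.number_of_edges() == curated_table.n_associations

    def test_single_association_two_nodes_one_link(self):
        g = build_diseasome(AssociationTable(records=(rec("TYR", "Vitiligo", "HYPO"),)))
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1

    def test_shared_gene_has_degree_two(self):
        t = AssociationTable(records=(rec("TYR", "Vitiligo", "HYPO"),
                                      rec("TYR", "Oculocutaneous albinism", "HYPO")))
        g = build_diseasome(t)
        assert g.degree("TYR") == 2

    def test_graph_is_bipartite(self, curated_table):
        g = build_diseasome(curated_table)
        for u, v in g.edges():
            kinds = {g.nodes[u]["kind"], g.nodes[v]["kind"]}
            assert kinds == {"gene", "disease"}

    def test_disease_nodes_carry_their_class(self, curated_table):
        g = build_diseasome(curated_table)
        dclasses = disease_classes(curated_table)
        for d, cls in dclasses.items():
            assert g.nodes[d]["phenotype_class"] == cls.value


class TestUpset:
    def _diseasome(self, memberships):
        records = tuple(rec(g, d, "HYPO") for d, genes in memberships.items()
                        for g in genes)
        return build_diseasome(AssociationTable(records=records))

    def test_hand_enumerable_overlap(self):
        g = self._diseasome({"D1": ["G1", "G2"], "D2": ["G2", "G3"]})
        counts = {c.intersection_pattern: c.gene_count
                  for c in upset_counts(g, ["D1", "D2"])}
        assert counts == {frozenset({"D1"}): 1, frozenset({"D2"}): 1,
                          frozenset({"D1", "D2"}): 1}

    def test_disjoint_diseases_have_no_joint_pattern(self):
        g = self._diseasome({"D1": ["G1"], "D2": ["G2"]})
        patterns = {c.intersection_pattern for c in upset_counts(g, ["D1", "D2"])}
        assert frozenset({"D1", "D2"}) not in patterns

    def test_unknown_disease_is_lookup_error(self):
        g = self._diseasome({"D1": ["G1"]})
        with pytest.raises(ValidationError, match="NOPE"):
            upset_counts(g, ["NOPE"])

    def test_counts_equal_brute_force_membership_enumeration(self, curated_table):
        """Exclusive patterns over 4 synthetic diseases match exhaustive
        enumeration of every gene's membership vector."""
        g = build_diseasome(curated_table)
        subset = sorted(curated_table.diseases,
                        key=lambda d: (-g.degree(d), d))[:4]
        got = {c.intersection_pattern: c.gene_count
               for c in upset_counts(g, subset)}
        expected: dict[frozenset, int] = {}
        for gene in curated_table.genes:
            vec = frozenset(d for d in subset if g.has_edge(gene, d))
            if vec:
                expected[vec] = expected.get(vec, 0) + 1
        assert got == expected

    def test_patterns_partition_the_covered_genes(self, curated_table):
        g = build_diseasome(curated_table)
        subset = sorted(curated_table.diseases,
                        key=lambda d: (-g.degree(d), d))[:4]
        counts = upset_counts(g, subset)
        covered = set(itertools.chain.from_iterable(
            g.neighbors(d) for d in subset))
        assert sum(c.gene_count for c in counts) == len(covered)
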