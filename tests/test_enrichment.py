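"""Class profiling, hypergeometric over-representation, BH adjustment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pigmentnet.enrichment import (
    LEVEL3_CLASSES,
    benjamini_hochberg,
    class_profile,
    hypergeometric_ora,
    hypergeometric_pvalue,
)
from pigmentnet.errors import ConfigurationError, ValidationError
from pigmentnet.io import TermSet


def enumerate_upper_tail(k, n_query, k_term, n_universe):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = range(n_universe)
    term = set(range(k_term))
    hits = total = 0
    for draw in itertools.combinations(universe, n_query):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_exact_fraction_for_small_case(self):
        # N=10, K=4, n=5, k=3 -> 66/252
        assert hypergeometric_pvalue(3, 5, 4, 10) == pytest.approx(66 / 252)

    def test_zero_overlap_gives_one(self):
        assert hypergeometric_pvalue(0, 5, 4, 10) == 1.0

    def test_query_equals_term_equals_universe(self):
        assert hypergeometric_pvalue(6, 6, 6, 6) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_up_to_n12(self):
        """Tail probabilities agree with brute-force enumeration over all
        C(N, n) draws for a grid of N <= 12 configurations."""
        cases = [(n_uni, k_term, n_query, k)
                 for n_uni in (5, 8, 12)
                 for k_term in (2, n_uni // 2)
                 for n_query in (2, n_uni // 2)
                 for k in range(0, min(n_query, k_term) + 1)]
        for n_uni, k_term, n_query, k in cases:
            expected = enumerate_upper_tail(k, n_query, k_term, n_uni)
            got = hypergeometric_pvalue(k, n_query, k_term, n_uni)
            assert got == pytest.approx(expected, abs=1e-12), (n_uni, k_term,
                                                               n_query, k)

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_pvalue(5, 4, 4, 10)


class TestBenjaminiHochberg:
    def test_stepup_hand_example(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3]) == pytest.approx([0.3])

    def test_equal_ps_unchanged(self):
        assert benjamini_hochberg([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_adjusted_never_below_raw_and_capped_at_one(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        assert all(a >= r - 1e-12 for a, r in zip(adj, p))
        assert all(a <= 1.0 for a in adj)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(4)
        p = sorted(rng.uniform(size=30))
        adj = benjamini_hochberg(p)
        assert adj == sorted(adj)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.2])


def _annotation(mapping):
    return pd.DataFrame({
        "gene": list(mapping),
        "class_l1": [f"{v} / class 1" for v in mapping.values()],
        "class_l2": [f"{v} / group 1" for v in mapping.values()],
        "class_l3": list(mapping.values()),
    })


class TestClassProfile:
    def test_counts_sum_to_gene_total_and_percent_to_100(self):
        ann = _annotation({"A": "Signaling", "B": "Metabolism", "C": "Signaling"})
        prof = class_profile(["A", "B", "C"], ann, level=3)
        assert prof["count"].sum() == 3
        assert prof["percent"].sum() == pytest.approx(100.0)

    def test_all_one_class_is_100_percent(self):
        ann = _annotation({"A": "Signaling", "B": "Signaling"})
        prof = class_profile(["A", "B"], ann, level=3)
        assert list(prof["class"]) == ["Signaling"]
        assert prof.loc[0, "percent"] == pytest.approx(100.0)

    def test_empty_gene_list_gives_empty_profile(self):
        prof = class_profile([], _annotation({"A": "Signaling"}), level=3)
        assert prof.empty

    def test_unannotated_genes_fall_into_unknown(self):
        prof = class_profile(["A", "NOVEL"], _annotation({"A": "Signaling"}), level=3)
        assert set(prof["class"]) == {"Signaling", "Unknown"}

    def test_invalid_level_rejected(self):
        with pytest.raises(ConfigurationError):
            class_profile(["A"], _annotation({"A": "Signaling"}), level=4)

    def test_disjoint_sets_profiled_independently(self):
        ann = _annotation({"A": "Signaling", "B": "Metabolism"})
        pa = class_profile(["A"], ann, level=3)
        pb = class_profile(["B"], ann, level=3)
        assert pa.loc[0, "class"] == "Signaling" and pa.loc[0, "percent"] == 100.0
        assert pb.loc[0, "class"] == "Metabolism" and pb.loc[0, "percent"] == 100.0

    def test_vocabulary_has_15_level3_classes_with_unknown(self):
        assert len(LEVEL3_CLASSES) == 15 and "Unknown" in LEVEL3_CLASSES

    def test_class_exclusive_to_one_gene_set(self, spec, sim_dir, curated_table):
        """A functional class present only among one disease class's genes
        shows >0% there and is absent from the other profile."""
        from pigmentnet.diseasome import assign_gene_classes
        from pigmentnet.enrichment import read_annotation
        from pigmentnet.io import NetworkClass
        ann = read_annotation(sim_dir.annotation)
        classes = assign_gene_classes(curated_table)
        hyper = [g for g, c in classes.items() if c is NetworkClass.HYPER]
        hypo = [g for g, c in classes.items() if c is NetworkClass.HYPO]
        ph = class_profile(hyper, ann, level=3)
        po = class_profile(hypo, ann, level=3)
        only_hypo = set(po["class"]) - set(ph["class"])
        for cls in only_hypo:
            assert po.loc[po["class"] == cls, "percent"].iloc[0] > 0


class TestOra:
    def _terms(self):
        return [TermSet("WP:GOOD", "planted", "WP", frozenset({"A", "B", "C"})),
                TermSet("BP:BAD", "background", "BP", frozenset({"X", "Y"}))]

    def test_planted_term_ranks_first_and_significant(self):
        universe = [f"G{i}" for i in range(40)] + ["A", "B", "C", "X", "Y"]
        res = hypergeometric_ora(["A", "B", "C"], self._terms(), universe, alpha=0.05)
        assert res[0].term_id == "WP:GOOD" and res[0].significant
        assert res[0].overlap == 3 and res[0].term_size == 3

    def test_adjusted_at_least_raw(self):
        universe = [f"G{i}" for i in range(30)] + ["A", "B", "C", "X", "Y"]
        for r in hypergeometric_ora(["A", "X"], self._terms(), universe):
            assert r.adjusted_p >= r.p_value - 1e-12

    def test_query_outside_universe_rejected_with_offenders(self):
        with pytest.raises(ValidationError, match="ZZZ"):
            hypergeometric_ora(["A", "ZZZ"], self._terms(), ["A", "B", "C"])

    def test_empty_query_returns_no_results(self):
        assert hypergeometric_ora([], self._terms(), ["A", "B", "C", "X", "Y"]) == []

    def test_null_queries_keep_empirical_fdr_controlled(self):
        """Uniformly drawn null queries over 1000 seeded replicates call at
        most alpha + 3 SE of terms significant at BH-adjusted 0.05."""
        rng = np.random.default_rng(12345)
        universe = [f"G{i:03d}" for i in range(200)]
        terms = []
        for t in range(40):
            size = int(rng.integers(5, 40))
            members = rng.choice(universe, size=size, replace=False)
            terms.append(TermSet(f"BP:T{t:02d}", f"null {t}", "BP",
                                 frozenset(str(m) for m in members)))
        fractions = []
        for _ in range(1000):
            query = rng.choice(universe, size=20, replace=False)
            res = hypergeometric_ora([str(q) for q in query], terms, universe,
                                     alpha=0.05)
            fractions.append(sum(r.significant for r in res) / len(res))
        mean = float(np.mean(fractions))
        se = float(np.std(fractions, ddof=1) / math.sqrt(len(fractions)))
        assert mean <= 0.05 + 3 * se
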