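"""Expression-pattern decision table, set algebra and sample clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hetvig import (
    CountMatrix,
    ExpressionMatrix,
    TrioCalls,
    TrioDesign,
    classify_all,
    classify_gene,
    common_dominance_set,
    exclude_zero_genes,
    hier_cluster,
    pairwise_trio_de,
    venn_counts,
)
from hetvig.classify import CATEGORY_OF_CLASS, DOMINANCE_CLASSES

from conftest import average_linkage_oracle

CALLS = ("up", "down", "ns")


def _means_for(mp, mu_f):
    """Parental means consistent with the c_mp call, hybrid mean as given."""
    mu_m, mu_p = {"up": (10.0, 40.0), "down": (40.0, 10.0), "ns": (20.0, 20.0)}[mp]
    return mu_m, mu_f, mu_p


def _all_inputs():
    """Every call combination crossed with hybrid-mean placements."""
    for fm, fp, mp in itertools.product(CALLS, repeat=3):
        for mu_f in (5.0, 25.0, 60.0):  # below both, between, above both
            mu_m, _, mu_p = _means_for(mp, mu_f)
            yield TrioCalls("g", fm, fp, mp, mu_m, mu_f, mu_p)


class TestDecisionTable:
    def test_total_function_with_consistent_categories(self):
        """Every call/ordering combination maps to exactly one label whose
        category matches the class-set convention."""
        seen = set()
        for t in _all_inputs():
            pc = classify_gene(t)
            assert pc.category == CATEGORY_OF_CLASS[pc.class_id]
            seen.add(pc.class_id)
        # all twelve classes plus the residual buckets are reachable
        assert {str(c) for c in range(1, 13)} <= seen
        assert {"nonDEG", "conflicting"} <= seen

    def test_class_set_category_invariants(self):
        assert {c for c, cat in CATEGORY_OF_CLASS.items() if cat == "additive"} == {"1", "12"}
        assert {c for c, cat in CATEGORY_OF_CLASS.items() if cat == "ELD-paternal-high"} == {"2"}
        assert {c for c, cat in CATEGORY_OF_CLASS.items() if cat == "ELD-paternal-low"} == {"11"}
        assert {c for c, cat in CATEGORY_OF_CLASS.items() if cat == "ELD-maternal-high"} == {"4"}
        assert {c for c, cat in CATEGORY_OF_CLASS.items() if cat == "ELD-maternal-low"} == {"9"}
        assert {c for c, cat in CATEGORY_OF_CLASS.items() if cat == "transgressive-up"} == {"3", "7", "10"}
        assert {c for c, cat in CATEGORY_OF_CLASS.items() if cat == "transgressive-down"} == {"5", "6", "8"}

    def test_hybrid_tracking_lower_father_is_class_11(self):
        """Hybrid indistinguishable from the lower-expressed paternal line."""
        t = TrioCalls("g", c_fm="down", c_fp="ns", c_mp="down",
                      mu_m=40.0, mu_f=11.0, mu_p=10.0)
        pc = classify_gene(t)
        assert pc.class_id == "11"
        assert pc.category == "ELD-paternal-low"

    def test_hybrid_tracking_lower_mother_is_class_9(self):
        t = TrioCalls("g", c_fm="ns", c_fp="down", c_mp="up",
                      mu_m=10.0, mu_f=9.5, mu_p=40.0)
        assert classify_gene(t).class_id == "9"

    def test_all_ns_is_nondeg(self):
        t = TrioCalls("g", "ns", "ns", "ns", 10, 10, 10)
        assert classify_gene(t).class_id == "nonDEG"

    def test_additive_requires_betweenness(self):
        between = TrioCalls("g", "up", "down", "up", 10, 25, 40)
        assert classify_gene(between).class_id == "1"
        outside = TrioCalls("g", "up", "down", "up", 10, 45, 40)
        assert classify_gene(outside).class_id == "conflicting"

    def test_deterministic_and_order_free(self):
        inputs = list(_all_inputs())
        first = [classify_gene(t).class_id for t in inputs]
        second = [classify_gene(t).class_id for t in reversed(inputs)][::-1]
        assert first == second

    def test_reciprocal_cross_symmetry(self):
        """Swapping parental roles permutes classes 2<->4, 11<->9, 3<->10,
        6<->5, 1<->12 and fixes 7, 8, nonDEG and conflicting."""
        flip = {"up": "down", "down": "up", "ns": "ns"}
        mapping = {"2": "4", "4": "2", "11": "9", "9": "11", "3": "10",
                   "10": "3", "6": "5", "5": "6", "1": "12", "12": "1",
                   "7": "7", "8": "8", "nonDEG": "nonDEG",
                   "conflicting": "conflicting", "excluded": "excluded"}
        for t in _all_inputs():
            swapped = TrioCalls(
                t.gene_id, c_fm=t.c_fp, c_fp=t.c_fm, c_mp=flip[t.c_mp],
                mu_m=t.mu_p, mu_f=t.mu_f, mu_p=t.mu_m,
            )
            assert classify_gene(swapped).class_id == mapping[classify_gene(t).class_id]


class TestZeroExclusion:
    def _matrix(self, arr):
        return CountMatrix(pd.DataFrame(
            np.asarray(arr),
            index=pd.Index([f"g{i}" for i in range(len(arr))], name="gene_id"),
            columns=["m1", "m2", "p1", "p2", "f1", "f2"],
        ))

    def test_zero_everywhere_excluded(self, tiny_design):
        m = self._matrix([[0, 0, 0, 0, 0, 0], [1, 1, 1, 1, 1, 1]])
        assert exclude_zero_genes(m, tiny_design) == {"g0"}

    def test_single_zero_replicate_not_excluded(self, tiny_design):
        m = self._matrix([[5, 5, 5, 5, 0, 3]])
        assert exclude_zero_genes(m, tiny_design) == set()
        # but the stricter any-sample rule does exclude it
        assert exclude_zero_genes(m, tiny_design, rule="any") == {"g0"}

    def test_planted_zero_line_genes_exactly_recovered(self, tiny_design):
        rng = np.random.default_rng(4)
        arr = rng.integers(1, 100, size=(30, 6))
        planted = [2, 7, 11, 19, 28]
        for i, block in zip(planted, itertools.cycle([(0, 2), (2, 4), (4, 6)])):
            arr[i, block[0]:block[1]] = 0
        m = self._matrix(arr)
        assert exclude_zero_genes(m, tiny_design) == {f"g{i}" for i in planted}


class TestClassifyAll:
    def test_recovery_on_simulated_truth(self, small_trio):
        m, d, truth = small_trio
        tables = pairwise_trio_de(m, d)
        table, props = classify_all(tables, m, d)
        agree = (table["category"] == truth.categories()).mean()
        assert agree >= 0.8
        assert props.sum() == pytest.approx(1.0)

    def test_empty_deg_set_flagged(self, tiny_design):
        ns_table = pd.DataFrame(
            {"mean_a": [10.0], "mean_b": [10.0], "log2fc": [0.0],
             "pvalue": [1.0], "padj": [1.0], "call": ["ns"]},
            index=pd.Index(["g0"], name="gene_id"),
        )
        m = CountMatrix(pd.DataFrame(
            [[10] * 6], index=pd.Index(["g0"], name="gene_id"),
            columns=["m1", "m2", "p1", "p2", "f1", "f2"],
        ))
        tables = {k: ns_table for k in ("f_vs_m", "f_vs_p", "p_vs_m")}
        table, props = classify_all(tables, m, tiny_design)
        assert len(props) == 0
        assert (table["class"] == "nonDEG").all()

    def test_mismatched_universe_rejected(self, tiny_counts, tiny_design):
        bad = pd.DataFrame(
            {"mean_a": [1.0], "mean_b": [2.0], "log2fc": [1.0],
             "pvalue": [0.5], "padj": [0.5], "call": ["ns"]},
            index=pd.Index(["other"], name="gene_id"),
        )
        with pytest.raises(ValueError, match="universe"):
            classify_all({"f_vs_m": bad, "f_vs_p": bad, "p_vs_m": bad},
                         tiny_counts, tiny_design)


class TestSetAlgebra:
    def test_identical_sets(self):
        s = {f"g{i}" for i in range(10)}
        assert venn_counts(s, s) == (0, 10, 0)

    def test_disjoint_sets(self):
        assert venn_counts({"a", "b", "c"}, {"d", "e", "f", "g"}) == (3, 0, 4)

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(200)]
        for _ in range(20):
            a = set(rng.choice(universe, rng.integers(0, 150), replace=False))
            b = set(rng.choice(universe, rng.integers(0, 150), replace=False))
            only_a, both, only_b = venn_counts(a, b)
            assert only_a == sum(1 for g in universe if g in a and g not in b)
            assert both == sum(1 for g in universe if g in a and g in b)
            assert only_b == sum(1 for g in universe if g not in a and g in b)
            assert only_a + both == len(a) and only_b + both == len(b)

    @staticmethod
    def _class_table(classes):
        return pd.DataFrame(
            {"class": classes},
            index=pd.Index([f"g{i}" for i in range(len(classes))], name="gene_id"),
        )

    def test_single_cross_returns_its_dominance_set(self):
        tab = self._class_table(["2", "1", "9", "nonDEG", "11"])
        assert common_dominance_set([tab]) == {"g0", "g2", "g4"}

    def test_gene_dominant_in_two_of_three_crosses_excluded(self):
        t1 = self._class_table(["2"])
        t2 = self._class_table(["4"])
        t3 = self._class_table(["3"])  # transgressive in cross 3
        assert common_dominance_set([t1, t2, t3]) == set()

    def test_planted_common_dominance_genes(self):
        rng = np.random.default_rng(12)
        n = 300
        planted = set(rng.choice(n, 40, replace=False))
        others = ["1", "3", "7", "nonDEG", "conflicting", "12"]
        tables = []
        for cross in range(3):
            classes = []
            for i in range(n):
                if i in planted:
                    classes.append(rng.choice(sorted(DOMINANCE_CLASSES)))
                else:
                    # non-dominance in at least this cross
                    classes.append(others[(i + cross) % len(others)])
            tables.append(self._class_table(classes))
        assert common_dominance_set(tables) == {f"g{i}" for i in sorted(planted)}


def _expr(values, samples):
    df = pd.DataFrame(values, columns=samples)
    df.index = pd.Index([f"g{i}" for i in range(len(df))], name="gene_id")
    return ExpressionMatrix(
        values=df,
        lengths=pd.Series(1000.0, index=df.index),
        totals=pd.Series(1e6, index=df.columns),
    )


class TestHierCluster:
    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 100, size=50)
        e = _expr(np.column_stack([x, x, x[::-1]]), ["a", "b", "c"])
        z, leaves = hier_cluster(e)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(leaves) == {"a", "b", "c"}

    def test_forced_topology_identical_pair_before_anticorrelated(self):
        x = np.linspace(1, 50, 30)
        e = _expr(np.column_stack([x, x, x.max() + 1 - x]), ["s1", "s2", "s3"])
        z, _ = hier_cluster(e)
        # first merge joins the two identical samples (leaves 0 and 1)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert z[1, 2] > z[0, 2]

    def test_merge_heights_match_brute_force_average_linkage(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(200, 6))
        samples = [f"s{j}" for j in range(6)]
        e = _expr(x, samples)
        z, _ = hier_cluster(e)
        corr = np.corrcoef(x, rowvar=False)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        expected = average_linkage_oracle((dist + dist.T) / 2)
        assert np.allclose(sorted(z[:, 2]), expected, rtol=1e-10)

    def test_constant_sample_rejected(self):
        e = _expr(np.column_stack([np.arange(10.0), np.full(10, 3.0)]), ["a", "b"])
        with pytest.raises(ValueError, match="constant"):
            hier_cluster(e)
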