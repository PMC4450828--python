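"""Binomial tail, lineage sign test, GO-category scan, resampling."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from omegascan.accel import (
    GOMap,
    binomial_sf,
    category_accel_test,
    lineage_sign_test,
    resample_concatenations,
)
from omegascan.simulate import simulate_alignment
from omegascan.trees import parse_newick


def exact_binomial_sf(x: int, n: int, p_num: int, p_den: int) -> Fraction:
    """Arbitrary-precision tail by direct summation of rational pmf terms."""
    from math import comb

    p = Fraction(p_num, p_den)
    return sum(
        (Fraction(comb(n, k)) * p**k * (1 - p) ** (n - k) for k in range(x, n + 1)),
        Fraction(0),
    )


class TestBinomialSF:
    def test_half_support_example(self):
        assert binomial_sf(5, 10, 0.5) == pytest.approx(638 / 1024, abs=1e-12)

    def test_zero_successes_is_one(self):
        assert binomial_sf(0, 10, 0.3) == 1.0

    def test_all_successes_single_term(self):
        assert binomial_sf(20, 20, 0.5) == pytest.approx(2.0 ** -20, rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binomial_sf(11, 10, 0.5)
        with pytest.raises(ValueError):
            binomial_sf(1, 10, 0.0)

    @given(st.integers(0, 200), st.integers(1, 200), st.integers(1, 19))
    @settings(max_examples=40, deadline=None)
    def test_matches_arbitrary_precision_summation(self, x, n, p20):
        x = min(x, n)
        exact = exact_binomial_sf(x, n, p20, 20)
        got = binomial_sf(x, n, p20 / 20)
        assert got == pytest.approx(float(exact), rel=1e-12, abs=1e-300)

    def test_matches_scipy(self):
        # independent library cross-check on the survival function
        for x, n, p in ((3, 17, 0.2), (40, 80, 0.5), (199, 200, 0.9)):
            assert binomial_sf(x, n, p) == pytest.approx(
                binom.sf(x - 1, n, p), rel=1e-10)


def _rates_frame(omega_a, omega_b, n_a=None, n_b=None):
    rows = []
    for i, (wa, wb) in enumerate(zip(omega_a, omega_b)):
        gene = f"g{i}"
        rows.append({"gene": gene, "lineage": "A", "omega": wa,
                     "n": (n_a or [10] * len(omega_a))[i], "Ka": 0.1, "Ks": 0.2})
        rows.append({"gene": gene, "lineage": "B", "omega": wb,
                     "n": (n_b or [10] * len(omega_b))[i], "Ka": 0.1, "Ks": 0.2})
    return pd.DataFrame(rows)


class TestSignTest:
    def test_sixty_of_hundred(self):
        rng = np.random.default_rng(0)
        wa = np.where(np.arange(100) < 60, 1.0, 0.1) + rng.random(100) * 0
        wb = np.full(100, 0.5)
        res = lineage_sign_test(_rates_frame(wa, wb), "A", "B")
        assert (res.n_a_greater, res.n_informative) == (60, 100)
        assert res.p_value == pytest.approx(0.02844, abs=2e-4)

    def test_all_favor_a(self):
        res = lineage_sign_test(_rates_frame([2.0] * 80, [0.5] * 80), "A", "B")
        assert res.p_value == pytest.approx(2.0 ** -80, rel=1e-9)

    def test_symmetric_rates_not_significant(self):
        wa = [0.1, 0.9] * 25
        wb = [0.9, 0.1] * 25
        res = lineage_sign_test(_rates_frame(wa, wb), "A", "B")
        assert res.p_value > 0.3

    def test_ties_and_missing_excluded_low_power_flagged(self):
        wa = [0.5, 0.5, np.nan, 0.7]
        wb = [0.5, 0.5, 0.2, 0.3]
        res = lineage_sign_test(_rates_frame(wa, wb), "A", "B")
        assert res.n_informative == 1
        assert res.low_power


class TestCategoryScan:
    def _table(self, n_genes, nf, nl):
        rows = []
        for i in range(n_genes):
            rows.append({"gene": f"g{i}", "lineage": "F", "omega": 0.5,
                         "n": nf[i], "Ka": .1, "Ks": .2})
            rows.append({"gene": f"g{i}", "lineage": "L", "omega": 0.5,
                         "n": nl[i], "Ka": .1, "Ks": .2})
        return pd.DataFrame(rows)

    def test_more_than_twenty_is_strict(self):
        nf = nl = [5.0] * 45
        table = self._table(45, nf, nl)
        gomap = GOMap.from_pairs(
            [(f"g{i}", "cat20") for i in range(20)]
            + [(f"g{i}", "cat21") for i in range(21)]
        )
        out = category_accel_test(table, gomap, "F", "L")
        assert list(out["category"]) == ["cat21"]

    def test_null_matching_category_not_flagged(self):
        nf = nl = [6.0] * 30
        table = self._table(30, nf, nl)
        gomap = GOMap.from_pairs([(f"g{i}", "c") for i in range(25)])
        out = category_accel_test(table, gomap, "F", "L")
        assert out["p_F"].iloc[0] >= 0.5
        assert not out["accel_F"].iloc[0]

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        nf = rng.poisson(8, 60).astype(float)
        nl = rng.poisson(6, 60).astype(float)
        table = self._table(60, nf, nl)
        pairs = [(f"g{i}", "c1") for i in range(25)] + \
                [(f"g{i}", "c2") for i in range(30, 55)]
        out1 = category_accel_test(table, GOMap.from_pairs(pairs), "F", "L")
        out2 = category_accel_test(
            table.sample(frac=1, random_state=0),
            GOMap.from_pairs(pairs[::-1]), "F", "L")
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_overlap_rejected(self):
        table = self._table(5, [1.0] * 5, [1.0] * 5)
        gomap = GOMap.from_pairs([("other", "c")])
        with pytest.raises(ValueError, match="overlap"):
            category_accel_test(table, gomap, "F", "L")

    def test_gene_level_variant_runs(self):
        rng = np.random.default_rng(4)
        nf = rng.poisson(8, 40).astype(float)
        nl = rng.poisson(8, 40).astype(float)
        table = self._table(40, nf, nl)
        table.loc[table.lineage == "F", "omega"] = rng.random(40)
        table.loc[table.lineage == "L", "omega"] = rng.random(40)
        gomap = GOMap.from_pairs([(f"g{i}", "c") for i in range(25)])
        out = category_accel_test(table, gomap, "F", "L", method="genes")
        assert len(out) == 1 and 0 <= out["p_F"].iloc[0] <= 1


class TestGOMap:
    def test_inverse_index_consistent(self):
        gm = GOMap.from_pairs([("g1", "a"), ("g1", "b"), ("g2", "a")])
        assert gm.cat_to_genes["a"] == {"g1", "g2"}
        assert gm.gene_to_cats["g1"] == {"a", "b"}

    def test_tsv_roundtrip(self, tmp_path):
        gm = GOMap.from_pairs([("g1", "a"), ("g2", "a"), ("g3", "b")])
        p = tmp_path / "go.tsv"
        gm.to_tsv(p)
        back = GOMap.from_tsv(p)
        assert back.gene_to_cats == gm.gene_to_cats


@pytest.fixture(scope="module")
def genes_and_tree():
    tree = parse_newick("(A:0.2,B:0.2,C:0.4);")
    genes = [
        simulate_alignment(tree, 60, seed=500 + i, kappa=2.0,
                           branch_omegas={"default": 0.4, "A": 0.8})[0]
        for i in range(12)
    ]
    return genes, tree


class TestResample:
    def test_determinism_same_seed(self, genes_and_tree):
        genes, tree = genes_and_tree
        s1, df1 = resample_concatenations(genes, tree, ["A", "B"], k=4, R=3, seed=9)
        s2, df2 = resample_concatenations(genes, tree, ["A", "B"], k=4, R=3, seed=9)
        assert np.array_equal(s1["A"].omegas, s2["A"].omegas)
        pd.testing.assert_frame_equal(df1, df2)

    def test_identical_genes_degenerate(self, genes_and_tree):
        # all genes identical copies -> every replicate concatenates the
        # same alignment, so the estimates are identical and sd is 0
        _, tree = genes_and_tree
        gene = simulate_alignment(tree, 250, seed=555, kappa=2.0,
                                  branch_omegas=0.5)[0]
        copies = [gene] * 6
        s, _ = resample_concatenations(copies, tree, ["A"], k=3, R=3, seed=1)
        assert len(set(s["A"].omegas.tolist())) == 1
        assert s["A"].sd == pytest.approx(0.0, abs=1e-10)

    def test_k_larger_than_pool_rejected(self, genes_and_tree):
        genes, tree = genes_and_tree
        with pytest.raises(ValueError, match="exceeds"):
            resample_concatenations(genes, tree, ["A"], k=99, R=2, seed=1)

    def test_summary_counts(self, genes_and_tree):
        genes, tree = genes_and_tree
        s, df = resample_concatenations(genes, tree, ["A", "B"], k=4, R=5, seed=2)
        assert len(s["A"].omegas) == 5
        assert len(df) == 10
        d = s["A"].summary_dict()
        assert d["seed"] == 2 and d["R"] == 5
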