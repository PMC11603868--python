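import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminadiv.divergence import (
    bin_by_lfc,
    category_counts,
    classify_genes,
    lfc_correlation,
    subset_tally,
    udeg_set,
)
from laminadiv.errors import InsufficientDataError, ParameterError
from laminadiv.io import GeneAnnotation

from conftest import classify_one_oracle, make_table, random_paired_tables


class TestClassify:
    def test_toy_tables_match_hand_enumeration(self, toy_tables):
        classified = classify_genes(*toy_tables)
        got = dict(zip(classified["gene_id"], classified["category"]))
        assert got == {
            "CONVUP": "convergent_up",
            "CONVDN": "convergent_down",
            "DIVG": "divergent",
            "UNIQA": "unique_a",
            "UNIQB": "unique_b",
            "NS": "not_significant",
        }

    def test_unique_by_definition(self):
        a = make_table("A", [("G1", 1.0, 0.01), ("G2", 1.0, 0.5), ("G3", 1.0, 0.5)])
        b = make_table("B", [("G1", 0.5, 0.40), ("G2", 1.0, 0.5), ("G3", 1.0, 0.5)])
        classified = classify_genes(a, b)
        assert classified.set_index("gene_id").loc["G1", "category"] == "unique_a"

    def test_divergent_by_definition(self):
        a = make_table("A", [("G1", 1.0, 0.02), ("X", 0, 0.9), ("Y", 0, 0.9)])
        b = make_table("B", [("G1", -0.5, 0.03), ("X", 0, 0.9), ("Y", 0, 0.9)])
        classified = classify_genes(a, b)
        assert classified.set_index("gene_id").loc["G1", "category"] == "divergent"

    def test_gene_in_one_table_only_eligible_for_unique(self):
        a = make_table("A", [("ONLYA", 2.0, 0.001), ("SH", 0.1, 0.9)])
        b = make_table("B", [("SH", 0.1, 0.9)])
        classified = classify_genes(a, b)
        row = classified.set_index("gene_id").loc["ONLYA"]
        assert row["category"] == "unique_a"
        assert math.isnan(row["p_b"])
        # exclude policy drops the singleton instead
        excl = classify_genes(a, b, missing_policy="exclude")
        assert "ONLYA" not in set(excl["gene_id"])

    def test_tiers(self, toy_tables):
        classified = classify_genes(*toy_tables).set_index("gene_id")
        assert classified.loc["CONVUP", "sig_tier_a"] == "p01"
        assert classified.loc["CONVDN", "sig_tier_a"] == "p05"
        assert classified.loc["UNIQB", "sig_tier_a"] == "ns"

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_alpha_out_of_range(self, toy_tables, alpha):
        with pytest.raises(ParameterError):
            classify_genes(*toy_tables, alpha=alpha)

    def test_partition_and_symmetry(self, rng):
        """Categories partition the union; swapping laminae swaps unique_a/b
        and fixes convergent/divergent counts."""
        for _ in range(20):
            a, b = random_paired_tables(rng)
            cl_ab = classify_genes(a, b)
            cl_ba = classify_genes(b, a)
            union = a.genes | b.genes
            assert len(cl_ab) == len(union)
            assert sum(category_counts(cl_ab).values()) == len(union)
            c_ab, c_ba = category_counts(cl_ab), category_counts(cl_ba)
            assert c_ab["unique_a"] == c_ba["unique_b"]
            assert c_ab["unique_b"] == c_ba["unique_a"]
            assert c_ab["divergent"] == c_ba["divergent"]
            assert c_ab["convergent_up"] == c_ba["convergent_up"]
            assert c_ab["convergent_down"] == c_ba["convergent_down"]

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            a, b = random_paired_tables(rng)
            classified = classify_genes(a, b)
            pa = a.data.set_index("gene_id")
            pb = b.data.set_index("gene_id")
            for _, row in classified.iterrows():
                g = row["gene_id"]
                expected = classify_one_oracle(
                    pa["p_value"].get(g), pa["lfc"].get(g, 0.0),
                    pb["p_value"].get(g), pb["lfc"].get(g, 0.0),
                )
                assert row["category"] == expected, g


class TestUdegSet:
    def test_appending_identity(self, rng):
        """|uDEG_x| - |unique_x| = |divergent|, and divergent genes appear in
        both laminae's uDEG sets."""
        a, b = random_paired_tables(rng, n_genes=200)
        classified = classify_genes(a, b)
        counts = category_counts(classified)
        ua, ub = udeg_set(classified, "a"), udeg_set(classified, "b")
        assert len(ua) == counts["unique_a"] + counts["divergent"]
        assert len(ub) == counts["unique_b"] + counts["divergent"]
        div = set(classified.loc[classified["category"] == "divergent", "gene_id"])
        assert div <= ua and div <= ub

    def test_no_divergent_equals_unique(self, toy_tables):
        a, b = toy_tables
        classified = classify_genes(a, b)
        classified = classified[classified["category"] != "divergent"]
        assert udeg_set(classified, "a") == set(
            classified.loc[classified["category"] == "unique_a", "gene_id"]
        )

    def test_bad_lamina(self, toy_tables):
        with pytest.raises(ParameterError):
            udeg_set(classify_genes(*toy_tables), "c")


class TestBinByLfc:
    def _classified(self, lfcs):
        rows = [(f"G{i}", lfc, 0.01) for i, lfc in enumerate(lfcs)]
        a = make_table("A", rows)
        b = make_table("B", [(f"G{i}", 0.0, 0.9) for i in range(len(lfcs))])
        return classify_genes(a, b)

    def test_boundary_arithmetic(self):
        bins = bin_by_lfc(self._classified([0.30]), "a")
        assert bins.iloc[0][["bin_low", "bin_high"]].tolist() == [0.25, 0.50]

    def test_half_open_on_boundary_nearer_zero(self):
        bins = bin_by_lfc(self._classified([0.25]), "a")
        assert bins.iloc[0]["bin_low"] == pytest.approx(0.25)
        neg = bin_by_lfc(self._classified([-0.25]), "a")
        assert neg.iloc[0][["bin_low", "bin_high"]].tolist() == [-0.50, -0.25]

    def test_counts_match_hand_histogram(self):
        lfcs = [0.1, 0.2, 0.3, 0.26, 0.55, -0.1, -0.3, -0.75, 1.2, -0.26]
        bins = bin_by_lfc(self._classified(lfcs), "a")
        table = {
            (row["bin_low"], row["direction"]): row["count"]
            for _, row in bins.iterrows()
        }
        assert table[(0.0, "up")] == 2
        assert table[(0.25, "up")] == 2
        assert table[(0.5, "up")] == 1
        assert table[(1.0, "up")] == 1
        assert table[(-0.25, "down")] == 1
        assert table[(-0.5, "down")] == 2
        assert table[(-1.0, "down")] == 1
        assert bins["count"].sum() == len(lfcs)

    def test_bad_width(self, toy_tables):
        with pytest.raises(ParameterError):
            bin_by_lfc(classify_genes(*toy_tables), "a", width=0.0)

    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=30), st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_totals_preserved(self, lfcs, width):
        bins = bin_by_lfc(self._classified(lfcs), "a", width=width)
        assert bins["count"].sum() == len(lfcs)


class TestCorrelation:
    def test_identical_vectors(self):
        a = make_table("A", [("G1", 1, 0.5), ("G2", 2, 0.5), ("G3", -1, 0.5)])
        b = make_table("B", [("G1", 1, 0.5), ("G2", 2, 0.5), ("G3", -1, 0.5)])
        assert lfc_correlation(a, b) == pytest.approx(1.0)

    def test_negated_vectors(self):
        a = make_table("A", [("G1", 1, 0.5), ("G2", 2, 0.5), ("G3", -1, 0.5)])
        b = make_table("B", [("G1", -1, 0.5), ("G2", -2, 0.5), ("G3", 1, 0.5)])
        assert lfc_correlation(a, b) == pytest.approx(-1.0)

    def test_hand_computed_four_pairs(self):
        # pairs (1,2),(2,1),(3,5),(4,4): direct textbook formula gives
        # r = Sxy/sqrt(Sxx*Syy) = 5/sqrt(5*10) ~ 0.7071
        a = make_table("A", [("G1", 1, 0.5), ("G2", 2, 0.5), ("G3", 3, 0.5), ("G4", 4, 0.5)])
        b = make_table("B", [("G1", 2, 0.5), ("G2", 1, 0.5), ("G3", 5, 0.5), ("G4", 4, 0.5)])
        x, y = np.array([1, 2, 3, 4.0]), np.array([2, 1, 5, 4.0])
        expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert lfc_correlation(a, b) == pytest.approx(expected)

    def test_too_few_shared_genes(self):
        a = make_table("A", [("G1", 1, 0.5), ("G2", 2, 0.5)])
        b = make_table("B", [("G1", 1, 0.5), ("G3", 2, 0.5)])
        with pytest.raises(InsufficientDataError):
            lfc_correlation(a, b)


class TestSubsetTally:
    def _annotation(self):
        ann = GeneAnnotation()
        for i in range(7):
            ann.table[f"NC{i}"] = ("21", "ncRNA")
        for i in range(7):
            ann.table[f"PC{i}"] = ("21", "protein_coding")
        ann.table["OFF"] = ("1", "protein_coding")
        return ann

    def test_half_ncrna(self):
        ann = self._annotation()
        genes = set(ann.table) | {"UNANNOTATED"}
        tally = subset_tally(genes, ann, "21")
        assert tally.n_total == 14
        assert tally.counts["ncRNA"] == 7
        assert tally.fractions["ncRNA"] == pytest.approx(0.5)

    def test_empty_subset(self):
        tally = subset_tally(set(), self._annotation(), "21")
        assert tally.n_total == 0
        assert tally.fractions is None

    def test_all_protein_coding(self):
        ann = self._annotation()
        tally = subset_tally({"PC0", "PC1", "PC2"}, ann, "21")
        assert tally.fractions["protein_coding"] == pytest.approx(1.0)

    def test_unfiltered_counts_unknown(self):
        ann = self._annotation()
        tally = subset_tally({"PC0", "MYSTERY"}, ann, None)
        assert tally.counts["unknown"] == 1
        assert sum(tally.counts.values()) == tally.n_total == 2
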