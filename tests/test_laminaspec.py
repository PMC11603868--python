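import itertools

import networkx as nx
import pandas as pd
import pytest

from laminadiv.errors import ConfigurationError, ValidationError
from laminadiv.laminaspec import (
    COHORTS,
    FLAGS,
    LABELS,
    build_flag_matrix,
    filter_terms_by_keyword,
    label_ancestors,
    label_flag_vector,
    label_terms,
)


def vector(**overrides):
    flags = {c: "not_significant" for c in COHORTS}
    flags.update(overrides)
    return flags


def result_frame(cohort, rows):
    """rows: (set_id, p, z)"""
    return pd.DataFrame(
        [
            {"set_id": sid, "cohort": cohort, "p_value": p, "adj_p": p, "activation_z": z}
            for sid, p, z in rows
        ]
    )


class TestFlagMatrix:
    def _results(self):
        return {
            "a_unique": result_frame("a_unique", [("T1", 0.01, 2.0), ("T2", 0.2, 1.0)]),
            "b_unique": result_frame("b_unique", [("T1", 0.5, 0.0)]),
            "a_all": result_frame("a_all", [("T2", 0.03, -1.5)]),
            "b_all": result_frame("b_all", [("T3", 0.02, float("nan"))]),
            "convergent": result_frame("convergent", [("T3", 0.01, 0.0)]),
        }

    def test_matrix_matches_hand_tabulation(self):
        matrix = build_flag_matrix(self._results(), alpha=0.05)
        assert list(matrix.columns) == list(COHORTS)
        assert matrix.loc["T1"].tolist() == [
            "significant_up", "not_significant", "not_significant",
            "not_significant", "not_significant",
        ]
        assert matrix.loc["T2", "a_unique"] == "not_significant"  # p=0.2
        assert matrix.loc["T2", "a_all"] == "significant_down"
        assert matrix.loc["T3", "b_all"] == "significant_nodir"  # z is NA
        assert matrix.loc["T3", "convergent"] == "significant_nodir"  # z == 0

    def test_missing_cohort_is_config_error(self):
        results = self._results()
        del results["convergent"]
        with pytest.raises(ConfigurationError, match="convergent"):
            build_flag_matrix(results)

    def test_term_significant_everywhere(self):
        results = {
            c: result_frame(c, [("T", 0.001, 1.0)]) for c in COHORTS
        }
        matrix = build_flag_matrix(results)
        assert (matrix.loc["T"] == "significant_up").all()


class TestLabeling:
    def test_layer_specific_base_rule(self):
        assert (
            label_flag_vector(vector(a_unique="significant_up", a_all="significant_up"))
            == "a_layer_specific"
        )

    def test_layer_specific_admits_opposite_direction(self):
        flags = vector(
            a_unique="significant_up",
            a_all="significant_up",
            b_all="significant_down",
        )
        assert label_flag_vector(flags) == "a_layer_specific"
        # strict mode requires the other lamina to be silent; opposing full-list
        # signals then read as divergence between laminae
        assert label_flag_vector(flags, strict=True) == "divergent_between_laminae"

    def test_unique_only(self):
        assert label_flag_vector(vector(a_unique="significant_down")) == "a_unique_only"
        assert label_flag_vector(vector(b_unique="significant_up")) == "b_unique_only"

    def test_genotype_shared_and_divergent(self):
        shared = vector(a_all="significant_up", b_all="significant_up")
        assert label_flag_vector(shared) == "genotype_shared"
        diverg = vector(a_all="significant_up", b_all="significant_down")
        assert label_flag_vector(diverg) == "divergent_between_laminae"

    def test_totality_and_uniqueness(self):
        """Every one of the 4^5 flag vectors receives exactly one valid label."""
        for combo in itertools.product(FLAGS, repeat=len(COHORTS)):
            flags = dict(zip(COHORTS, combo))
            label = label_flag_vector(flags)
            assert label in LABELS

    def test_mirror_symmetry(self):
        """Swapping the laminae swaps a_* and b_* labels and fixes the rest."""
        swap_label = {
            "a_layer_specific": "b_layer_specific",
            "b_layer_specific": "a_layer_specific",
            "a_unique_only": "b_unique_only",
            "b_unique_only": "a_unique_only",
        }
        for combo in itertools.product(FLAGS, repeat=len(COHORTS)):
            flags = dict(zip(COHORTS, combo))
            swapped = {
                "a_unique": flags["b_unique"],
                "b_unique": flags["a_unique"],
                "a_all": flags["b_all"],
                "b_all": flags["a_all"],
                "convergent": flags["convergent"],
            }
            lab = label_flag_vector(flags)
            assert label_flag_vector(swapped) == swap_label.get(lab, lab)

    def test_label_terms_frame(self):
        matrix = pd.DataFrame(
            [vector(a_unique="significant_up", a_all="significant_up"), vector()],
            index=["T1", "T2"],
        )[list(COHORTS)]
        labels = label_terms(matrix)
        assert labels.set_index("term_id").loc["T1", "label"] == "a_layer_specific"
        assert labels.set_index("term_id").loc["T2", "label"] == "unlabeled"


class TestAncestors:
    def _labels(self, mapping):
        return pd.DataFrame(
            [{"term_id": t, "label": l} for t, l in mapping.items()],
            columns=["term_id", "label"],
        )

    def test_chain(self):
        graph = nx.DiGraph([("C", "B"), ("B", "A")])
        labels = self._labels(
            {"C": "a_layer_specific", "B": "genotype_shared", "A": "unlabeled"}
        )
        out = label_ancestors(labels, graph, ["C"])
        assert out[["ancestor", "label"]].values.tolist() == [
            ["A", "unlabeled"],
            ["B", "genotype_shared"],
        ]

    def test_root_has_no_ancestors(self):
        graph = nx.DiGraph([("C", "B"), ("B", "A")])
        out = label_ancestors(self._labels({}), graph, ["A"])
        assert len(out) == 0

    def test_diamond_listed_once_and_order_invariant(self):
        edges = [("D", "B"), ("D", "C"), ("B", "A"), ("C", "A")]
        g1 = nx.DiGraph(edges)
        g2 = nx.DiGraph(list(reversed(edges)))
        out1 = label_ancestors(self._labels({}), g1, ["D"])
        out2 = label_ancestors(self._labels({}), g2, ["D"])
        assert out1["ancestor"].tolist() == ["A", "B", "C"]
        assert out1.equals(out2)

    def test_focus_term_absent(self):
        graph = nx.DiGraph([("B", "A")])
        with pytest.raises(ValidationError, match="ZZZ"):
            label_ancestors(self._labels({}), graph, ["ZZZ"])

    def test_cyclic_graph_rejected(self):
        graph = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(ValidationError, match="cycle"):
            label_ancestors(self._labels({}), graph, ["A"])


class TestKeywordFilter:
    def test_substring_tagging(self):
        out = filter_terms_by_keyword(
            {"T1": "autophagosome assembly"}, {"autophag": "autophagy"}
        )
        assert out.iloc[0]["category"] == "autophagy"

    def test_no_match_excluded(self):
        out = filter_terms_by_keyword({"T1": "lipid storage"}, {"autophag": "autophagy"})
        assert len(out) == 0

    def test_first_keyword_in_config_order_wins(self):
        out = filter_terms_by_keyword(
            {"T1": "synaptic receptor signaling"},
            {"synap": "activity", "receptor": "NIR"},
        )
        assert out.iloc[0]["category"] == "activity"
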