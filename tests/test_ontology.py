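"""Hierarchy construction, true-path closure, per-protein leaves, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pill import (
    AnnotationMatrix,
    LabelHierarchy,
    OntologyError,
    conditional_probability,
    leaf_labels_of_protein,
    parse_funcat_labels,
    parse_obo,
    relationship_statistics,
    true_path_closure,
)
from conftest import random_closed_corpus

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: a
namespace: biological_process

[Term]
id: GO:0000002
name: b
namespace: biological_process
is_a: GO:0000001 ! a

[Term]
id: GO:0000003
name: c
namespace: biological_process
is_a: GO:0000001 ! a

[Term]
id: GO:0000004
name: d
namespace: biological_process
is_a: GO:0000002 ! b
is_a: GO:0000003 ! c

[Term]
id: GO:0000005
name: gone
namespace: biological_process
is_obsolete: true

[Term]
id: GO:0000006
name: other
namespace: molecular_function
"""


class TestParseFuncat:
    def test_prefixes_become_ancestors(self):
        Y, H = parse_funcat_labels([("p1", "01.03.02")])
        assert H.labels == {"01", "01.03", "01.03.02"}
        assert H.parents("01.03.02") == {"01.03"}
        assert H.parents("01.03") == {"01"}
        assert Y.Y[0, Y.label_index("01.03.02")] == 1
        # not yet closed
        assert Y.Y[0, Y.label_index("01")] == 0

    def test_empty_input(self):
        Y, H = parse_funcat_labels([])
        assert Y.n == 0 and Y.K == 0 and len(H) == 0

    def test_shared_label_two_proteins(self):
        Y, H = parse_funcat_labels([("p1", "01"), ("p2", "01")])
        assert Y.K == 1 and Y.Y.sum() == 2

    def test_duplicates_collapse(self):
        Y, _ = parse_funcat_labels([("p1", "01"), ("p1", "01")])
        assert Y.Y.sum() == 1

    def test_malformed_identifier_names_row(self):
        with pytest.raises(OntologyError, match="row 1"):
            parse_funcat_labels([("p1", "01"), ("p2", "01..02")])


class TestParseObo:
    def test_is_a_edges_and_obsolete(self):
        H = parse_obo(DIAMOND_OBO, namespace="biological_process")
        assert "GO:0000005" not in H  # obsolete
        assert "GO:0000006" not in H  # other namespace
        assert H.parents("GO:0000002") == {"GO:0000001"}

    def test_diamond_ancestors(self):
        H = parse_obo(DIAMOND_OBO, namespace="biological_process")
        assert H.parents("GO:0000004") == {"GO:0000002", "GO:0000003"}
        assert H.ancestors("GO:0000004") == {"GO:0000001", "GO:0000002", "GO:0000003"}

    def test_unknown_namespace_warns_empty(self):
        with pytest.warns(UserWarning):
            H = parse_obo(DIAMOND_OBO, namespace="nope")
        assert len(H) == 0


class TestHierarchy:
    def test_cycle_rejected(self):
        with pytest.raises(OntologyError, match="cycl"):
            LabelHierarchy({"a": {"b"}, "b": {"a"}})

    def test_self_parent_rejected(self):
        with pytest.raises(OntologyError):
            LabelHierarchy({"a": {"a"}})

    def test_roots_and_descendants(self):
        H = LabelHierarchy({"a": set(), "b": {"a"}, "c": {"b"}})
        assert H.roots() == {"a"}
        assert H.descendants("a") == {"b", "c"}

    def test_top_level_siblings_via_virtual_root(self):
        # FunCat: '01' and '12' have no explicit common parent yet '12'
        # acts as an uncle of '01.03'
        _, H = parse_funcat_labels([("p", "01.03"), ("p", "12")])
        assert "12" in H.siblings("01")
        assert "12" in H.uncles("01.03")


class TestClosure:
    def test_chain(self):
        Y, H = parse_funcat_labels([("p", "01.03.02")])
        closed = true_path_closure(Y, H)
        assert closed.labels_of("p") == {"01", "01.03", "01.03.02"}

    def test_diamond_dag(self):
        H = LabelHierarchy({"A": set(), "B": {"A"}, "C": {"A"}, "D": {"B", "C"}})
        Y = AnnotationMatrix(["p"], ["A", "B", "C", "D"], np.array([[0, 0, 0, 1]]))
        closed = true_path_closure(Y, H)
        assert closed.labels_of("p") == {"A", "B", "C", "D"}

    def test_unknown_label_listed(self):
        H = LabelHierarchy({"A": set()})
        Y = AnnotationMatrix(["p"], ["A", "Z"], np.array([[1, 1]]))
        with pytest.raises(OntologyError, match="Z"):
            true_path_closure(Y, H)

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent_and_monotone(self, seed):
        Y, H = random_closed_corpus(seed, n_proteins=15)
        once = true_path_closure(Y, H)
        twice = true_path_closure(once, H)
        assert np.array_equal(once.Y, twice.Y)
        # adding an annotation never removes a closed one
        rng = np.random.default_rng(seed)
        Y2 = once.copy()
        Y2.Y[rng.integers(Y2.n), rng.integers(Y2.K)] = 1
        closed2 = true_path_closure(Y2, H)
        assert (closed2.Y >= once.Y).all()

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_member_counts_grow_toward_ancestors(self, seed):
        Y, H = random_closed_corpus(seed, n_proteins=15)
        for label in Y.labels:
            for anc in H.ancestors(label):
                if anc in set(Y.labels):
                    assert Y.member_count(label) <= Y.member_count(anc)


class TestLeafLabels:
    def test_deepest_label_is_leaf(self):
        Y, H = parse_funcat_labels([("p1", "01.03.02")])
        closed = true_path_closure(Y, H)
        assert leaf_labels_of_protein(closed, H, "p1") == {"01.03.02"}

    def test_leafness_is_per_protein(self):
        # '12.04' is a leaf for p2 but not for p1, which carries a descendant
        rows = [("p1", "12.04.02"), ("p2", "12.04")]
        Y, H = parse_funcat_labels(rows)
        closed = true_path_closure(Y, H)
        assert "12.04" not in leaf_labels_of_protein(closed, H, "p1")
        assert leaf_labels_of_protein(closed, H, "p2") == {"12.04"}

    def test_no_labels_empty_set(self):
        Y, H = parse_funcat_labels([("p1", "01")])
        Y.Y[:] = 0
        assert leaf_labels_of_protein(Y, H, "p1") == frozenset()

    def test_unknown_protein(self):
        Y, H = parse_funcat_labels([("p1", "01")])
        with pytest.raises(OntologyError):
            leaf_labels_of_protein(Y, H, "nope")

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_leaves_form_antichain(self, seed):
        Y, H = random_closed_corpus(seed, n_proteins=10)
        for p in Y.proteins:
            leaves = leaf_labels_of_protein(Y, H, p)
            for a in leaves:
                for b in leaves:
                    if a != b:
                        assert not H.is_ancestor(a, b)


class TestRelationshipStatistics:
    def test_worked_conditional_probability(self):
        # 272 proteins with '40', 170 with both '40' and '43' -> 62.5%
        n = 5700
        proteins = [f"p{i}" for i in range(n)]
        Y = np.zeros((n, 2), dtype=np.int8)
        Y[:272, 0] = 1          # '40'
        Y[102:102 + 448, 1] = 1  # '43'; overlap with '40' = 170
        A = AnnotationMatrix(proteins, ["40", "43"], Y)
        assert (A.Y[:, 0] & A.Y[:, 1]).sum() == 170
        assert conditional_probability(A, "43", "40") == pytest.approx(170 / 272)
        assert conditional_probability(A, "43", "40") * 100 == pytest.approx(62.5)

    def test_toy_chain_with_uncle(self):
        # A(10 members) -> B(4) -> C(2); B'(3) sibling of B; |N(C) ∩ N(B')| = 1
        H = LabelHierarchy({"A": set(), "B": {"A"}, "B'": {"A"}, "C": {"B"}})
        n = 12
        Y = np.zeros((n, 4), dtype=np.int8)
        labels = ["A", "B", "B'", "C"]
        Y[:10, 0] = 1
        Y[:4, 1] = 1
        Y[3:6, 2] = 1   # B' = {p3, p4, p5}; C = {p0, p1}... overlap with C below
        Y[:2, 3] = 1
        # make |N(C) ∩ N(B')| = 1: shift B' to include p1
        Y[:, 2] = 0
        Y[[1, 4, 5], 2] = 1
        A = AnnotationMatrix([f"p{i}" for i in range(n)], labels, Y)
        table = relationship_statistics(A, H, drop_zeros=False)
        def p(label, relation, relative):
            row = table[(table.label == label) & (table.relation == relation)
                        & (table.relative == relative)]
            assert len(row) == 1
            return float(row.probability.iloc[0])
        assert p("C", "parent", "B") == pytest.approx(0.5)
        assert p("C", "grandparent", "A") == pytest.approx(0.2)
        assert p("C", "uncle", "B'") == pytest.approx(1 / 3)

    def test_full_membership_gives_probability_one(self, toy_corpus):
        Y, H = toy_corpus
        Y2 = Y.copy()
        Y2.Y[:, Y2.label_index("A.1")] = Y2.Y[:, Y2.label_index("A")]
        table = relationship_statistics(Y2, H, drop_zeros=False)
        row = table[(table.label == "A.1") & (table.relation == "parent")]
        assert float(row.probability.iloc[0]) == 1.0

    def test_absent_relatives_yield_no_rows(self, toy_corpus):
        Y, H = toy_corpus
        table = relationship_statistics(Y, H, drop_zeros=False)
        # A has no parent in the hierarchy: no parent rows for it
        assert table[(table.label == "A") & (table.relation == "parent")].empty

    @settings(derandomize=True, max_examples=15)
    @given(seed=st.integers(0, 10_000))
    def test_parent_bound_exceeds_grandparent_bound(self, seed):
        """On closed annotations p(s|par) >= p(s|gpar) along each parent path."""
        Y, H = random_closed_corpus(seed, n_proteins=25)
        table = relationship_statistics(Y, H, drop_zeros=False)
        by = {(r.label, r.relation, r.relative): r.probability for r in table.itertuples()}
        for s in Y.labels:
            if s not in H:
                continue
            for par in H.parents(s):
                for gpar in H.parents(par):
                    pp = by.get((s, "parent", par))
                    pg = by.get((s, "grandparent", gpar))
                    if pp is not None and pg is not None:
                        assert pp >= pg - 1e-12
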