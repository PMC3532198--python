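"""Wang semantic similarity: S-values, term and gene similarity, matrix."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dddkit.io_formats import GeneAnnotation, OntologyGraph
from dddkit.semsim import (build_similarity_matrix, combined_gene_similarity,
                           gene_similarity, s_values, term_similarity)
from conftest import make_ontology


def s_values_oracle(anchor, ontology, weights):
    """Brute force: max over all upward paths of the weight product."""
    g = ontology.graph
    table = {anchor: 1.0}
    for term in {anchor} | ontology.ancestors(anchor):
        if term == anchor:
            continue
        best = 0.0
        for path in nx.all_simple_paths(g, anchor, term):
            prod = 1.0
            for child, parent in zip(path, path[1:]):
                prod *= weights[g.edges[child, parent]["relation"]]
            best = max(best, prod)
        table[term] = best
    return table


def random_dag(rng, n_terms, namespace="BP"):
    g = nx.DiGraph()
    terms = [f"T{i}" for i in range(n_terms)]
    g.add_node(terms[0], name=terms[0], namespace=namespace)
    for i in range(1, n_terms):
        g.add_node(terms[i], name=terms[i], namespace=namespace)
        n_parents = 1 + (rng.random() < 0.4 and i > 1)
        for p in rng.choice(i, size=n_parents, replace=False):
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            g.add_edge(terms[i], terms[int(p)], relation=rel)
    return OntologyGraph(graph=g)


class TestSValues:
    def test_root_term_alone(self, chain_ontology):
        table = s_values("R", chain_ontology)
        assert dict(table.s) == {"R": 1.0}
        assert table.sv == 1.0

    def test_chain_hand_values(self, chain_ontology):
        table = s_values("A", chain_ontology)
        assert table.s["A"] == 1.0
        assert table.s["B"] == pytest.approx(0.8)
        assert table.s["R"] == pytest.approx(0.64)
        assert table.sv == pytest.approx(2.44)

    def test_diamond_takes_max_over_paths(self, diamond_ontology):
        # paths to R: is_a,is_a = 0.64 vs part_of,is_a = 0.48
        table = s_values("A", diamond_ontology)
        assert table.s["R"] == pytest.approx(0.64)

    def test_matches_path_enumeration_oracle_on_random_dags(self):
        rng = np.random.default_rng(8)
        weights = {"is_a": 0.8, "part_of": 0.6}
        for n in (5, 12, 30):
            ontology = random_dag(rng, n)
            for anchor in ontology.terms:
                table = s_values(anchor, ontology, weights)
                oracle = s_values_oracle(anchor, ontology, weights)
                assert set(table.s) == set(oracle)
                for term, expected in oracle.items():
                    assert table.s[term] == pytest.approx(expected,
                                                          abs=1e-12)

    def test_s_monotone_non_increasing_upward(self):
        rng = np.random.default_rng(9)
        ontology = random_dag(rng, 20)
        for anchor in ontology.terms[:5]:
            table = s_values(anchor, ontology)
            for child, parent in ontology.graph.subgraph(table.s).edges:
                assert table.s[parent] <= table.s[child] + 1e-12


class TestTermSimilarity:
    def test_self_similarity_is_one(self, chain_ontology):
        assert term_similarity("A", "A", chain_ontology) == pytest.approx(1.0)

    def test_sibling_hand_value(self, sibling_ontology):
        # shared {R}: (0.8 + 0.8) / (1.8 + 1.8)
        assert term_similarity("A", "B", sibling_ontology) == pytest.approx(
            4 / 9)

    def test_disconnected_components_score_zero(self):
        ontology = make_ontology([("A", "R1", "is_a"), ("B", "R2", "is_a")])
        assert term_similarity("A", "B", ontology) == 0.0

    def test_cross_namespace_rejected(self):
        g = nx.DiGraph()
        g.add_node("A", name="A", namespace="BP")
        g.add_node("B", name="B", namespace="MF")
        ontology = OntologyGraph(graph=g)
        with pytest.raises(ValueError, match="namespace"):
            term_similarity("A", "B", ontology)

    def test_bounded_and_symmetric_on_random_dag(self):
        rng = np.random.default_rng(10)
        ontology = random_dag(rng, 15)
        for a, b in itertools.combinations(ontology.terms, 2):
            s_ab = term_similarity(a, b, ontology)
            s_ba = term_similarity(b, a, ontology)
            assert 0.0 <= s_ab <= 1.0
            assert s_ab == pytest.approx(s_ba)


class TestGeneSimilarity:
    @staticmethod
    def annotate(**genes):
        return GeneAnnotation(annotations={
            g: {"BP": frozenset(ts)} for g, ts in genes.items()})

    def test_identical_annotation_sets_score_one(self, sibling_ontology):
        ann = self.annotate(g1={"A", "B"}, g2={"A", "B"})
        assert gene_similarity("g1", "g2", "BP", ann,
                               sibling_ontology) == pytest.approx(1.0)

    def test_singleton_versus_pair_formula(self, sibling_ontology):
        # gi={A}, gj={A,B}: (1 + 1 + s) / 3 with s = Sim(A,B)
        ann = self.annotate(g1={"A"}, g2={"A", "B"})
        s = term_similarity("A", "B", sibling_ontology)
        expected = (1 + 1 + s) / 3
        assert gene_similarity("g1", "g2", "BP", ann,
                               sibling_ontology) == pytest.approx(expected)

    def test_unannotated_namespace_is_missing(self, sibling_ontology):
        ann = self.annotate(g1={"A"}, g2=set())
        assert np.isnan(gene_similarity("g1", "g2", "BP", ann,
                                        sibling_ontology))

    def test_unknown_gene_rejected(self, sibling_ontology):
        ann = self.annotate(g1={"A"})
        with pytest.raises(KeyError):
            gene_similarity("g1", "nope", "BP", ann, sibling_ontology)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_identity_and_symmetry_on_random_sets(self, data):
        rng = np.random.default_rng(11)
        ontology = random_dag(rng, 12)
        terms = ontology.terms
        set1 = data.draw(st.sets(st.sampled_from(terms), min_size=1,
                                 max_size=4))
        set2 = data.draw(st.sets(st.sampled_from(terms), min_size=1,
                                 max_size=4))
        ann = GeneAnnotation(annotations={
            "g1": {"BP": frozenset(set1)},
            "g2": {"BP": frozenset(set2)},
            "g3": {"BP": frozenset(set1)}})
        assert gene_similarity("g1", "g3", "BP", ann,
                               ontology) == pytest.approx(1.0)
        assert gene_similarity("g1", "g2", "BP", ann,
                               ontology) == pytest.approx(
            gene_similarity("g2", "g1", "BP", ann, ontology))


class TestCombinedSimilarity:
    def test_single_namespace_passthrough(self, sibling_ontology):
        ann = GeneAnnotation(annotations={
            "g1": {"BP": frozenset({"A"})},
            "g2": {"BP": frozenset({"B"})}})
        score, used = combined_gene_similarity("g1", "g2", ann,
                                               sibling_ontology)
        assert used == ("BP",)
        assert score == pytest.approx(
            gene_similarity("g1", "g2", "BP", ann, sibling_ontology))

    def test_mean_of_available_namespaces(self):
        bp = make_ontology([("A", "R", "is_a")], namespace="BP")
        mf = make_ontology([("X", "S", "is_a")], namespace="MF")
        g = nx.compose(bp.graph, mf.graph)
        ontology = OntologyGraph(graph=g)
        ann = GeneAnnotation(annotations={
            "g1": {"BP": frozenset({"A"}), "MF": frozenset({"X"}),
                   "CC": frozenset()},
            "g2": {"BP": frozenset({"R"}), "MF": frozenset({"X"}),
                   "CC": frozenset()}})
        score, used = combined_gene_similarity("g1", "g2", ann, ontology)
        bp_s = gene_similarity("g1", "g2", "BP", ann, ontology)
        assert used == ("BP", "MF")
        assert score == pytest.approx((bp_s + 1.0) / 2)

    def test_no_shared_namespace_is_missing(self, sibling_ontology):
        ann = GeneAnnotation(annotations={
            "g1": {"BP": frozenset({"A"})},
            "g2": {"BP": frozenset()}})
        score, used = combined_gene_similarity("g1", "g2", ann,
                                               sibling_ontology)
        assert np.isnan(score) and used == ()


class TestSimilarityMatrix:
    def test_single_gene_identity_matrix(self, sibling_ontology):
        ann = GeneAnnotation(annotations={"g1": {"BP": frozenset({"A"})}})
        matrix = build_similarity_matrix(["g1"], ["g1"], ann,
                                         sibling_ontology)
        assert matrix.shape == (1, 1)
        assert matrix.iloc[0, 0] == pytest.approx(1.0)

    def test_unannotated_rows_dropped_with_warning(self, sibling_ontology):
        ann = GeneAnnotation(annotations={
            "g1": {"BP": frozenset({"A"})},
            "bare": {"BP": frozenset()}})
        with pytest.warns(UserWarning, match="without usable"):
            matrix = build_similarity_matrix(["g1", "bare"], ["g1"], ann,
                                             sibling_ontology)
        assert list(matrix.index) == ["g1"]

    def test_invariant_under_list_reordering(self):
        rng = np.random.default_rng(12)
        ontology = random_dag(rng, 10)
        terms = ontology.terms
        ann = GeneAnnotation(annotations={
            f"g{i}": {"BP": frozenset(rng.choice(terms, size=2))}
            for i in range(4)})
        genes = [f"g{i}" for i in range(4)]
        m1 = build_similarity_matrix(genes, genes, ann, ontology)
        m2 = build_similarity_matrix(genes[::-1], genes[::-1], ann, ontology)
        assert np.allclose(m1.values,
                           m2.loc[m1.index, m1.columns].values)

    def test_planted_groups_separate(self):
        from dddkit.synthetic import two_group_similarity_matrix
        matrix, groups = two_group_similarity_matrix(seed=2)
        g0 = [g for g, k in groups.items() if k == 0]
        g1 = [g for g, k in groups.items() if k == 1]
        ref0 = matrix.columns[:len(matrix.columns) // 2]
        ref1 = matrix.columns[len(matrix.columns) // 2:]
        within = (matrix.loc[g0, ref0].mean().mean()
                  + matrix.loc[g1, ref1].mean().mean()) / 2
        between = (matrix.loc[g0, ref1].mean().mean()
                   + matrix.loc[g1, ref0].mean().mean()) / 2
        assert within > between + 0.2
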