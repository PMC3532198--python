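"""Shared fixtures: toy ontologies and small library tables."""

import networkx as nx
import pandas as pd
import pytest

from dddkit.io_formats import GeneAnnotation, LibraryTable, OntologyGraph, PoolManifest


def make_ontology(edges, namespace="BP", extra_nodes=()):
    """Build an OntologyGraph from (child, parent, relation) triples."""
    g = nx.DiGraph()
    for child, parent, rel in edges:
        for node in (child, parent):
            if node not in g:
                g.add_node(node, name=node, namespace=namespace)
        g.add_edge(child, parent, relation=rel)
    for node in extra_nodes:
        if node not in g:
            g.add_node(node, name=node, namespace=namespace)
    return OntologyGraph(graph=g)


@pytest.fixture
def chain_ontology():
    """A is_a B is_a R."""
    return make_ontology([("A", "B", "is_a"), ("B", "R", "is_a")])


@pytest.fixture
def sibling_ontology():
    """A and B both is_a R."""
    return make_ontology([("A", "R", "is_a"), ("B", "R", "is_a")])


@pytest.fixture
def diamond_ontology():
    """A reaches R through two parents with different weights."""
    return make_ontology([
        ("A", "P1", "is_a"),
        ("A", "P2", "part_of"),
        ("P1", "R", "is_a"),
        ("P2", "R", "is_a"),
    ])


def make_library_table(lib_counts, totals, tissue="lung", condition="x"):
    """lib_counts: {library_id: {gene: count}}."""
    rows = [
        (lib, tissue, condition, gene, count)
        for lib, counts in lib_counts.items()
        for gene, count in counts.items()
    ]
    frame = pd.DataFrame(
        rows, columns=["library_id", "tissue", "condition", "gene_id",
                       "est_count"])
    return LibraryTable(frame=frame, totals=totals)


@pytest.fixture
def two_library_table():
    return make_library_table(
        {"L1": {"g1": 3, "g2": 10}, "L2": {"g1": 4, "g3": 2}},
        {"L1": 100, "L2": 50})


@pytest.fixture
def simple_manifest():
    return PoolManifest(members={"A": {"L1"}, "B": {"L2"}},
                        roles={"A": "reference", "B": "query"},
                        test_pool="A")
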