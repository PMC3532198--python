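"""Synthetic EST libraries, toy ontologies and planted annotations.

This generator stands in for the public EST/ontology downloads the
pipeline would normally consume, at desk scale but with the same
structure: a baseline transcriptome drawn from a skewed Dirichlet, EST
libraries sampled multinomially at fixed sequencing depth (EST
libraries have a fixed depth, so counts are multinomial rather than
independent Poisson), planted differentially expressed genes whose
proportions are multiplied or divided by a known fold, and planted
functionally coherent gene groups annotated from disjoint branches of a
random GO-like DAG.  Every stage is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (GeneAnnotation, LibraryTable, OntologyGraph,
                         PoolManifest)

__all__ = [
    "DEGene",
    "SimulationConfig",
    "GroundTruth",
    "gene_ids",
    "simulate_libraries",
    "simulate_ontology",
    "simulate_annotations",
    "two_group_config",
    "two_group_similarity_matrix",
]


@dataclass(frozen=True)
class DEGene:
    """A planted differentially expressed gene."""

    gene_id: str
    fold: float
    direction: Literal["up", "down"]

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("planted fold must be > 1")
        if self.direction not in ("up", "down"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults describe a desk-scale study: 300 genes, 6 reference and 6
    query libraries plus 20 other-tissue libraries, library depths of
    2e4 to 5e4 ESTs — far below a full EST compendium but structurally
    identical to one.
    """

    seed: int
    n_genes: int = 300
    n_ref_libs: int = 6
    n_query_libs: int = 6
    n_other_libs: int = 20
    library_total_range: tuple[int, int] = (20_000, 50_000)
    de_genes: tuple[DEGene, ...] = ()
    dirichlet_concentration: float = 0.5
    namespaces: tuple[str, ...] = ("BP", "MF", "CC")
    ontology_terms_per_namespace: int = 40
    n_groups: int = 2
    genes_per_group: int = 10
    terms_per_gene_mean: float = 3.0
    group_leakage: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_ref_libs", "n_query_libs",
                     "ontology_terms_per_namespace", "n_groups",
                     "genes_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_other_libs < 0:
            raise ValueError("n_other_libs must be non-negative")
        lo, hi = self.library_total_range
        if not (0 < lo <= hi):
            raise ValueError("invalid library_total_range")
        if not 0 <= self.group_leakage <= 1:
            raise ValueError("group_leakage must be a probability")
        if self.terms_per_gene_mean <= 0:
            raise ValueError("terms_per_gene_mean must be positive")


@dataclass
class GroundTruth:
    """What was planted: DE genes, group membership, baseline proportions."""

    de_genes: dict[str, DEGene] = field(default_factory=dict)
    groups: dict[str, int] = field(default_factory=dict)
    proportions: dict[str, float] = field(default_factory=dict)

    def group_members(self, group: int) -> frozenset[str]:
        return frozenset(g for g, k in self.groups.items() if k == group)


def gene_ids(config: SimulationConfig) -> list[str]:
    width = max(4, len(str(config.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


# ---------------------------------------------------------------------------
# EST libraries

def simulate_libraries(config: SimulationConfig
                       ) -> tuple[LibraryTable, PoolManifest, GroundTruth]:
    """Sample EST libraries for a reference/query pool contrast.

    Baseline proportions are Dirichlet-distributed; query-condition
    libraries perturb each planted DE gene's proportion by its fold
    (multiplied when up, divided when down) and renormalise.  Each
    library's depth is uniform on ``library_total_range`` and its gene
    counts multinomial.  Pool A holds the reference libraries, pool B
    the query libraries (the test pool); other-tissue libraries are in
    the table but no pool.
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config)
    universe = set(genes)
    for de in config.de_genes:
        if de.gene_id not in universe:
            raise ValueError(f"DE gene {de.gene_id!r} not in gene universe")
    theta = rng.dirichlet(
        np.full(config.n_genes, config.dirichlet_concentration))
    theta_query = theta.copy()
    for de in config.de_genes:
        i = genes.index(de.gene_id)
        theta_query[i] *= de.fold if de.direction == "up" else 1 / de.fold
    theta_query /= theta_query.sum()

    lo, hi = config.library_total_range
    rows = []
    totals: dict[str, int] = {}

    def add_library(lib_id: str, tissue: str, condition: str,
                    props: np.ndarray) -> None:
        total = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(total, props)
        totals[lib_id] = total
        for g, c in zip(genes, counts):
            if c > 0:
                rows.append((lib_id, tissue, condition, g, int(c)))

    for i in range(config.n_ref_libs):
        add_library(f"REF{i + 1:02d}", "lung", "reference", theta)
    for i in range(config.n_query_libs):
        add_library(f"QRY{i + 1:02d}", "lung", "query", theta_query)
    for i in range(config.n_other_libs):
        add_library(f"OTH{i + 1:02d}", f"tissue{i + 1}", "other", theta)

    frame = pd.DataFrame(rows, columns=["library_id", "tissue", "condition",
                                        "gene_id", "est_count"])
    table = LibraryTable(frame=frame, totals=totals)
    manifest = PoolManifest(
        members={"A": {f"REF{i + 1:02d}" for i in range(config.n_ref_libs)},
                 "B": {f"QRY{i + 1:02d}" for i in range(config.n_query_libs)}},
        roles={"A": "reference", "B": "query"},
        test_pool="B")
    truth = GroundTruth(
        de_genes={de.gene_id: de for de in config.de_genes},
        proportions=dict(zip(genes, theta.tolist())))
    return table, manifest, truth


# ---------------------------------------------------------------------------
# ontology

def simulate_ontology(config: SimulationConfig) -> OntologyGraph:
    """A rooted random DAG per namespace.

    Each new term attaches to one existing term (or two, with
    probability 0.3) with an ``is_a`` edge with probability 0.8, else
    ``part_of``; acyclic by construction since parents predate children.
    """
    if config.ontology_terms_per_namespace < 2:
        raise ValueError("need at least 2 terms per namespace")
    rng = np.random.default_rng(config.seed + 1)
    g = nx.DiGraph()
    for ns in config.namespaces:
        terms = [f"{ns}:{i:07d}" for i in range(
            config.ontology_terms_per_namespace)]
        g.add_node(terms[0], name=f"{ns} root", namespace=ns)
        for i, term in enumerate(terms[1:], start=1):
            g.add_node(term, name=f"{ns} term {i}", namespace=ns)
            n_parents = 1 if (i == 1 or rng.random() < 0.7) else 2
            parents = rng.choice(i, size=n_parents, replace=False)
            for p in parents:
                relation = "is_a" if rng.random() < 0.8 else "part_of"
                g.add_edge(term, terms[int(p)], relation=relation)
    return OntologyGraph(graph=g)


# ---------------------------------------------------------------------------
# annotations with planted groups

def _disjoint_branches(ontology: OntologyGraph, namespace: str,
                       n_groups: int, min_size: int) -> list[list[str]]:
    """Greedily select disjoint (term + descendants) branches."""
    g = ontology.graph
    candidates = []
    root_set = set(ontology.roots(namespace))
    for term in ontology.terms:
        if ontology.namespace_of(term) != namespace or term in root_set:
            continue
        branch = {term} | ontology.descendants(term)
        if len(branch) >= min_size:
            candidates.append(sorted(branch))
    # smallest first: small branches overlap least, so more disjoint
    # picks fit; group coherence needs only min_size terms per branch
    candidates.sort(key=lambda b: (len(b), b[0]))
    chosen: list[list[str]] = []
    used: set[str] = set()
    for branch in candidates:
        if used.isdisjoint(branch):
            chosen.append(branch)
            used.update(branch)
        if len(chosen) == n_groups:
            return chosen
    raise ValueError(
        f"namespace {namespace}: fewer than {n_groups} disjoint branches "
        f"of size >= {min_size}; grow the ontology")


def simulate_annotations(config: SimulationConfig, ontology: OntologyGraph
                         ) -> tuple[GeneAnnotation, GroundTruth]:
    """Annotate genes, planting functionally coherent groups.

    In every namespace each group is assigned a disjoint branch (a term
    and its descendants); group members draw Poisson-many terms from
    their branch, each draw leaking to a uniform namespace-wide term
    with probability ``group_leakage``.  Background genes draw
    uniformly from the namespace.  Genes may end up with empty term
    sets; they remain present in the annotation.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = gene_ids(config)
    n_grouped = config.n_groups * config.genes_per_group
    if n_grouped > config.n_genes:
        raise ValueError("more grouped genes than genes")
    grouped = rng.choice(config.n_genes, size=n_grouped, replace=False)
    groups = {genes[int(gi)]: k
              for k, start in enumerate(range(0, n_grouped,
                                              config.genes_per_group))
              for gi in grouped[start:start + config.genes_per_group]}
    min_size = max(2, math.ceil(config.terms_per_gene_mean))
    branches = {ns: _disjoint_branches(ontology, ns, config.n_groups,
                                       min_size)
                for ns in config.namespaces}
    ns_terms = {ns: sorted(t for t in ontology.terms
                           if ontology.namespace_of(t) == ns)
                for ns in config.namespaces}

    ann: dict[str, dict[str, frozenset[str]]] = {}
    for gene in genes:
        per_ns: dict[str, frozenset[str]] = {}
        group = groups.get(gene)
        for ns in config.namespaces:
            k = int(rng.poisson(config.terms_per_gene_mean))
            pool = ns_terms[ns] if group is None else branches[ns][group]
            drawn: set[str] = set()
            for _ in range(k):
                if group is not None and rng.random() < config.group_leakage:
                    drawn.add(ns_terms[ns][int(rng.integers(
                        len(ns_terms[ns])))])
                else:
                    drawn.add(pool[int(rng.integers(len(pool)))])
            per_ns[ns] = frozenset(drawn)
        ann[gene] = per_ns
    truth = GroundTruth(groups=groups)
    return GeneAnnotation(annotations=ann), truth


# ---------------------------------------------------------------------------
# the packaged planted-two-group clustering dataset

def two_group_config(seed: int) -> SimulationConfig:
    """Config of the canonical planted-two-group clustering dataset."""
    return SimulationConfig(
        seed=seed,
        n_genes=44,
        ontology_terms_per_namespace=60,
        n_groups=2,
        genes_per_group=22,
        terms_per_gene_mean=4.0,
        group_leakage=0.0,
    )


def two_group_similarity_matrix(seed: int,
                                n_reference_per_group: int = 10,
                                ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Similarity matrix with two planted, cleanly separated gene groups.

    From each planted group the last ``n_reference_per_group`` members
    are held out as reference (column) genes and the rest are the
    clustered candidates, so each candidate's profile is high against
    its own group's reference genes and low against the other's.
    Returns the candidate x reference matrix and the candidate ->
    group-id ground truth.
    """
    from .semsim import build_similarity_matrix

    config = two_group_config(seed)
    ontology = simulate_ontology(config)
    annotation, truth = simulate_annotations(config, ontology)
    candidates: list[str] = []
    reference: list[str] = []
    membership: dict[str, int] = {}
    for k in range(config.n_groups):
        members = sorted(truth.group_members(k))
        reference.extend(members[-n_reference_per_group:])
        held = members[:-n_reference_per_group]
        candidates.extend(held)
        membership.update({g: k for g in held})
    matrix = build_similarity_matrix(candidates, reference, annotation,
                                     ontology)
    membership = {g: membership[g] for g in matrix.index}
    return matrix, membership
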