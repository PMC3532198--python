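"""Wang semantic similarity over the Gene Ontology.

The Wang measure scores two GO terms by how much of their weighted
ancestor mass they share.  Each term ``a`` induces an S-value table over
``T_a``, the term itself plus all its ancestors through ``is_a`` and
``part_of`` edges: ``S_a(a) = 1`` and, moving upward,

    S_a(t) = max over children t' of t within T_a of
             w(relation(t' -> t)) * S_a(t')

with edge weights ``w`` (defaults: 0.8 for is_a, 0.6 for part_of, the
standard Wang constants).  ``SV(a)`` is the sum of the table.  The
between-term similarity is then

    Sim(a, b) = sum over t in T_a & T_b of (S_a(t) + S_b(t))
                / (SV(a) + SV(b))

which is symmetric and lies in [0, 1].

Gene products annotated to term sets gi = {gi1..gim} and
gj = {gj1..gjn} are compared with the best-match average: every term of
each gene contributes its maximum similarity to the other gene's terms,
and the total is divided by m + n.  Scores from the three orthogonal
ontologies (BP, MF, CC) are combined by an unweighted mean over the
namespaces in which both genes are annotated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, OntologyGraph

__all__ = [
    "DEFAULT_WEIGHTS",
    "SValueTable",
    "s_values",
    "term_similarity",
    "gene_similarity",
    "combined_gene_similarity",
    "build_similarity_matrix",
    "SimilarityMatrix",
]

DEFAULT_WEIGHTS: Mapping[str, float] = {"is_a": 0.8, "part_of": 0.6}

NAMESPACES = ("BP", "MF", "CC")


@dataclass(frozen=True)
class SValueTable:
    """Weighted ancestor contributions of one anchor term."""

    anchor: str
    s: Mapping[str, float]
    sv: float


def s_values(anchor: str, graph: OntologyGraph,
             weights: Mapping[str, float] = DEFAULT_WEIGHTS) -> SValueTable:
    """S-value table of ``anchor``: itself plus all its ancestors.

    Computed in topological order from the anchor upward, so each term
    is visited once even in a dense DAG.
    """
    g = graph.graph
    if anchor not in g:
        raise KeyError(f"term {anchor!r} not in ontology")
    induced_nodes = {anchor} | graph.ancestors(anchor)
    sub = g.subgraph(induced_nodes)
    s = {anchor: 1.0}
    # child -> parent edges: topological order visits children first
    for term in nx.topological_sort(sub):
        if term == anchor:
            continue
        best = 0.0
        for child in sub.predecessors(term):
            if child in s:
                w = weights[sub.edges[child, term]["relation"]]
                best = max(best, w * s[child])
        s[term] = best
    return SValueTable(anchor=anchor, s=s, sv=float(sum(s.values())))


def term_similarity(a: str, b: str, graph: OntologyGraph,
                    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
                    _cache: dict | None = None) -> float:
    """Wang similarity between two terms of the same namespace."""
    if graph.namespace_of(a) != graph.namespace_of(b):
        raise ValueError(
            f"terms {a!r} and {b!r} are in different namespaces")
    if _cache is not None:
        ta = _cache.get(a) or _cache.setdefault(a, s_values(a, graph, weights))
        tb = _cache.get(b) or _cache.setdefault(b, s_values(b, graph, weights))
    else:
        ta = s_values(a, graph, weights)
        tb = s_values(b, graph, weights)
    shared = ta.s.keys() & tb.s.keys()
    if not shared:
        return 0.0
    num = sum(ta.s[t] + tb.s[t] for t in shared)
    return num / (ta.sv + tb.sv)


def gene_similarity(gi: str, gj: str, namespace: str,
                    annotation: GeneAnnotation, graph: OntologyGraph,
                    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
                    _cache: dict | None = None) -> float:
    """Best-match-average similarity of two genes in one namespace.

    Returns NaN (missing) when either gene has no terms in the
    namespace.
    """
    terms_i = sorted(annotation.terms(gi, namespace))
    terms_j = sorted(annotation.terms(gj, namespace))
    if not terms_i or not terms_j:
        return float("nan")
    sim = {}
    for a in terms_i:
        for b in terms_j:
            sim[a, b] = term_similarity(a, b, graph, weights, _cache=_cache)
    total = sum(max(sim[a, b] for b in terms_j) for a in terms_i)
    total += sum(max(sim[a, b] for a in terms_i) for b in terms_j)
    return total / (len(terms_i) + len(terms_j))


def combined_gene_similarity(gi: str, gj: str, annotation: GeneAnnotation,
                             graph: OntologyGraph,
                             weights: Mapping[str, float] = DEFAULT_WEIGHTS,
                             namespaces: Sequence[str] = NAMESPACES,
                             _cache: dict | None = None,
                             ) -> tuple[float, tuple[str, ...]]:
    """Mean per-namespace gene similarity over shared annotated namespaces.

    Returns ``(score, namespaces_used)``; the score is NaN and the tuple
    empty when the genes share no annotated namespace.
    """
    scores = []
    used = []
    for ns in namespaces:
        s = gene_similarity(gi, gj, ns, annotation, graph, weights,
                            _cache=_cache)
        if not np.isnan(s):
            scores.append(s)
            used.append(ns)
    if not scores:
        return float("nan"), ()
    return float(np.mean(scores)), tuple(used)


#: a similarity matrix is a DataFrame: rows = candidates, columns = reference
SimilarityMatrix = pd.DataFrame


def build_similarity_matrix(candidates: Sequence[str],
                            reference: Sequence[str],
                            annotation: GeneAnnotation,
                            graph: OntologyGraph,
                            weights: Mapping[str, float] = DEFAULT_WEIGHTS,
                            namespaces: Sequence[str] = NAMESPACES,
                            ) -> SimilarityMatrix:
    """Candidate x reference GO-similarity matrix.

    All pairs are scored with :func:`combined_gene_similarity`; S-value
    tables are cached per term so each term's ancestor propagation runs
    once.  Rows whose every entry is missing (candidate without usable
    annotation) are dropped with a warning.
    """
    if not len(candidates) or not len(reference):
        raise ValueError("candidate and reference lists must be non-empty")
    cache: dict[str, SValueTable] = {}
    known = set(annotation.annotations)
    values = np.full((len(candidates), len(reference)), np.nan)
    for i, gi in enumerate(candidates):
        if gi not in known:
            continue  # no annotation at all: row stays missing, dropped below
        for j, gj in enumerate(reference):
            if gj not in known:
                continue
            score, _ = combined_gene_similarity(
                gi, gj, annotation, graph, weights, namespaces, _cache=cache)
            values[i, j] = score
    matrix = pd.DataFrame(values, index=list(candidates),
                          columns=list(reference))
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        dropped = list(matrix.index[all_missing])
        warnings.warn(
            f"dropping {len(dropped)} candidate(s) without usable "
            f"annotation: {dropped}")
        matrix = matrix.loc[~all_missing]
    return matrix
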