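"""Readers and writers for the external formats the pipeline touches.

Tabular inputs and outputs are UTF-8, tab-separated, with ``#``-prefixed
comment lines.  Ontologies are read from OBO 1.2 (``is_a`` and
``relationship: part_of`` edges only), annotations from GAF 2.x.
Dendrograms are additionally exported as Newick.  Gene identifiers are
treated as opaque text throughout.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd
from Bio.UniProt import GOA

__all__ = [
    "LibraryTable",
    "PoolManifest",
    "OntologyGraph",
    "GeneAnnotation",
    "read_library_table",
    "write_library_table",
    "read_pool_manifest",
    "write_pool_manifest",
    "read_obo",
    "write_obo",
    "read_gaf",
    "write_gaf",
    "read_gene_list",
    "write_gene_list",
    "write_results",
    "load_biomarker_table",
    "load_pan_cancer_list",
]

_ASPECT_TO_NS = {"P": "BP", "F": "MF", "C": "CC"}
_NS_TO_ASPECT = {v: k for k, v in _ASPECT_TO_NS.items()}
_OBO_NAMESPACES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}
_NS_TO_OBO = {"BP": "biological_process", "MF": "molecular_function",
              "CC": "cellular_component"}

LIBRARY_COLUMNS = ["library_id", "tissue", "condition", "gene_id",
                   "est_count", "total_ests"]


class FormatError(ValueError):
    """Raised when an input file is malformed or violates an invariant."""


@dataclass
class LibraryTable:
    """Per-gene EST counts for a set of cDNA libraries.

    ``frame`` has one row per (library, gene) pair with columns
    ``library_id, tissue, condition, gene_id, est_count``; ``totals``
    gives each library's declared sequencing depth, which must be at
    least the sum of its per-gene counts (unassigned ESTs are allowed).
    """

    frame: pd.DataFrame
    totals: dict[str, int]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        f = self.frame
        missing = [c for c in LIBRARY_COLUMNS[:5] if c not in f.columns]
        if missing:
            raise FormatError(f"library table missing columns: {missing}")
        if (f["est_count"] < 0).any():
            bad = f.loc[f["est_count"] < 0].iloc[0]
            raise FormatError(
                f"negative EST count for gene {bad['gene_id']!r} in "
                f"library {bad['library_id']!r}")
        dup = f.duplicated(subset=["library_id", "gene_id"])
        if dup.any():
            bad = f.loc[dup].iloc[0]
            raise FormatError(
                f"duplicate (library, gene) pair: "
                f"({bad['library_id']!r}, {bad['gene_id']!r})")
        sums = f.groupby("library_id")["est_count"].sum()
        for lib, s in sums.items():
            tot = self.totals.get(lib)
            if tot is None:
                raise FormatError(f"no declared total for library {lib!r}")
            if tot <= 0:
                raise FormatError(f"non-positive total for library {lib!r}")
            if tot < s:
                raise FormatError(
                    f"library {lib!r}: declared total {tot} is less than "
                    f"the sum of its gene counts {s}")

    @property
    def library_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["library_id"]))

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.frame["gene_id"].unique())

    def counts_for(self, library_ids: Iterable[str]) -> pd.Series:
        """Summed per-gene counts over the given libraries."""
        ids = set(library_ids)
        unknown = ids - set(self.totals)
        if unknown:
            raise KeyError(f"unknown library ids: {sorted(unknown)}")
        sub = self.frame[self.frame["library_id"].isin(ids)]
        return sub.groupby("gene_id")["est_count"].sum()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LibraryTable):
            return NotImplemented
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b) and self.totals == other.totals


@dataclass
class PoolManifest:
    """Assignment of libraries to the two DDD pools.

    ``members`` maps pool id ("A"/"B") to the member library ids;
    ``roles`` maps pool id to "reference" or "query"; ``test_pool``
    names the pool whose direction defines the fold-change sign.
    """

    members: dict[str, set[str]]
    roles: dict[str, str]
    test_pool: str

    def __post_init__(self) -> None:
        if set(self.members) != {"A", "B"}:
            raise FormatError("manifest must define exactly pools A and B")
        if not self.members["A"] or not self.members["B"]:
            raise FormatError("pools must be non-empty")
        overlap = self.members["A"] & self.members["B"]
        if overlap:
            raise FormatError(f"pools A and B overlap: {sorted(overlap)}")
        if self.test_pool not in self.members:
            raise FormatError(f"test_pool {self.test_pool!r} is not a pool")
        bad_roles = set(self.roles.values()) - {"reference", "query"}
        if bad_roles:
            raise FormatError(f"unknown pool roles: {sorted(bad_roles)}")


@dataclass
class OntologyGraph:
    """A GO-style DAG with typed child-to-parent edges.

    ``graph`` is a :class:`networkx.DiGraph` whose edges point from child
    to parent and carry a ``relation`` attribute (``is_a`` or
    ``part_of``); nodes carry ``name`` and ``namespace`` (BP/MF/CC).
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise FormatError(
                f"ontology contains a cycle through term {cycle[0][0]!r}")
        for _, _, rel in self.graph.edges(data="relation"):
            if rel not in ("is_a", "part_of"):
                raise FormatError(f"unknown edge relation {rel!r}")

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def namespace_of(self, term: str) -> str:
        return self.graph.nodes[term]["namespace"]

    def namespaces(self) -> list[str]:
        return sorted({d["namespace"] for _, d in self.graph.nodes(data=True)})

    def parents(self, term: str) -> list[str]:
        return list(self.graph.successors(term))

    def children(self, term: str) -> list[str]:
        return list(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from ``term`` (excluding itself)."""
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        return nx.ancestors(self.graph, term)

    def roots(self, namespace: str | None = None) -> list[str]:
        out = [t for t in self.graph.nodes
               if self.graph.out_degree(t) == 0]
        if namespace is not None:
            out = [t for t in out if self.namespace_of(t) == namespace]
        return sorted(out)


@dataclass
class GeneAnnotation:
    """Per-gene, per-namespace sets of directly annotated GO terms."""

    annotations: dict[str, dict[str, frozenset[str]]] = field(
        default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.annotations)

    def terms(self, gene: str, namespace: str) -> frozenset[str]:
        if gene not in self.annotations:
            raise KeyError(f"unknown gene {gene!r}")
        return self.annotations[gene].get(namespace, frozenset())

    def namespaces(self, gene: str) -> list[str]:
        """Namespaces in which ``gene`` has at least one term."""
        return sorted(ns for ns, ts in self.annotations.get(gene, {}).items()
                      if ts)


# ---------------------------------------------------------------------------
# library tables and pool manifests

def read_library_table(path: str | Path) -> LibraryTable:
    """Read a tab-separated EST library table.

    Expects a header with columns ``library_id tissue condition gene_id
    est_count total_ests``; the declared total is repeated on every row
    of a library and must be consistent.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#",
                            dtype={"library_id": str, "tissue": str,
                                   "condition": str, "gene_id": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse library table: {exc}")
    missing = [c for c in LIBRARY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("est_count", "total_ests"):
        vals = frame[col]
        bad = vals[pd.to_numeric(vals, errors="coerce").isna()]
        if len(bad):
            line = bad.index[0] + 2  # header is line 1
            raise FormatError(
                f"{path}: line {line}: non-integer {col} {bad.iloc[0]!r}")
        as_num = pd.to_numeric(vals)
        if (as_num != as_num.astype(int)).any():
            line = as_num[as_num != as_num.astype(int)].index[0] + 2
            raise FormatError(f"{path}: line {line}: non-integer {col}")
        frame[col] = as_num.astype(int)
    totals = {}
    for lib, sub in frame.groupby("library_id"):
        declared = sub["total_ests"].unique()
        if len(declared) > 1:
            raise FormatError(
                f"{path}: library {lib!r} declares conflicting totals "
                f"{sorted(declared)}")
        totals[lib] = int(declared[0])
    return LibraryTable(frame=frame.drop(columns=["total_ests"]),
                        totals=totals)


def write_library_table(table: LibraryTable, path: str | Path) -> None:
    frame = table.frame.copy()
    frame["total_ests"] = frame["library_id"].map(table.totals)
    frame.to_csv(path, sep="\t", index=False, columns=LIBRARY_COLUMNS)


def read_pool_manifest(path: str | Path) -> PoolManifest:
    """Read a manifest TSV with columns pool_id, role, is_test, library_id."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = {"pool_id", "role", "is_test", "library_id"}
    if not needed <= set(frame.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(needed)}")
    members: dict[str, set[str]] = {}
    roles: dict[str, str] = {}
    test_pools = set()
    for _, row in frame.iterrows():
        pid = row["pool_id"]
        members.setdefault(pid, set()).add(row["library_id"])
        roles[pid] = row["role"]
        if str(row["is_test"]).lower() in ("1", "true", "yes"):
            test_pools.add(pid)
    if len(test_pools) != 1:
        raise FormatError(f"{path}: exactly one pool must be the test pool")
    return PoolManifest(members=members, roles=roles,
                        test_pool=test_pools.pop())


def write_pool_manifest(manifest: PoolManifest, path: str | Path) -> None:
    rows = []
    for pid in sorted(manifest.members):
        for lib in sorted(manifest.members[pid]):
            rows.append({"pool_id": pid, "role": manifest.roles[pid],
                         "is_test": pid == manifest.test_pool,
                         "library_id": lib})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ontology and annotations

def read_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO 1.2 file into an :class:`OntologyGraph`.

    Obsolete terms are dropped; only ``is_a`` and ``part_of`` edges are
    kept.  Raises on cycles and on unknown namespaces.
    """
    multi = obonet.read_obo(str(path))  # skips obsolete terms
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        ns_raw = data.get("namespace")
        if ns_raw is None:
            raise FormatError(f"term {node!r} has no namespace")
        if ns_raw not in _OBO_NAMESPACES:
            raise FormatError(f"term {node!r}: unknown namespace {ns_raw!r}")
        g.add_node(node, name=data.get("name", node),
                   namespace=_OBO_NAMESPACES[ns_raw])
    for child, parent, key in multi.edges(keys=True):
        if key in ("is_a", "part_of") and parent in g:
            g.add_edge(child, parent, relation=key)
    return OntologyGraph(graph=g)


def write_obo(ontology: OntologyGraph, path: str | Path) -> None:
    g = ontology.graph
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: synthetic\n")
        for term in sorted(g.nodes):
            data = g.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            fh.write(f"namespace: {_NS_TO_OBO[data['namespace']]}\n")
            for parent in sorted(g.successors(term)):
                rel = g.edges[term, parent]["relation"]
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


def read_gaf(path: str | Path, ontology: OntologyGraph | None = None,
             *, missing_term: str = "warn",
             evidence: set[str] | None = None) -> GeneAnnotation:
    """Read a GAF 2.x annotation file.

    Rows with a NOT qualifier are dropped; aspects P/F/C map to
    namespaces BP/MF/CC; per-gene term sets are deduplicated.  When an
    ``ontology`` is supplied, annotations to unknown terms are dropped
    with a warning (``missing_term="warn"``) or raise
    (``missing_term="error"``).  ``evidence``, when given, is an
    inclusion list of evidence codes; by default no evidence filtering
    is applied.
    """
    if missing_term not in ("warn", "error"):
        raise ValueError("missing_term must be 'warn' or 'error'")
    ann: dict[str, dict[str, set[str]]] = {}
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            if "NOT" in rec["Qualifier"]:
                continue
            if evidence is not None and rec["Evidence"] not in evidence:
                continue
            gene = rec["DB_Object_ID"]
            term = rec["GO_ID"]
            ns = _ASPECT_TO_NS.get(rec["Aspect"])
            if ns is None:
                raise FormatError(f"{path}: unknown aspect {rec['Aspect']!r}")
            if ontology is not None and term not in ontology.graph:
                if missing_term == "error":
                    raise FormatError(
                        f"{path}: term {term!r} absent from ontology")
                warnings.warn(f"dropping annotation to unknown term {term}")
                continue
            ann.setdefault(gene, {}).setdefault(ns, set()).add(term)
    return GeneAnnotation(annotations={
        g: {ns: frozenset(ts) for ns, ts in d.items()}
        for g, d in ann.items()})


def write_gaf(annotation: GeneAnnotation, path: str | Path,
              db: str = "dddkit") -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in annotation.genes:
            for ns in ("BP", "MF", "CC"):
                for term in sorted(annotation.terms(gene, ns)):
                    cols = [db, gene, gene, "", term, "SYN:0000000", "IEA",
                            "", _NS_TO_ASPECT[ns], "", "", "gene", "taxon:9606",
                            "20120101", db, "", ""]
                    fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# gene lists

def read_gene_list(path: str | Path) -> list[str]:
    """Read one gene id per line; '#' comments allowed; order preserved,
    duplicates removed with a warning; empty list is an error."""
    out: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if line in seen:
                warnings.warn(f"{path}: duplicate id {line!r} dropped")
                continue
            seen.add(line)
            out.append(line)
    if not out:
        raise FormatError(f"{path}: gene list is empty")
    return out


def write_gene_list(ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


# ---------------------------------------------------------------------------
# results

PANEL_COLUMNS = ["panel", "gene_symbol", "ddd1_freq_a", "ddd1_freq_b",
                 "ddd1_fold", "ddd2_freq_a", "ddd2_freq_b", "ddd2_fold"]


def write_results(records, path: str | Path, kind: str) -> None:
    """Write pipeline outputs as TSV.

    ``kind`` selects the schema: ``ddd`` (one row per DDD record),
    ``similarity_matrix`` (genes x genes with row/column ids),
    ``clusters`` (cluster membership rows; pass a ``(supports,
    dendrogram)`` pair to also write ``<path>.nwk`` with AU node
    labels), or ``panels`` (the eight eight-column panel-layout columns).
    """
    path = Path(path)
    if kind == "ddd":
        rows = [r.as_dict() for r in records]
        cols = ["gene_id", "count_a", "count_b", "freq_a", "freq_b",
                "fold", "p_value", "q_value", "direction"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    elif kind == "similarity_matrix":
        if not isinstance(records, pd.DataFrame):
            raise TypeError("similarity_matrix output must be a DataFrame")
        records.to_csv(path, sep="\t", index_label="gene_id")
    elif kind == "clusters":
        supports, dendrogram = records
        rows = []
        for i, sup in enumerate(supports):
            rows.append({
                "node": i,
                "n_members": len(sup.members),
                "au": "" if sup.au is None else f"{sup.au:.4f}",
                "bp": f"{sup.bp:.4f}",
                "members": ",".join(sorted(sup.members)),
            })
        cols = ["node", "n_members", "au", "bp", "members"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        nwk = dendrogram.to_newick(
            labels={frozenset(s.members):
                    ("" if s.au is None else f"{s.au:.3f}")
                    for s in supports})
        Path(str(path) + ".nwk").write_text(nwk + "\n")
    elif kind == "panels":
        rows = []
        for panel in records:
            rows.extend(panel.as_rows())
        pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown results kind {kind!r}")


# ---------------------------------------------------------------------------
# packaged fixtures

def _data_path(name: str):
    return resources.files("dddkit.data").joinpath(name)


def load_biomarker_table() -> pd.DataFrame:
    """The packaged 38-gene lung-cancer biomarker panel table.

    Frequencies and fold changes are kept verbatim as printed
    (strings), including the exclusive "+"/"-" markers.
    """
    with _data_path("lung_biomarker_panels.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    frame["panel"] = frame["panel"].astype(int)
    frame["cluster"] = frame["cluster"].astype(int)
    return frame


def load_pan_cancer_list() -> list[str]:
    """The packaged synthetic pan-cancer exclusion list (18 symbols)."""
    with resources.as_file(
            _data_path("pan_cancer_exclusion_synthetic.txt")) as p:
        return read_gene_list(p)
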