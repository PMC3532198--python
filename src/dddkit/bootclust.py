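"""Hierarchical clustering with multiscale-bootstrap cluster support.

Genes are clustered on their similarity profiles (rows of the
candidate x reference GO-similarity matrix) with agglomerative linkage
on a correlation distance, and every internal node of the dendrogram
receives two support values estimated by resampling the profile
columns:

* **BP** (bootstrap probability): the fraction of bootstrap replicate
  dendrograms that contain a node with the identical membership set.
* **AU** (approximately unbiased p-value): a bias-corrected support
  obtained from *multiscale* bootstrapping.  Replicates are drawn at
  several resample sizes ``n_r = round(n * r)`` for scale factors ``r``
  around 1; the probit-transformed BP curve

      psi(rho_r) = Phi^{-1}(1 - BP_r),   rho_r = n_r / n

  is fitted by weighted least squares to ``v * sqrt(rho) + c /
  sqrt(rho)``, whose two coefficients estimate the signed distance
  ``v`` and curvature ``c`` of the cluster boundary.  Then
  ``AU = 1 - Phi(v - c)`` and the fitted ordinary bootstrap probability
  is ``BP = 1 - Phi(v + c)``.

A scale whose BP is exactly 0 or 1 carries no probit information and
is excluded from the fit; when fewer than two informative scales
remain, the direction of the curve decides the support directly:
AU = BP = 1 for a curve pinned high (a cluster recovered in essentially
every replicate), 0 for one pinned low.  This mirrors pvclust's
handling of degenerate curves.

Clusters are finally selected top-down: a node is reported, and its
subtree pruned, when its AU meets the significance level alpha
(default 0.95).  The root is never reported (it is contained in every
replicate by construction, so its support is uninformative), matching
the convention of pvclust's ``pvpick``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "BootstrapConfig",
    "DendroNode",
    "Dendrogram",
    "ClusterSupport",
    "profile_distance",
    "hcluster",
    "multiscale_bootstrap",
    "fit_au",
    "pick_clusters",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


@dataclass
class BootstrapConfig:
    """Multiscale bootstrap settings (pvclust-style defaults)."""

    seed: int
    scales: Sequence[float] = DEFAULT_SCALES
    n_boot: int = 1000
    distance: str = "correlation"
    linkage: str = "average"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        if self.distance not in ("correlation", "euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.linkage not in ("average", "complete", "single"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


# ---------------------------------------------------------------------------
# distances

def _pearson_distance(X: np.ndarray, strict: bool,
                      labels: Sequence[str] | None = None) -> np.ndarray:
    """1 - Pearson correlation between rows; pairwise-complete on NaN.

    With ``strict`` a constant profile is an error (named after its
    gene); otherwise its correlations are taken as 0 (distance 1), the
    lenient behaviour used inside bootstrap replicates.
    """
    n = X.shape[0]
    labels = labels if labels is not None else [str(i) for i in range(n)]
    if not np.isnan(X).any():
        sd = X.std(axis=1)
        const = sd == 0
        if const.any() and strict:
            raise ValueError(
                f"constant profile for gene {labels[int(np.where(const)[0][0])]!r}: "
                "correlation distance undefined")
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        d = 1.0 - np.clip(corr, -1.0, 1.0)
        d = (d + d.T) / 2.0  # corrcoef is not exactly symmetric
        np.fill_diagonal(d, 0.0)
        return d
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~np.isnan(X[i]) & ~np.isnan(X[j])
            if mask.sum() < 3:
                raise ValueError(
                    f"genes {labels[i]!r} and {labels[j]!r} share fewer "
                    "than 3 observed columns")
            xi, xj = X[i, mask], X[j, mask]
            si, sj = xi.std(), xj.std()
            if si == 0 or sj == 0:
                if strict:
                    bad = labels[i] if si == 0 else labels[j]
                    raise ValueError(
                        f"constant profile for gene {bad!r}: correlation "
                        "distance undefined")
                corr = 0.0
            else:
                corr = float(np.corrcoef(xi, xj)[0, 1])
            d[i, j] = d[j, i] = 1.0 - min(1.0, max(-1.0, corr))
    return d


def _euclidean_distance(X: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform
    if np.isnan(X).any():
        raise ValueError("euclidean distance requires a complete matrix")
    return squareform(pdist(X))


def _distance(X: np.ndarray, method: str, strict: bool,
              labels: Sequence[str] | None = None) -> np.ndarray:
    if method == "correlation":
        return _pearson_distance(X, strict, labels)
    return _euclidean_distance(X)


def profile_distance(matrix: pd.DataFrame,
                     method: str = "correlation") -> pd.DataFrame:
    """Distance between gene similarity profiles (matrix rows).

    The correlation method uses ``1 - Pearson r`` with pairwise-complete
    handling of missing values; pairs sharing fewer than 3 observed
    columns, and constant profiles, are errors.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("need at least 3 rows and 2 columns")
    d = _distance(matrix.to_numpy(dtype=float), method, strict=True,
                  labels=list(matrix.index))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# agglomerative clustering

@dataclass
class DendroNode:
    """A node of the merge tree; leaves have ``height`` 0 and no children."""

    members: frozenset[str]
    height: float
    children: tuple["DendroNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    """Binary merge tree over gene leaves."""

    root: DendroNode
    leaves: tuple[str, ...]

    def internal_nodes(self) -> list[DendroNode]:
        """Internal nodes in merge (height) order, root last."""
        out: list[DendroNode] = []

        def walk(node: DendroNode) -> None:
            if node.is_leaf:
                return
            for ch in node.children:
                walk(ch)
            out.append(node)

        walk(self.root)
        out.sort(key=lambda n: (n.height, len(n.members),
                                tuple(sorted(n.members))))
        return out

    def to_newick(self, labels: Mapping[frozenset, str] | None = None) -> str:
        """Newick string; internal node labels taken from ``labels``
        (keyed by membership set), branch lengths from merge heights."""

        def fmt(node: DendroNode, parent_height: float) -> str:
            length = max(0.0, parent_height - node.height)
            if node.is_leaf:
                (leaf,) = node.members
                return f"{leaf}:{length:.6g}"
            inner = ",".join(fmt(ch, node.height) for ch in node.children)
            label = "" if labels is None else labels.get(node.members, "")
            return f"({inner}){label}:{length:.6g}"

        inner = ",".join(fmt(ch, self.root.height)
                         for ch in self.root.children)
        label = "" if labels is None else labels.get(self.root.members, "")
        return f"({inner}){label};"


def _merge_sequence(dist: np.ndarray, linkage: str,
                    labels: Sequence[str],
                    ) -> list[tuple[frozenset, frozenset, float]]:
    """Agglomerative merges on a full distance matrix.

    Returns (left members, right members, height) triples in merge
    order.  Ties on the minimum distance are broken deterministically by
    the lexicographically smallest merged membership set.
    """
    n = dist.shape[0]
    D = dist.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    members: list[frozenset] = [frozenset([labels[i]]) for i in range(n)]
    sort_keys = [tuple(sorted(m)) for m in members]
    merges = []
    for _ in range(n - 1):
        sub = np.where(active)[0]
        block = D[np.ix_(sub, sub)].copy()
        block[np.tril_indices_from(block)] = np.inf  # search i < j only
        h = block.min()
        ti, tj = np.where(block == h)
        pairs = [(sub[a], sub[b]) for a, b in zip(ti, tj)]
        if len(pairs) > 1:
            pairs.sort(key=lambda p: tuple(sorted(
                set(sort_keys[p[0]]) | set(sort_keys[p[1]]))))
        i, j = pairs[0]
        merges.append((members[i], members[j], float(h)))
        si, sj = sizes[i], sizes[j]
        others = active.copy()
        others[[i, j]] = False
        if linkage == "average":
            D[i, others] = (si * D[i, others] + sj * D[j, others]) / (si + sj)
        elif linkage == "complete":
            D[i, others] = np.maximum(D[i, others], D[j, others])
        else:  # single
            D[i, others] = np.minimum(D[i, others], D[j, others])
        D[others, i] = D[i, others]
        sizes[i] = si + sj
        members[i] = members[i] | members[j]
        sort_keys[i] = tuple(sorted(members[i]))
        active[j] = False
        D[j, :] = np.inf
        D[:, j] = np.inf
    return merges


def hcluster(distances: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a symmetric distance table.

    ``average`` is UPGMA: the distance between clusters is the mean over
    all cross pairs.  Tie-breaking is deterministic (smallest
    lexicographic merged membership), so membership sets are
    well-defined across bootstrap replicates.
    """
    labels = list(distances.index)
    merges = _merge_sequence(distances.to_numpy(dtype=float), linkage, labels)
    nodes: dict[frozenset, DendroNode] = {
        frozenset([l]): DendroNode(frozenset([l]), 0.0) for l in labels}
    for left, right, h in merges:
        node = DendroNode(left | right, h, (nodes[left], nodes[right]))
        nodes[left | right] = node
    return Dendrogram(root=nodes[frozenset(labels)], leaves=tuple(labels))


# ---------------------------------------------------------------------------
# multiscale bootstrap

@dataclass
class ScaleCount:
    rho: float
    n_boot: int
    hits: int


@dataclass
class ClusterSupport:
    """Bootstrap support for one internal dendrogram node."""

    members: frozenset[str]
    scales: list[ScaleCount]
    au: float | None = None
    bp: float | None = None
    v: float | None = None
    c: float | None = None
    chisq: float | None = None


def fit_au(bp_values: Sequence[float], rho: Sequence[float],
           n_boot: Sequence[int] | int,
           ) -> tuple[float, float, float, float, float]:
    """Fit the multiscale BP curve and return (au, bp, v, c, chisq).

    ``bp_values`` are per-scale bootstrap probabilities; each is clamped
    to [1/(2B), 1 - 1/(2B)] before the probit transform.  The weighted
    least squares uses weights ``B * phi(psi)^2 / (BP (1 - BP))``, the
    inverse delta-method variance of psi.
    """
    bp_arr = np.asarray(bp_values, dtype=float)
    rho_arr = np.asarray(rho, dtype=float)
    if np.isscalar(n_boot):
        nb = np.full_like(bp_arr, float(n_boot))
    else:
        nb = np.asarray(n_boot, dtype=float)
    if len(bp_arr) < 2 or len(np.unique(rho_arr)) < 2:
        raise ValueError("need at least 2 distinct scales to fit")
    lo = 1.0 / (2.0 * nb)
    bp_c = np.clip(bp_arr, lo, 1.0 - lo)
    psi = norm.ppf(1.0 - bp_c)
    X = np.column_stack([np.sqrt(rho_arr), 1.0 / np.sqrt(rho_arr)])
    w = nb * norm.pdf(psi) ** 2 / (bp_c * (1.0 - bp_c))
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ psi)
    v, c = float(beta[0]), float(beta[1])
    resid = psi - X @ beta
    chisq = float((w * resid**2).sum())
    au = float(1.0 - norm.cdf(v - c))
    bp_fit = float(1.0 - norm.cdf(v + c))
    return au, bp_fit, v, c, chisq


def _support_from_counts(members: frozenset, counts: list[ScaleCount]
                         ) -> ClusterSupport:
    """Fit one node's BP curve, pvclust-style.

    Scales with a degenerate BP (0 or 1) carry no probit information
    and are excluded from the fit; when fewer than two informative
    scales remain, the curve direction decides: AU = BP = 1 for a
    high curve (mean BP >= 0.5), 0 for a low one.
    """
    sup = ClusterSupport(members=members, scales=counts)
    hits = np.array([c.hits for c in counts])
    nb = np.array([c.n_boot for c in counts])
    valid = nb > 0
    if not valid.any():
        sup.au = None
        sup.bp = 0.0
        return sup
    bp_all = hits[valid] / nb[valid]
    rho_all = np.array([c.rho for c in counts])[valid]
    use = (hits[valid] > 0) & (hits[valid] < nb[valid])
    if use.sum() < 2 or len(np.unique(rho_all[use])) < 2:
        high = 1.0 if bp_all.mean() >= 0.5 else 0.0
        sup.au = sup.bp = high
        return sup
    au, bp_fit, v, c_coef, chisq = fit_au(bp_all[use], rho_all[use],
                                          nb[valid][use])
    sup.au, sup.bp, sup.v, sup.c, sup.chisq = au, bp_fit, v, c_coef, chisq
    return sup


def multiscale_bootstrap(matrix: pd.DataFrame, config: BootstrapConfig
                         ) -> tuple[list[ClusterSupport], Dendrogram]:
    """AU/BP support for every internal node of the observed dendrogram.

    For each scale factor ``r`` the reference columns are resampled with
    replacement to size ``round(n * r)`` (minimum 3) and the genes are
    reclustered with the same distance and linkage as the observed
    tree; a node is *hit* when a replicate tree contains its exact
    membership set.  Fully seeded and reproducible.
    """
    labels = list(matrix.index)
    X = matrix.to_numpy(dtype=float)
    n_cols = X.shape[1]
    d_obs = _distance(X, config.distance, strict=True, labels=labels)
    dendro = hcluster(
        pd.DataFrame(d_obs, index=labels, columns=labels), config.linkage)
    nodes = dendro.internal_nodes()
    node_sets = [n.members for n in nodes]
    hit_counts = np.zeros((len(nodes), len(config.scales)), dtype=int)
    rng = np.random.default_rng(config.seed)
    rhos = []
    for si, scale in enumerate(config.scales):
        n_r = max(3, int(round(n_cols * scale)))
        rhos.append(n_r / n_cols)
        for _ in range(config.n_boot):
            idx = rng.integers(0, n_cols, size=n_r)
            db = _distance(X[:, idx], config.distance, strict=False,
                           labels=labels)
            replicate = {frozenset(left | right) for left, right, _ in
                         _merge_sequence(db, config.linkage, labels)}
            for ni, ms in enumerate(node_sets):
                if ms in replicate:
                    hit_counts[ni, si] += 1
    supports = []
    for ni, node in enumerate(nodes):
        counts = [ScaleCount(rho=rhos[si], n_boot=config.n_boot,
                             hits=int(hit_counts[ni, si]))
                  for si in range(len(config.scales))]
        supports.append(_support_from_counts(node.members, counts))
    return supports, dendro


def pick_clusters(supports: Sequence[ClusterSupport], dendrogram: Dendrogram,
                  alpha: float = 0.95) -> list[frozenset[str]]:
    """Maximal significant clusters by top-down traversal.

    A node is reported, and its subtree pruned, when AU >= alpha.
    Leaves are never reported, and neither is the root (always
    supported by construction), so the result is a set of disjoint,
    informative clusters.
    """
    by_members = {s.members: s for s in supports}
    picked: list[frozenset[str]] = []

    def visit(node: DendroNode, is_root: bool) -> None:
        if node.is_leaf:
            return
        sup = by_members.get(node.members)
        if (not is_root and sup is not None and sup.au is not None
                and sup.au >= alpha):
            picked.append(node.members)
            return
        for ch in node.children:
            visit(ch, False)

    visit(dendrogram.root, True)
    return picked
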