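"""Digital differential display (DDD).

EST libraries are digitally pooled into a test pool and a background
pool; for every gene the transcript frequency (EST count over pool
total) is compared between pools.  Differential expression is scored by
a signed fold change on the frequencies and a two-sided Fisher exact
test on the counts, with Benjamini-Hochberg correction across genes.

The fold-change sign convention is always relative to the designated
*test* pool: positive means higher frequency in the test pool.  A gene
observed in only one pool has an undefined finite fold and is reported
with an exclusive "+" or "-" marker instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import LibraryTable, PoolManifest

__all__ = [
    "LibraryPool",
    "FoldChange",
    "DDDRecord",
    "pool_libraries",
    "transcript_frequency",
    "signed_fold",
    "fisher_exact_2x2",
    "run_ddd",
]

#: relative tolerance guarding float ties in the point-probability method
_FISHER_GAMMA = 1 + 1e-7


@dataclass
class LibraryPool:
    """Aggregated per-gene EST counts for one pool of libraries."""

    pool_id: str
    members: frozenset[str]
    counts: dict[str, int]
    total: int

    def count(self, gene: str) -> int:
        return self.counts.get(gene, 0)


def pool_libraries(table: LibraryTable,
                   manifest: PoolManifest) -> tuple[LibraryPool, LibraryPool]:
    """Digitally pool the manifest's libraries into pools A and B.

    Counts are summed per gene per pool; the pool total is the sum of
    the member libraries' declared totals, so genes absent from a pool
    implicitly count 0.
    """
    pools = []
    for pid in ("A", "B"):
        members = manifest.members[pid]
        unknown = members - set(table.totals)
        if unknown:
            raise KeyError(
                f"pool {pid}: unknown library ids {sorted(unknown)}")
        counts = table.counts_for(members)
        pools.append(LibraryPool(
            pool_id=pid,
            members=frozenset(members),
            counts={g: int(c) for g, c in counts.items() if c > 0},
            total=sum(table.totals[m] for m in members)))
    return pools[0], pools[1]


def transcript_frequency(count: int, pool_total: int) -> float:
    """EST count as a fraction of the pool total."""
    if pool_total <= 0:
        raise ValueError("pool total must be positive")
    if not 0 <= count <= pool_total:
        raise ValueError(f"count {count} outside [0, {pool_total}]")
    return count / pool_total


def round_frequency(freq: float, ndigits: int = 4) -> float:
    """Reporting variant of a frequency, rounded half-up."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(freq)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FoldChange:
    """A signed fold change, possibly exclusive.

    ``sign`` is +1 when the test pool dominates, -1 otherwise.
    ``magnitude`` is None for exclusive changes (gene seen in one pool
    only), which render as bare "+"/"-".
    """

    sign: int
    magnitude: float | None

    @property
    def exclusive(self) -> bool:
        return self.magnitude is None

    @property
    def value(self) -> float:
        """Signed magnitude; +/-inf for exclusive changes."""
        if self.magnitude is None:
            return self.sign * math.inf
        return self.sign * self.magnitude

    def rounded(self, ndigits: int = 2) -> float | None:
        if self.magnitude is None:
            return None
        q = Decimal(10) ** -ndigits
        mag = Decimal(repr(self.magnitude)).quantize(
            q, rounding=ROUND_HALF_UP)
        return self.sign * float(mag)

    def __str__(self) -> str:
        s = "+" if self.sign >= 0 else "-"
        if self.magnitude is None:
            return s
        mag = self.rounded()
        assert mag is not None
        text = f"{abs(mag):.2f}".rstrip("0").rstrip(".")
        return f"{s}{text}"


def signed_fold(freq_test: float, freq_other: float) -> FoldChange:
    """Signed fold change between two transcript frequencies.

    The magnitude is the ratio of the larger to the smaller frequency;
    the sign follows the test pool (+ when it is the larger).  If one
    frequency is zero the change is exclusive: "+" when only the test
    pool expresses the gene, "-" when only the other pool does.  Equal
    frequencies give +1.
    """
    if freq_test < 0 or freq_other < 0:
        raise ValueError("frequencies must be non-negative")
    if freq_test == 0 and freq_other == 0:
        raise ValueError("gene absent from both pools; filter first")
    if freq_other == 0:
        return FoldChange(sign=+1, magnitude=None)
    if freq_test == 0:
        return FoldChange(sign=-1, magnitude=None)
    if freq_test >= freq_other:
        return FoldChange(sign=+1, magnitude=freq_test / freq_other)
    return FoldChange(sign=-1, magnitude=freq_other / freq_test)


def fisher_exact_2x2(count_a: int, total_a: int,
                     count_b: int, total_b: int) -> float:
    """Two-sided Fisher exact test on a gene's 2x2 pooled-count table.

    The table is [[count_a, total_a - count_a], [count_b, total_b -
    count_b]].  The p-value is the point-probability two-sided variant:
    with margins fixed, sum the hypergeometric probabilities of every
    table whose probability does not exceed that of the observed table
    (up to a relative tolerance guarding float ties).  The enumeration
    runs over the gene margin ``count_a + count_b``, which is small for
    EST data, so the cost is O(count_a + count_b).
    """
    for name, val in (("count_a", count_a), ("total_a", total_a),
                      ("count_b", count_b), ("total_b", total_b)):
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    if count_a > total_a or count_b > total_b:
        raise ValueError("count exceeds its pool total")
    m = count_a + count_b          # gene margin
    n = total_a + total_b
    if m == 0 or m == n:
        return 1.0
    lo = max(0, m - total_b)
    hi = min(m, total_a)
    support = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(support, n, m, total_a)
    log_obs = logp[count_a - lo]
    keep = logp <= log_obs + math.log(_FISHER_GAMMA)
    if keep.all():
        return 1.0  # every table as extreme as the observed one
    # log-sum-exp over the selected tables
    mx = logp[keep].max()
    p = math.exp(mx) * np.exp(logp[keep] - mx).sum()
    return min(1.0, float(p))


@dataclass
class DDDRecord:
    """Per-gene DDD result for one pool contrast."""

    gene_id: str
    count_a: int
    count_b: int
    freq_a: float
    freq_b: float
    fold: FoldChange
    p_value: float
    q_value: float | None = None

    @property
    def direction(self) -> str:
        if self.fold.exclusive or self.fold.magnitude > 1:
            return "up" if self.fold.sign > 0 else "down"
        return "none"

    def as_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "count_a": self.count_a,
            "count_b": self.count_b,
            "freq_a": f"{round_frequency(self.freq_a):.4f}",
            "freq_b": f"{round_frequency(self.freq_b):.4f}",
            "fold": str(self.fold),
            "p_value": f"{self.p_value:.6g}",
            "q_value": "" if self.q_value is None else f"{self.q_value:.6g}",
            "direction": self.direction,
        }


def run_ddd(table: LibraryTable, manifest: PoolManifest,
            min_fold: float = 2.0,
            alpha: float | None = None) -> list[DDDRecord]:
    """Run digital differential display for one pool contrast.

    Every gene with a nonzero count in either pool is tested; q-values
    are Benjamini-Hochberg over all tested genes.  Records whose finite
    fold magnitude is below ``min_fold`` are dropped; exclusive records
    are always kept.  If ``alpha`` is given, records with q-value above
    it are dropped too (off by default: the 2-fold rule is the operative
    filter).  Output is sorted exclusives first, then by fold magnitude
    descending, ties by gene id.
    """
    pool_a, pool_b = pool_libraries(table, manifest)
    test_is_a = manifest.test_pool == "A"
    genes = sorted(set(pool_a.counts) | set(pool_b.counts))
    if not genes:
        return []
    records = []
    for gene in genes:
        ca, cb = pool_a.count(gene), pool_b.count(gene)
        fa = transcript_frequency(ca, pool_a.total)
        fb = transcript_frequency(cb, pool_b.total)
        if test_is_a:
            fold = signed_fold(fa, fb)
        else:
            fold = signed_fold(fb, fa)
        p = fisher_exact_2x2(ca, pool_a.total, cb, pool_b.total)
        records.append(DDDRecord(gene_id=gene, count_a=ca, count_b=cb,
                                 freq_a=fa, freq_b=fb, fold=fold, p_value=p))
    qvals = multipletests([r.p_value for r in records], method="fdr_bh")[1]
    for rec, q in zip(records, qvals):
        rec.q_value = float(q)
    kept = [r for r in records
            if r.fold.exclusive or r.fold.magnitude >= min_fold]
    if alpha is not None:
        kept = [r for r in kept if r.q_value <= alpha]
    kept.sort(key=lambda r: (not r.fold.exclusive,
                             -(r.fold.magnitude or math.inf),
                             r.gene_id))
    return kept
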