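"""Subtractive candidate filtering.

Narrows a differential-expression hit list by intersecting two DDD
contrasts, removing genes on exclusion lists (for example pan-cancer
genes differentially expressed in many tumour types), and translating
identifiers to a canonical namespace with duplicate collapse.  Every
step appends to a provenance log so the arithmetic of the narrowing is
auditable and reproducible.

The step order is fixed: intersect, then exclude, then map.  Exclusion
and mapping commute only when the mapping is injective on the exclusion
list, so the order matters in general.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .ddd import DDDRecord

__all__ = ["CandidateSet", "intersect_contrasts", "exclude_genes",
           "map_identifiers"]


@dataclass
class ProvenanceStep:
    step: str
    n_before: int
    n_removed: int
    n_after: int

    def __post_init__(self) -> None:
        if self.n_after != self.n_before - self.n_removed:
            raise ValueError(f"inconsistent provenance step {self}")


@dataclass
class CandidateSet:
    """An ordered, deduplicated gene id list with a provenance log."""

    ids: list[str]
    log: list[ProvenanceStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("candidate ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def _record(self, step: str, n_before: int, ids: list[str]) -> None:
        self.ids = ids
        self.log.append(ProvenanceStep(
            step=step, n_before=n_before,
            n_removed=n_before - len(ids), n_after=len(ids)))


def intersect_contrasts(ddd1: Sequence[DDDRecord],
                        ddd2: Sequence[DDDRecord]) -> CandidateSet:
    """Genes differentially expressed in both contrasts.

    The second contrast is treated as the list being narrowed (its hit
    count is the step's n_before), and order follows the second
    contrast's fold magnitude, descending (exclusives first), so the
    disease contrast drives the ranking.
    """
    if not ddd1 or not ddd2:
        raise ValueError("both contrasts must be non-empty")
    in_first = {r.gene_id for r in ddd1}
    ddd2_ids = list(dict.fromkeys(r.gene_id for r in ddd2))
    shared = [g for g in ddd2_ids if g in in_first]
    out = CandidateSet(ids=ddd2_ids)
    out._record("intersect_contrasts", len(ddd2_ids), shared)
    return out


def exclude_genes(candidates: CandidateSet,
                  exclusion: Sequence[str],
                  step: str = "exclude_genes") -> CandidateSet:
    """Remove every candidate on the exclusion list, preserving order."""
    drop = set(exclusion)
    kept = [g for g in candidates.ids if g not in drop]
    out = CandidateSet(ids=list(candidates.ids), log=list(candidates.log))
    out._record(step, len(candidates.ids), kept)
    return out


def map_identifiers(candidates: CandidateSet,
                    mapping: Mapping[str, str]) -> CandidateSet:
    """Translate ids through a source-to-canonical mapping.

    Sources without a mapping are dropped with a warning; canonical
    duplicates are collapsed keeping the first occurrence (mirroring the
    shrink of a hit list on conversion to a canonical gene namespace).
    """
    if not isinstance(mapping, Mapping):
        raise TypeError("mapping must be a mapping with unique source keys")
    mapped: list[str] = []
    seen: set[str] = set()
    for src in candidates.ids:
        if src not in mapping:
            warnings.warn(f"no mapping for id {src!r}; dropped")
            continue
        dst = mapping[src]
        if dst in seen:
            continue
        seen.add(dst)
        mapped.append(dst)
    out = CandidateSet(ids=list(candidates.ids), log=list(candidates.log))
    out._record("map_identifiers", len(candidates.ids), mapped)
    return out


def write_provenance(candidates: CandidateSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("step\tn_before\tn_removed\tn_after\n")
        for s in candidates.log:
            fh.write(f"{s.step}\t{s.n_before}\t{s.n_removed}\t{s.n_after}\n")
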