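"""Biomarker panel assembly.

A panel is the intersection of one statistically supported cluster with
the prioritised biomarker list, reported with both DDD contrasts'
per-gene statistics (the eight-column layout: panel, gene, and
frequency pair plus fold for each contrast).  Panels are numbered in
dendrogram order of their source clusters, not by size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .ddd import DDDRecord, FoldChange, round_frequency

__all__ = ["Panel", "parse_fold", "assemble_panels", "count_direction",
           "panels_from_biomarker_table"]


def parse_fold(text: str) -> FoldChange:
    """Parse a printed fold-change cell ("+12.44", "-112", "+", "-")."""
    text = text.strip()
    if text in ("+", "-"):
        return FoldChange(sign=+1 if text == "+" else -1, magnitude=None)
    sign = -1 if text.startswith("-") else +1
    return FoldChange(sign=sign, magnitude=abs(float(text)))


@dataclass
class MemberStats:
    """One biomarker's frequencies and fold in one contrast."""

    freq_a: str
    freq_b: str
    fold: FoldChange

    @classmethod
    def from_record(cls, rec: DDDRecord) -> "MemberStats":
        return cls(freq_a=f"{round_frequency(rec.freq_a):.4f}",
                   freq_b=f"{round_frequency(rec.freq_b):.4f}",
                   fold=rec.fold)

    @classmethod
    def blank(cls) -> "MemberStats":
        return cls(freq_a="", freq_b="", fold=None)  # type: ignore[arg-type]


@dataclass
class Panel:
    """A numbered biomarker panel derived from one cluster."""

    index: int
    cluster: frozenset[str]
    members: list[str]
    label: str = ""
    ddd1: dict[str, MemberStats] = field(default_factory=dict)
    ddd2: dict[str, MemberStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.members) <= set(self.cluster):
            raise ValueError("panel members must lie in the source cluster")

    def __len__(self) -> int:
        return len(self.members)

    def as_rows(self) -> list[dict]:
        rows = []
        for gene in self.members:
            s1 = self.ddd1.get(gene, MemberStats.blank())
            s2 = self.ddd2.get(gene, MemberStats.blank())
            rows.append({
                "panel": self.index,
                "gene_symbol": gene,
                "ddd1_freq_a": s1.freq_a,
                "ddd1_freq_b": s1.freq_b,
                "ddd1_fold": "" if s1.fold is None else str(s1.fold),
                "ddd2_freq_a": s2.freq_a,
                "ddd2_freq_b": s2.freq_b,
                "ddd2_fold": "" if s2.fold is None else str(s2.fold),
            })
        return rows


def assemble_panels(clusters: Sequence[frozenset[str]],
                    biomarkers: Sequence[str],
                    ddd1: Sequence[DDDRecord] = (),
                    ddd2: Sequence[DDDRecord] = (),
                    labels: Mapping[int, str] | None = None) -> list[Panel]:
    """Intersect each significant cluster with the biomarker list.

    Clusters are visited in the given (dendrogram) order; empty
    intersections are dropped and surviving panels numbered 1..k.
    Per-member statistics are joined from the two contrasts; a
    biomarker absent from both triggers a warning and blank statistics.
    """
    rec1 = {r.gene_id: r for r in ddd1}
    rec2 = {r.gene_id: r for r in ddd2}
    marker_order = {g: i for i, g in enumerate(biomarkers)}
    panels: list[Panel] = []
    for cluster in clusters:
        members = sorted(cluster & set(biomarkers),
                         key=marker_order.__getitem__)
        if not members:
            continue
        idx = len(panels) + 1
        panel = Panel(index=idx, cluster=frozenset(cluster), members=members,
                      label="" if labels is None else labels.get(idx, ""))
        for gene in members:
            if gene not in rec1 and gene not in rec2 and (ddd1 or ddd2):
                warnings.warn(
                    f"biomarker {gene!r} absent from both contrasts; "
                    "statistics left blank")
            if gene in rec1:
                panel.ddd1[gene] = MemberStats.from_record(rec1[gene])
            if gene in rec2:
                panel.ddd2[gene] = MemberStats.from_record(rec2[gene])
        panels.append(panel)
    return panels


def count_direction(panel: Panel, contrast: str
                    ) -> tuple[int, int, int, int]:
    """Tally (n_up, n_down, n_exclusive_up, n_exclusive_down).

    Finite folds of magnitude 1 (no change) count in no bin.
    """
    if contrast not in ("ddd1", "ddd2"):
        raise ValueError("contrast must be 'ddd1' or 'ddd2'")
    stats: dict[str, MemberStats] = getattr(panel, contrast)
    n_up = n_down = n_xup = n_xdown = 0
    for gene in panel.members:
        s = stats.get(gene)
        if s is None or s.fold is None:
            continue
        if s.fold.exclusive:
            if s.fold.sign > 0:
                n_xup += 1
            else:
                n_xdown += 1
        elif s.fold.magnitude > 1:
            if s.fold.sign > 0:
                n_up += 1
            else:
                n_down += 1
    return n_up, n_down, n_xup, n_xdown


def panels_from_biomarker_table(frame: pd.DataFrame) -> list[Panel]:
    """Rebuild the four printed biomarker panels from the packaged table."""
    panels = []
    for panel_no, sub in frame.groupby("panel", sort=True):
        members = list(sub["gene_symbol"])
        panel = Panel(index=int(panel_no), cluster=frozenset(members),
                      members=members,
                      label=str(sub["biomarker_class"].iloc[0]))
        for _, row in sub.iterrows():
            gene = row["gene_symbol"]
            panel.ddd1[gene] = MemberStats(
                freq_a=row["ddd1_freq_a"], freq_b=row["ddd1_freq_b"],
                fold=parse_fold(row["ddd1_fold"]))
            panel.ddd2[gene] = MemberStats(
                freq_a=row["ddd2_freq_a"], freq_b=row["ddd2_freq_b"],
                fold=parse_fold(row["ddd2_fold"]))
        panels.append(panel)
    return panels
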