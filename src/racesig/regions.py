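"""Interval algebra for sweep x QTL and cross-population region comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rio


@dataclass
class IntervalSet:
    """Labelled 0-based half-open intervals grouped by chromosome."""

    intervals: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels: set[str] = set()
        for chrom, items in self.intervals.items():
            items.sort(key=lambda t: (t[0], t[1]))
            for start, end, label in items:
                if start >= end:
                    raise ValueError(f"empty interval {label!r} on {chrom}")
                if label in labels:
                    raise ValueError(f"duplicate label {label!r}")
                labels.add(label)

    def add(self, chrom: str, start: int, end: int, label: str) -> None:
        self.intervals.setdefault(chrom, []).append((start, end, label))
        self.__post_init__()

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def items(self):
        for chrom, rows in self.intervals.items():
            for start, end, label in rows:
                yield chrom, start, end, label

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        out: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, label in rio.read_bed(path):
            out.setdefault(chrom, []).append((start, end, label))
        return cls(out)

    @classmethod
    def from_tuples(cls, rows) -> "IntervalSet":
        out: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, label in rows:
            out.setdefault(chrom, []).append((start, end, label))
        return cls(out)

    def to_bed(self, path: str | Path) -> None:
        rio.write_bed(path, list(self.items()))


def overlap(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> pd.DataFrame:
    """All interval pairs sharing at least ``min_bp`` bases.

    Sweep-line over per-chromosome sorted lists; the output equals the
    all-pairs brute force.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    rows = []
    for chrom in sorted(set(a.intervals) & set(b.intervals)):
        items_b = b.intervals[chrom]
        for a_start, a_end, a_label in a.intervals[chrom]:
            for b_start, b_end, b_label in items_b:
                if b_start >= a_end:
                    break
                ov = min(a_end, b_end) - max(a_start, b_start)
                if ov >= min_bp:
                    rows.append({
                        "chrom": chrom, "a": a_label, "b": b_label,
                        "a_start": a_start, "a_end": a_end,
                        "b_start": b_start, "b_end": b_end,
                        "overlap_bp": ov,
                    })
    return pd.DataFrame(rows, columns=["chrom", "a", "b", "a_start", "a_end",
                                       "b_start", "b_end", "overlap_bp"])


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def venn_tally(
    sets: dict[str, IntervalSet], reciprocal_frac: float = 0.5
) -> tuple[dict[tuple[str, ...], int], list[dict]]:
    """Cluster regions across named sets and tally subset membership.

    Two intervals from different sets are "the same region" when their
    overlap covers at least ``reciprocal_frac`` of both.  Clusters are
    connected components of that relation; each is assigned the subset of
    set names it touches.  Tallies partition the clusters.
    """
    if len(sets) < 2:
        raise ValueError("need at least two interval sets")
    nodes = []  # (set_name, chrom, start, end, label)
    for name, iset in sets.items():
        for chrom, start, end, label in iset.items():
            nodes.append((name, chrom, start, end, label))
    uf = _UnionFind(len(nodes))
    for i in range(len(nodes)):
        ni, ci, si, ei, _ = nodes[i]
        for j in range(i + 1, len(nodes)):
            nj, cj, sj, ej, _ = nodes[j]
            if ni == nj or ci != cj:
                continue
            ov = min(ei, ej) - max(si, sj)
            if ov <= 0:
                continue
            if ov >= reciprocal_frac * (ei - si) and ov >= reciprocal_frac * (ej - sj):
                uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        clusters.setdefault(uf.find(i), []).append(i)
    tallies: dict[tuple[str, ...], int] = {}
    cluster_rows = []
    for members in clusters.values():
        names = tuple(sorted({nodes[i][0] for i in members}))
        tallies[names] = tallies.get(names, 0) + 1
        cluster_rows.append({
            "sets": names,
            "chrom": nodes[members[0]][1],
            "start": min(nodes[i][2] for i in members),
            "end": max(nodes[i][3] for i in members),
            "labels": [nodes[i][4] for i in members],
        })
    return tallies, cluster_rows
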