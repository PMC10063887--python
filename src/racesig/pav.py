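"""Gene presence–absence calling from k-mer evidence.

A sample's k-mers are placed on an annotated reference by exact canonical
lookup (every matching locus counts), per-gene horizontal and vertical
coverage are derived from the per-base hit depth, and a gene is called
present when at least ``min_support`` distinct k-mers intersect it — three
by default.  Exact lookup is deterministic and, at k of 31/47, spurious
matches are negligible, so no mismatch-tolerant mapping is attempted.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel
from .kmers import KmerCountTable, canonical


@dataclass
class ReferenceIndex:
    """Exact canonical k-mer -> loci index over a reference."""

    k: int
    loci: dict[str, list[tuple[str, int]]]    # canonical k-mer -> [(chrom, start0)]
    chrom_lengths: dict[str, int]


def index_reference(reference: dict[str, str], k: int) -> ReferenceIndex:
    loci: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in reference.items():
        seq = seq.upper()
        n = len(seq)
        for i in range(n - k + 1):
            window = seq[i : i + k]
            if any(b not in "ACGT" for b in window):
                continue
            loci.setdefault(canonical(window), []).append((chrom, i))
    return ReferenceIndex(k=k, loci=loci,
                          chrom_lengths={c: len(s) for c, s in reference.items()})


@dataclass
class KmerHits:
    """Placement of a k-mer set on a reference."""

    k: int
    depth: dict[str, np.ndarray]               # per-base overlapping-hit depth
    kmer_positions: dict[str, list[tuple[str, int]]]

    def n_placed(self) -> int:
        return len(self.kmer_positions)


def place_kmers(kmers, reference, k: int | None = None,
                index: ReferenceIndex | None = None) -> KmerHits:
    """Place k-mers by exact canonical lookup; multi-mappers hit all loci.

    ``kmers`` is a KmerCountTable or an iterable of k-mer strings;
    ``reference`` a {chrom: seq} dict (ignored when ``index`` is given).
    """
    if isinstance(kmers, KmerCountTable):
        if k is None:
            k = kmers.k
        elif k != kmers.k:
            raise ValueError("k disagrees with the count table")
        query = kmers.counts.keys()
    else:
        query = list(kmers)
        if k is None:
            if not query:
                raise ValueError("k required for an empty k-mer set")
            k = len(next(iter(query)))
    if index is None:
        index = index_reference(reference, k)
    elif index.k != k:
        raise ValueError("reference index built at a different k")

    diffs = {c: np.zeros(n + 1, dtype=np.int32) for c, n in index.chrom_lengths.items()}
    positions: dict[str, list[tuple[str, int]]] = {}
    for km in query:
        if len(km) != k:
            raise ValueError(f"k-mer {km[:12]!r}... has length {len(km)}, expected {k}")
        hits = index.loci.get(canonical(km))
        if not hits:
            continue
        positions[km] = hits
        for chrom, start in hits:
            d = diffs[chrom]
            d[start] += 1
            d[start + k] -= 1
    depth = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return KmerHits(k=k, depth=depth, kmer_positions=positions)


def gene_coverage(hits: KmerHits, genes: list[GeneModel]) -> pd.DataFrame:
    """Per-gene distinct supporting k-mers plus horizontal/vertical coverage.

    A k-mer supports a gene when any of its hit intervals [start, start+k)
    intersects the gene interval; horizontal coverage is the fraction of
    gene bases at depth > 0 and vertical coverage the mean depth.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: g.start)
    starts = {c: [g.start for g in glist] for c, glist in by_chrom.items()}
    max_len = {c: max(g.length for g in glist) for c, glist in by_chrom.items()}

    support: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    for km, occ in hits.kmer_positions.items():
        for chrom, pos in occ:
            glist = by_chrom.get(chrom)
            if not glist:
                continue
            lo, hi = pos, pos + hits.k
            # candidate genes start in [lo - max_len, hi); scan left from the
            # last gene starting before hi
            i = bisect_left(starts[chrom], hi) - 1
            while i >= 0 and glist[i].start > lo - max_len[chrom]:
                if glist[i].end > lo:
                    support[glist[i].gene_id].add(km)
                i -= 1

    rows = []
    for g in genes:
        d = hits.depth.get(g.chrom)
        seg = d[g.start : g.end] if d is not None else np.zeros(g.length)
        rows.append({
            "gene_id": g.gene_id,
            "supporting_kmers": len(support[g.gene_id]),
            "horizontal_coverage": float(np.mean(seg > 0)),
            "vertical_coverage": float(np.mean(seg)),
        })
    return pd.DataFrame(rows).set_index("gene_id")


def call_pav(
    coverages: dict[str, pd.DataFrame],
    min_support: int = 3,
    min_horizontal: float | None = None,
) -> pd.DataFrame:
    """Presence/absence matrix (genes x samples) from coverage tables.

    A gene is present in a sample iff its distinct supporting k-mers are
    >= ``min_support`` (and, when the optional secondary filter is on, its
    horizontal coverage >= ``min_horizontal``).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    samples = list(coverages)
    genes = coverages[samples[0]].index
    mat = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for s in samples:
        cov = coverages[s]
        present = cov["supporting_kmers"] >= min_support
        if min_horizontal is not None:
            present &= cov["horizontal_coverage"] >= min_horizontal
        mat[s] = present.astype(int)
    return mat


def pav_summaries(calls: pd.DataFrame, groups: dict[str, str]) -> dict:
    """Core genes and per-group exclusive genes from a PAV matrix.

    "Common" genes are present in every sample; a gene is exclusive to a
    group when it is present in at least one of that group's samples and
    in none outside it.
    """
    group_names = list(dict.fromkeys(groups.values()))
    common = calls.index[(calls == 1).all(axis=1)].tolist()
    exclusive: dict[str, list[str]] = {}
    for g in group_names:
        inside = [s for s in calls.columns if groups[s] == g]
        outside = [s for s in calls.columns if groups[s] != g]
        mask = (calls[inside] == 1).any(axis=1)
        if outside:
            mask &= (calls[outside] == 0).all(axis=1)
        exclusive[g] = calls.index[mask].tolist()
    return {"common_genes": common, "group_exclusive": exclusive}


def pav_pipeline(
    sample_kmers: dict[str, KmerCountTable],
    reference: dict[str, str],
    genes: list[GeneModel],
    min_support: int = 3,
    min_horizontal: float | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Place each sample's k-mers, compute coverages and call the PAV matrix."""
    ks = {t.k for t in sample_kmers.values()}
    if len(ks) != 1:
        raise ValueError("all samples must use the same k")
    index = index_reference(reference, ks.pop())
    coverages = {
        s: gene_coverage(place_kmers(t, reference, index=index), genes)
        for s, t in sample_kmers.items()
    }
    return call_pav(coverages, min_support, min_horizontal), coverages
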