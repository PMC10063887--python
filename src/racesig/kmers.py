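"""Canonical k-mer counting, MinHash sketch distances and sharing analysis.

The race-signature workflow reduces each accession (reads or assembly) to
its canonical k-mer multiset, compares accessions through bottom-s MinHash
sketches and the Mash distance, and decomposes the union of k-mers across
accessions into sharing classes (present in all five races, in four, ...,
private to one race).
"""

from __future__ import annotations

import json
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import iter_sequences, revcomp

_ACGT_RUN = re.compile(r"[^ACGT]+")

#: Recorded seed constant for the 64-bit k-mer hash; changing it changes
#: every sketch, so it is fixed for cross-run reproducibility.
HASH_SEED = 0x3C6EF372FE94F82A
_MASK64 = (1 << 64) - 1
_TO_DIGITS = str.maketrans("ACGT", "0123")

#: k presets used in the field: 47 for distinct-k-mer comparisons, 31 for
#: hash-based counting.  Neither is hard-coded anywhere; both are plain
#: config values.
K_PRESETS = {"distinct": 47, "count": 31}


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _check_k(k: int) -> None:
    if not (0 < k <= 255):
        raise ValueError("k must be in (0, 255]")
    if k % 2 == 0:
        raise ValueError(
            "k must be odd: even k admits palindromic k-mers equal to their "
            "own reverse complement, making canonicalization ambiguous"
        )


@dataclass
class KmerCountTable:
    """Abundances of canonical k-mers from one sample."""

    k: int
    counts: dict[str, int]
    source: str = ""

    def __len__(self) -> int:
        return len(self.counts)

    def total_occurrences(self) -> int:
        return sum(self.counts.values())


def count_kmers(seqs, k: int, min_count: int = 1, source: str = "") -> KmerCountTable:
    """Count canonical k-mers with abundance >= ``min_count``.

    ``seqs`` may be a FASTA/FASTQ path, an iterable of sequence strings, or
    one sequence.  Windows containing non-ACGT characters contribute no
    k-mer.  ``min_count=2`` reproduces the singleton filter used to drop
    likely sequencing-error k-mers.
    """
    _check_k(k)
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter[str] = Counter()
    for seq in iter_sequences(seqs):
        for chunk in _ACGT_RUN.split(seq):
            n = len(chunk)
            if n < k:
                continue
            rc = revcomp(chunk)
            for i in range(n - k + 1):
                fwd = chunk[i : i + k]
                rev = rc[n - i - k : n - i]
                counts[fwd if fwd <= rev else rev] += 1
    if min_count > 1:
        counts = Counter({km: c for km, c in counts.items() if c >= min_count})
    return KmerCountTable(k=k, counts=dict(counts), source=source)


def abundance_histogram(table: KmerCountTable) -> dict[int, int]:
    """Map abundance -> number of distinct k-mers at that abundance."""
    return dict(sorted(Counter(table.counts.values()).items()))


def choose_k(seqs, k_grid, min_count: int = 1) -> tuple[int, dict[int, int]]:
    """Pick the k maximising distinct k-mers with abundance >= min_count.

    A proxy for histogram-model optimal-k estimators: on low-error data the
    count of "genomic" (non-singleton-filtered) distinct k-mers peaks at
    the same k.  Ties go to the smaller k.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    for k in k_grid:
        _check_k(k)
    seq_list = list(iter_sequences(seqs))
    per_k = {k: len(count_kmers(seq_list, k, min_count)) for k in k_grid}
    best = max(k_grid, key=lambda k: (per_k[k], -k))
    return best, per_k


# ---------------------------------------------------------------------------
# MinHash sketches and Mash distance
# ---------------------------------------------------------------------------

def _splitmix64(x: int) -> int:
    z = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def kmer_hash(kmer: str) -> int:
    """Seeded 64-bit hash of a canonical k-mer (2-bit packed, splitmix64).

    k-mers longer than 32 bases are folded limb-wise so every length gets
    the full 64-bit range; the function is platform-independent.
    """
    v = int(kmer.translate(_TO_DIGITS), 4) if kmer else 0
    h = HASH_SEED
    while True:
        h = _splitmix64(h ^ (v & _MASK64))
        v >>= 64
        if v == 0:
            return h


@dataclass
class MinHashSketch:
    """Bottom-s sketch: the s smallest hash values of the canonical k-mer set."""

    k: int
    sketch_size: int
    hashes: list[int] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.hashes, self.hashes[1:])):
            raise ValueError("sketch hashes must be strictly increasing")
        if len(self.hashes) > self.sketch_size:
            raise ValueError("sketch larger than sketch_size")

    @property
    def undersized(self) -> bool:
        return len(self.hashes) < self.sketch_size

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"k": self.k, "sketch_size": self.sketch_size,
             "hashes": self.hashes, "source": self.source}))

    @classmethod
    def from_json(cls, path: str | Path) -> "MinHashSketch":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def sketch(source, k: int | None = None, s: int = 1000,
           min_count: int = 1, name: str = "") -> MinHashSketch:
    """Bottom-s MinHash sketch of a count table, sequence(s) or file."""
    if s < 1:
        raise ValueError("sketch size s must be >= 1")
    if isinstance(source, KmerCountTable):
        k = source.k
        kmers = source.counts.keys()
        name = name or source.source
    else:
        if k is None:
            raise ValueError("k is required when sketching raw sequence")
        kmers = count_kmers(source, k, min_count).counts.keys()
    hashes = sorted({kmer_hash(km) for km in kmers})[:s]
    sk = MinHashSketch(k=k, sketch_size=s, hashes=hashes, source=name)
    if sk.undersized:
        warnings.warn(
            f"fewer than s={s} distinct k-mers ({len(hashes)}); sketch is short",
            stacklevel=2)
    return sk


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> tuple[float, float]:
    """Jaccard estimate and Mash distance D = -(1/k) ln(2j / (1 + j)).

    j is estimated on the bottom-s sketch of the union; disjoint sketches
    (j = 0) return the capped distance 1.
    """
    import math

    if a.k != b.k:
        raise ValueError(f"sketch k mismatch: {a.k} != {b.k}")
    s = min(a.sketch_size, b.sketch_size)
    set_a, set_b = set(a.hashes), set(b.hashes)
    merged = sorted(set_a | set_b)[:s]
    if not merged:
        return 0.0, 1.0
    shared = sum(1 for h in merged if h in set_a and h in set_b)
    j = shared / len(merged)
    if j == 0:
        return 0.0, 1.0
    d = max(0.0, -math.log(2 * j / (1 + j)) / a.k)
    return j, d


def distance_matrix(sketches: list[MinHashSketch]) -> pd.DataFrame:
    """Square symmetric Mash distance matrix over a sketch list."""
    names = [sk.source or f"s{i}" for i, sk in enumerate(sketches)]
    n = len(sketches)
    mat = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            _, d = mash_distance(sketches[i], sketches[j])
            mat[i][j] = mat[j][i] = d
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# Sharing decomposition and group-specific k-mers
# ---------------------------------------------------------------------------

@dataclass
class SharingProfile:
    """Exact membership of every distinct k-mer across a sample panel."""

    k: int
    samples: list[str]
    membership: dict[str, frozenset]

    def tallies(self) -> dict[int, int]:
        """#samples-sharing-the-k-mer -> count; partitions the union."""
        out: Counter[int] = Counter(len(m) for m in self.membership.values())
        return dict(sorted(out.items()))

    def sample_unique(self) -> dict[str, int]:
        out = {s: 0 for s in self.samples}
        for members in self.membership.values():
            if len(members) == 1:
                (s,) = members
                out[s] += 1
        return out

    def union_size(self) -> int:
        return len(self.membership)

    def class_table(self) -> pd.DataFrame:
        total = self.union_size()
        rows = [
            {"n_samples": n, "kmers": c, "fraction": c / total if total else 0.0}
            for n, c in self.tallies().items()
        ]
        return pd.DataFrame(rows)


def sharing_decomposition(tables: list[KmerCountTable]) -> SharingProfile:
    """Assign every distinct k-mer its exact set of carrying samples."""
    if not tables:
        raise ValueError("need at least one table")
    ks = {t.k for t in tables}
    if len(ks) != 1:
        raise ValueError(f"tables have mixed k: {sorted(ks)}")
    names = []
    for i, t in enumerate(tables):
        names.append(t.source or f"sample{i + 1}")
    membership: dict[str, set] = {}
    for name, t in zip(names, tables):
        for km in t.counts:
            membership.setdefault(km, set()).add(name)
    return SharingProfile(
        k=ks.pop(), samples=names,
        membership={km: frozenset(m) for km, m in membership.items()},
    )


def group_specific_kmers(
    profile: SharingProfile, groups: dict[str, str]
) -> dict[str, set[str]]:
    """k-mers whose every carrier sample belongs to a single group."""
    missing = [s for s in profile.samples if s not in groups]
    if missing:
        raise ValueError(f"samples without a group assignment: {missing}")
    out: dict[str, set[str]] = {g: set() for g in dict.fromkeys(groups.values())}
    for km, members in profile.membership.items():
        gs = {groups[s] for s in members}
        if len(gs) == 1:
            out[gs.pop()].add(km)
    return out
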