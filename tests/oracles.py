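"""Independent brute-force oracles used to validate the statistics.

Every function here is a direct, naive transcription of the published
definition (explicit loops, pairwise enumeration), deliberately sharing no
code with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pi_pairwise(alleles: np.ndarray) -> float:
    """Mean pairwise differences summed over sites, by full enumeration."""
    n = alleles.shape[0]
    total = 0
    n_pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int(np.sum(alleles[i] != alleles[j]))
        n_pairs += 1
    return total / n_pairs


def tajima_d_direct(alleles: np.ndarray) -> float:
    """Tajima's D from the constants, written out term by term."""
    n = alleles.shape[0]
    seg_cols = []
    for c in range(alleles.shape[1]):
        col = alleles[:, c]
        if 0 < col.sum() < n:
            seg_cols.append(c)
    S = len(seg_cols)
    if S == 0:
        return float("nan")
    theta_pi = pi_pairwise(alleles[:, seg_cols])
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    num = theta_pi - S / a1
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0 if abs(num) < 1e-12 else float("nan")
    return num / math.sqrt(var)


def wc_fst_site(genotypes: list[list[int]], pops: list[str]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) a, b, c for one site, scalar arithmetic.

    ``genotypes`` holds per-individual [allele1, allele2] (0/1, -1 missing).
    """
    by_pop: dict[str, list[list[int]]] = {}
    for g, p in zip(genotypes, pops):
        if g[0] >= 0 and g[1] >= 0:
            by_pop.setdefault(p, []).append(g)
    by_pop = {p: gs for p, gs in by_pop.items() if len(gs) >= 2}
    r = len(by_pop)
    if r < 2:
        return float("nan"), float("nan"), float("nan")
    ns, ps, hs = [], [], []
    for gs in by_pop.values():
        n = len(gs)
        p_freq = sum(a + b for a, b in gs) / (2.0 * n)
        h = sum(1 for a, b in gs if a != b) / n
        ns.append(n)
        ps.append(p_freq)
        hs.append(h)
    nbar = sum(ns) / r
    nc = (sum(ns) - sum(x * x for x in ns) / sum(ns)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def ehh_enumeration(alleles: np.ndarray, positions: np.ndarray, focal: int,
                    allele: int) -> dict[int, float]:
    """EHH at every site by enumerating distinct extended haplotype strings."""
    carriers = [h for h in range(alleles.shape[0]) if alleles[h, focal] == allele]
    n_c = len(carriers)
    denom = n_c * (n_c - 1) / 2
    out: dict[int, float] = {}
    for x in range(alleles.shape[1]):
        lo, hi = min(focal, x), max(focal, x)
        strings: dict[tuple, int] = {}
        for h in carriers:
            key = tuple(alleles[h, lo : hi + 1])
            strings[key] = strings.get(key, 0) + 1
        out[int(positions[x])] = sum(m * (m - 1) / 2 for m in strings.values()) / denom
    return out


def overlaps_allpairs(a_rows, b_rows, min_bp: int = 1):
    """All overlapping interval pairs, quadratic scan."""
    out = []
    for chrom_a, sa, ea, la in a_rows:
        for chrom_b, sb, eb, lb in b_rows:
            if chrom_a != chrom_b:
                continue
            ov = min(ea, eb) - max(sa, sb)
            if ov >= min_bp:
                out.append((la, lb, ov))
    return sorted(out)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary tree; returns (taxa labels, exact path-length matrix).

    Built by repeatedly joining two random clusters with fresh positive
    branch lengths, accumulating tip-to-tip distances exactly.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    dist = np.zeros((n_taxa, n_taxa))
    # depth bookkeeping: distance from each tip up to its cluster root
    clusters = [[i] for i in range(n_taxa)]
    up = np.zeros(n_taxa)
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        bi, bj = rng.uniform(0.05, 1.0, size=2)
        for a in clusters[i]:
            for b in clusters[j]:
                dist[a, b] = dist[b, a] = up[a] + bi + up[b] + bj
        for a in clusters[i]:
            up[a] += bi
        for b in clusters[j]:
            up[b] += bj
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return labels, dist
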