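"""Diversity and differentiation statistics.

Per-site nucleotide diversity, Watterson's theta and Tajima's D in
windows, the Weir–Cockerham (1984) variance-components Fst estimator,
linkage-disequilibrium decay, and the composite classifier that intersects
extreme Tajima's D windows with significantly low windowed Fst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeMatrix
from .io import GeneModel

# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(derived_count: int, n_haplotypes: int) -> float:
    """Unbiased per-site heterozygosity: 2 c0 c1 / (n (n - 1))."""
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    c1 = derived_count
    c0 = n_haplotypes - c1
    return 2.0 * c0 * c1 / (n_haplotypes * (n_haplotypes - 1))


def sites_pi(alleles: np.ndarray) -> np.ndarray:
    """Vectorized ``site_pi`` over a (haplotypes x sites) 0/1 matrix."""
    n = alleles.shape[0]
    c1 = alleles.sum(axis=0).astype(float)
    return 2.0 * c1 * (n - c1) / (n * (n - 1))


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants for sample size n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(alleles: np.ndarray) -> float:
    """Tajima's D for one window of 0/1 haplotypes.

    D = (theta_pi - S/a1) / sqrt(e1 S + e2 S (S - 1)); NaN when S = 0.
    """
    n = alleles.shape[0]
    c1 = alleles.sum(axis=0)
    seg = (c1 > 0) & (c1 < n)
    S = int(np.sum(seg))
    if S == 0:
        return float("nan")
    k = tajima_constants(n)
    theta_pi = float(np.sum(sites_pi(alleles[:, seg])))
    num = theta_pi - S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        # n = 2 has zero sampling variance and theta_pi == theta_w exactly
        return 0.0 if abs(num) < 1e-12 else float("nan")
    return num / np.sqrt(var)


def diversity_scan(
    hap: HaplotypeMatrix,
    window_bp: int = 100_000,
    chrom_length: int | None = None,
    population: str | None = None,
) -> pd.DataFrame:
    """Windowed S, theta_pi, theta_w (per window and per bp) and Tajima's D.

    Windows are fixed-width, non-overlapping, per chromosome; Tajima's D is
    NaN in windows without segregating sites.
    """
    if population is not None:
        hap = hap.subset_population(population)
    n = hap.n_haplotypes
    k = tajima_constants(n)
    rows = []
    for chrom in hap.chromosomes():
        sub = hap.subset_chromosome(chrom)
        last = chrom_length if chrom_length else int(sub.positions.max()) + 1
        for start in range(0, last, window_bp):
            end = min(start + window_bp, last)
            mask = (sub.positions >= start) & (sub.positions < end)
            block = sub.alleles[:, mask]
            c1 = block.sum(axis=0)
            seg = (c1 > 0) & (c1 < n)
            S = int(np.sum(seg))
            theta_pi = float(np.sum(sites_pi(block))) if block.size else 0.0
            theta_w = S / k["a1"]
            if S > 0:
                var = k["e1"] * S + k["e2"] * S * (S - 1)
                d = (theta_pi - theta_w) / np.sqrt(var) if var > 0 else np.nan
            else:
                d = np.nan
            rows.append({
                "chrom": chrom, "start": start, "end": end, "n_haplotypes": n,
                "S": S, "theta_pi": theta_pi, "theta_w": theta_w,
                "pi_per_bp": theta_pi / (end - start),
                "tajima_d": d,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

@dataclass
class FstScan:
    """Per-site Weir-Cockerham variance components."""

    chrom: np.ndarray
    positions: np.ndarray
    a: np.ndarray          # among-population component
    b: np.ndarray          # among-individual-within-population
    c: np.ndarray          # within-individual
    fst: np.ndarray        # a / (a + b + c); NaN when undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.positions,
                             "a": self.a, "b": self.b, "c": self.c, "fst": self.fst})

    def ratio_of_sums(self) -> float:
        """Multi-site Fst as sum(a) / sum(a + b + c) over defined sites."""
        ok = np.isfinite(self.a)
        denom = np.sum(self.a[ok] + self.b[ok] + self.c[ok])
        return float(np.sum(self.a[ok]) / denom) if denom != 0 else float("nan")


def wc_fst(
    dosages: np.ndarray,
    pop_labels,
    chrom: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> FstScan:
    """Per-site Weir & Cockerham (1984) a, b, c components and Fst.

    ``dosages`` is (n_samples x n_sites) diploid derived-allele dosage
    (0/1/2, -1 for missing).  Negative single-site estimates are reported
    as-is.  Sites where fewer than two populations have >= 2 genotyped
    individuals are NaN.
    """
    dosages = np.asarray(dosages)
    pop_labels = np.asarray(pop_labels)
    pops = list(dict.fromkeys(pop_labels.tolist()))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    n_sites = dosages.shape[1]

    n_i, p_i, h_i = [], [], []
    for pop in pops:
        block = dosages[pop_labels == pop]
        ok = block >= 0
        n = ok.sum(axis=0).astype(float)                      # diploids genotyped
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, block, 0).sum(axis=0) / (2 * n)
            h = np.where(ok & (block == 1), 1, 0).sum(axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)          # (r, n_sites)
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    usable = n_i >= 2
    r = usable.sum(axis=0).astype(float)
    valid = r >= 2
    n_i = np.where(usable, n_i, 0.0)
    w = np.where(usable, n_i, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.sum(axis=0) / r
        nc = (n_i.sum(axis=0) - (n_i**2).sum(axis=0) / n_i.sum(axis=0)) / (r - 1)
        pbar = (w * np.nan_to_num(p_i)).sum(axis=0) / (r * nbar)
        s2 = (w * (np.nan_to_num(p_i) - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (w * np.nan_to_num(h_i)).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        fst = np.where(denom != 0, a / denom, np.nan)

    bad = ~valid
    for arr in (a, b, c, fst):
        arr[bad] = np.nan
    if chrom is None:
        chrom = np.array(["chr"] * n_sites, dtype=object)
    if positions is None:
        positions = np.arange(n_sites)
    return FstScan(chrom=np.asarray(chrom), positions=np.asarray(positions),
                   a=a, b=b, c=c, fst=fst)


def hap_fst(hap: HaplotypeMatrix, pops: list[str] | None = None) -> FstScan:
    """Weir-Cockerham scan straight from a haplotype matrix."""
    labels = np.array([hap.populations[s] for s in hap.sample_ids])
    if pops is not None:
        keep = np.isin(labels, pops)
        dos = hap.dosages()[keep]
        labels = labels[keep]
    else:
        dos = hap.dosages()
    return wc_fst(dos, labels, chrom=hap.chrom, positions=hap.positions)


def windowed_fst(scan: FstScan, window_bp: int = 100_000) -> pd.DataFrame:
    """Ratio-of-sums Fst in fixed windows."""
    df = scan.to_frame().dropna(subset=["a"])
    rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        win = (grp["pos"] // window_bp).astype(int)
        for w, g in grp.groupby(win):
            denom = (g["a"] + g["b"] + g["c"]).sum()
            rows.append({
                "chrom": chrom, "start": int(w) * window_bp,
                "end": (int(w) + 1) * window_bp,
                "n_sites": len(g),
                "fst": g["a"].sum() / denom if denom != 0 else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(
    hap: HaplotypeMatrix,
    maf: float = 0.01,
    max_dist_kb: int = 2000,
    bin_kb: int = 50,
    use_haplotypes: bool = True,
) -> pd.DataFrame:
    """Distance-binned mean r-squared between site pairs.

    r2 is the squared Pearson correlation of haplotype alleles (or of
    genotype dosages when ``use_haplotypes`` is False, the composite-LD
    choice for unphased data).  No monotone smoothing is applied.
    """
    max_dist = max_dist_kb * 1000
    rows = []
    for chrom in hap.chromosomes():
        sub = hap.subset_chromosome(chrom)
        freq = sub.derived_freq()
        keep = np.minimum(freq, 1 - freq) >= maf
        X = (sub.alleles[:, keep] if use_haplotypes else sub.dosages()[:, keep]).astype(float)
        pos = sub.positions[keep]
        sd = X.std(axis=0)
        ok = sd > 0
        X, pos = X[:, ok], pos[ok]
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        n = X.shape[0]
        m = X.shape[1]
        for i in range(m):
            j = i + 1
            while j < m and pos[j] - pos[i] <= max_dist:
                r = float(Z[:, i] @ Z[:, j]) / n
                rows.append((int(pos[j] - pos[i]), r * r))
                j += 1
        # distance-0 duplicates (same position would violate the matrix
        # invariant, so only cross-chromosome calls ever see them)
    df = pd.DataFrame(rows, columns=["dist", "r2"])
    if df.empty:
        return pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2", "n_pairs"])
    bins = (df["dist"] // (bin_kb * 1000)).astype(int)
    out = df.groupby(bins).agg(mean_r2=("r2", "mean"), n_pairs=("r2", "size"))
    out["bin_start"] = out.index * bin_kb * 1000
    out["bin_end"] = (out.index + 1) * bin_kb * 1000
    return out[["bin_start", "bin_end", "mean_r2", "n_pairs"]].reset_index(drop=True)


def pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """r-squared between two allele/dosage vectors (D^2 / p1 q1 p2 q2 form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Composite Tajima's D x Fst classifier
# ---------------------------------------------------------------------------

#: Paper-style aliases applied to extreme-D windows that also fall in the
#: low-Fst tail; the raw quantile classes are always reported alongside.
DEFAULT_LABEL_ALIASES = {
    "negative_extreme": "purifying_or_expansion",
    "positive_extreme": "balancing_or_contraction",
}


def composite_selection(
    windows: pd.DataFrame,
    fst_windows: pd.DataFrame,
    d_quantiles: tuple[float, float] = (0.05, 0.95),
    fst_low_quantile: float = 0.05,
    genes: list[GeneModel] | None = None,
    label_aliases: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Intersect extreme Tajima's D windows with significantly low Fst.

    Both inputs must share the (chrom, start, end) windowing.  D windows
    beyond the empirical tail quantiles are "extreme"; Fst windows in the
    bottom ``fst_low_quantile`` are "significantly_low"; windows in both
    sets are flagged and given the alias label for their D sign.
    """
    if label_aliases is None:
        label_aliases = DEFAULT_LABEL_ALIASES
    merged = windows.merge(
        fst_windows[["chrom", "start", "end", "fst"]],
        on=["chrom", "start", "end"], how="inner",
    )
    d = merged["tajima_d"]
    lo, hi = d.quantile(d_quantiles[0]), d.quantile(d_quantiles[1])
    fst_lo = merged["fst"].quantile(fst_low_quantile)

    def d_class(v: float) -> str:
        if not np.isfinite(v):
            return "undefined"
        if v <= lo:
            return "negative_extreme"
        if v >= hi:
            return "positive_extreme"
        return "neutral"

    merged["tajima_class"] = d.map(d_class)
    merged["fst_class"] = np.where(
        merged["fst"] <= fst_lo, "significantly_low", "other")
    flagged = (merged["tajima_class"].isin(label_aliases)
               & (merged["fst_class"] == "significantly_low"))
    merged["flagged"] = flagged
    merged["label"] = np.where(
        flagged, merged["tajima_class"].map(label_aliases), merged["tajima_class"])
    if genes is not None:
        genic = np.zeros(len(merged), dtype=bool)
        for g in genes:
            genic |= ((merged["chrom"] == g.chrom)
                      & (merged["start"] < g.end) & (g.start < merged["end"])).to_numpy()
        merged["genic"] = genic
    return merged
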