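"""Haplotype-based selection scans.

Extended haplotype homozygosity (EHH) from a focal site, its integral
(iHH, trapezoid rule truncated where EHH decays below a cutoff), the
within-population iHS with derived-allele-frequency-bin standardization,
the cross-population XP-EHH with genome-wide standardization, multiple-
testing correction, and merging of significant sites into sweep regions
with gene assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .haplotypes import HaplotypeMatrix
from .io import GeneModel


# ---------------------------------------------------------------------------
# EHH and iHH
# ---------------------------------------------------------------------------

def _ehh_values(block: np.ndarray) -> np.ndarray:
    """EHH at each extension step for one direction.

    ``block`` is (carriers x steps) alleles ordered outward from (and
    excluding) the focal site.  Returns EHH after extending through each
    successive column: sum over distinct extended haplotypes h of
    C(n_h, 2) / C(n_c, 2).
    """
    n_c, steps = block.shape
    pairs_total = n_c * (n_c - 1) / 2
    out = np.empty(steps)
    labels = np.zeros(n_c, dtype=np.int64)
    for s in range(steps):
        key = labels * 2 + block[:, s]
        _, labels = np.unique(key, return_inverse=True)
        counts = np.bincount(labels)
        out[s] = np.sum(counts * (counts - 1) / 2) / pairs_total
    return out


def ehh(
    hap: HaplotypeMatrix,
    focal: int,
    allele: int | str = 1,
    carriers: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full EHH curve from a focal site over its chromosome.

    ``allele`` selects the carrier class: 1/"D" derived, 0/"A" ancestral,
    or "all" for the site-EHH over every haplotype (the XP-EHH flavour).
    Returns a frame of (pos, ehh) sorted by position; EHH at the focal
    site is 1 by definition and the curve is monotone non-increasing
    moving away from it.
    """
    sub = hap.subset_chromosome(str(hap.chrom[focal]))
    local = int(np.flatnonzero(sub.positions == hap.positions[focal])[0])
    if carriers is None:
        if allele == "all":
            carriers = np.ones(sub.n_haplotypes, dtype=bool)
        else:
            a = {"A": 0, "D": 1}.get(allele, allele)
            carriers = sub.alleles[:, local] == a
    if carriers.sum() < 2:
        raise ValueError("EHH undefined with fewer than 2 carrier haplotypes")
    block = sub.alleles[carriers]

    left_idx = np.arange(local - 1, -1, -1)
    right_idx = np.arange(local + 1, sub.n_sites)
    left = _ehh_values(block[:, left_idx]) if left_idx.size else np.empty(0)
    right = _ehh_values(block[:, right_idx]) if right_idx.size else np.empty(0)
    pos = np.concatenate([
        sub.positions[left_idx][::-1], [sub.positions[local]], sub.positions[right_idx],
    ])
    val = np.concatenate([left[::-1], [1.0], right])
    return pd.DataFrame({"pos": pos, "ehh": val})


def ihh(curve: pd.DataFrame, focal_pos: int, cutoff: float = 0.05) -> float:
    """Integrated EHH: trapezoid area in bp x homozygosity units.

    Each side is integrated outward from the focal site and truncated at
    the first site whose EHH falls below ``cutoff`` (that final trapezoid
    is included, then integration stops).
    """
    pos = curve["pos"].to_numpy()
    val = curve["ehh"].to_numpy()
    fi = int(np.flatnonzero(pos == focal_pos)[0])
    total = 0.0
    for idx in (range(fi, -1, -1), range(fi, len(pos))):
        idx = list(idx)
        for a, b in zip(idx, idx[1:]):
            width = abs(int(pos[b]) - int(pos[a]))
            total += 0.5 * (val[a] + val[b]) * width
            if val[b] < cutoff:
                break
    return total


def _ihh_one_side(block: np.ndarray, positions: np.ndarray, focal_local: int,
                  direction: int, cutoff: float) -> float:
    """Early-terminating one-sided iHH used by the genome scans."""
    n_c = block.shape[0]
    pairs_total = n_c * (n_c - 1) / 2
    labels = np.zeros(n_c, dtype=np.int64)
    prev_ehh = 1.0
    prev_pos = positions[focal_local]
    area = 0.0
    rng = (range(focal_local - 1, -1, -1) if direction < 0
           else range(focal_local + 1, len(positions)))
    for j in rng:
        key = labels * 2 + block[:, j]
        _, labels = np.unique(key, return_inverse=True)
        counts = np.bincount(labels)
        e = np.sum(counts * (counts - 1) / 2) / pairs_total
        area += 0.5 * (prev_ehh + e) * abs(int(positions[j]) - int(prev_pos))
        prev_ehh, prev_pos = e, positions[j]
        if e < cutoff:
            break
    return area


def _site_ihh(alleles: np.ndarray, positions: np.ndarray, local: int,
              carriers: np.ndarray, cutoff: float) -> float:
    block = alleles[carriers]
    return (_ihh_one_side(block, positions, local, -1, cutoff)
            + _ihh_one_side(block, positions, local, +1, cutoff))


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

def _merge_bins(bin_ids: np.ndarray, n_bins: int, min_sites: int) -> np.ndarray:
    """Merge adjacent frequency bins until each group holds >= min_sites."""
    counts = np.bincount(bin_ids, minlength=n_bins)
    group_of = np.empty(n_bins, dtype=int)
    groups: list[list[int]] = []
    current: list[int] = []
    total = 0
    for b in range(n_bins):
        current.append(b)
        total += counts[b]
        if total >= min_sites:
            groups.append(current)
            current, total = [], 0
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    for gi, members in enumerate(groups):
        for b in members:
            group_of[b] = gi
    return group_of[bin_ids]


def ihs(
    hap: HaplotypeMatrix,
    min_maf: float = 0.05,
    cutoff: float = 0.05,
    n_bins: int = 50,
    min_bin_sites: int = 10,
) -> pd.DataFrame:
    """Per-site iHS: ln(iHH_A / iHH_D), standardized within DAF bins.

    Allele 1 is taken as derived (the simulator provides true polarity;
    VCF input polarized as REF = ancestral should be treated as a stated
    assumption).  Sites below ``min_maf``, with < 2 carriers of either
    allele, or with a zero one-class iHH are excluded.  z-scores are
    standardized within ``n_bins`` equal-width derived-allele-frequency
    bins, merging bins with fewer than ``min_bin_sites``; p = 2 Phi(-|z|).
    """
    records = []
    for chrom in hap.chromosomes():
        sub = hap.subset_chromosome(chrom)
        freq = sub.derived_freq()
        for local in range(sub.n_sites):
            f = freq[local]
            if min(f, 1 - f) < min_maf:
                continue
            derived = sub.alleles[:, local] == 1
            if derived.sum() < 2 or (~derived).sum() < 2:
                continue
            ihh_d = _site_ihh(sub.alleles, sub.positions, local, derived, cutoff)
            ihh_a = _site_ihh(sub.alleles, sub.positions, local, ~derived, cutoff)
            if ihh_d <= 0 or ihh_a <= 0:
                continue
            records.append({
                "chrom": chrom, "pos": int(sub.positions[local]), "daf": float(f),
                "ihh_a": ihh_a, "ihh_d": ihh_d,
                "raw": float(np.log(ihh_a / ihh_d)),
            })
    df = pd.DataFrame(records)
    if df.empty:
        return df
    bin_ids = np.minimum((df["daf"].to_numpy() * n_bins).astype(int), n_bins - 1)
    df["bin"] = _merge_bins(bin_ids, n_bins, min_bin_sites)
    z = np.full(len(df), np.nan)
    for _, idx in df.groupby("bin").groups.items():
        vals = df.loc[idx, "raw"]
        sd = vals.std(ddof=0)
        if sd > 0:
            z[df.index.get_indexer(idx)] = (vals - vals.mean()) / sd
    df["z"] = z
    df = df[np.isfinite(df["z"])].reset_index(drop=True)
    df["p_value"] = 2 * norm.sf(np.abs(df["z"]))
    return df


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

def xpehh(
    hap_pop1: HaplotypeMatrix,
    hap_pop2: HaplotypeMatrix,
    min_maf: float = 0.05,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Cross-population XP-EHH: ln(iHH_pop1 / iHH_pop2), genome-wide z.

    Site EHH uses every haplotype of each population (no allele split).
    Positive standardized scores indicate longer haplotypes — a sweep —
    in population 1; swapping the populations negates the scores exactly.
    The focal-site MAF gate is evaluated on the pooled sample.
    """
    if (hap_pop1.n_sites != hap_pop2.n_sites
            or np.any(hap_pop1.positions != hap_pop2.positions)):
        raise ValueError("both populations must be typed at the same sites")
    records = []
    pooled = np.vstack([hap_pop1.alleles, hap_pop2.alleles])
    for chrom in dict.fromkeys(hap_pop1.chrom.tolist()):
        mask = hap_pop1.chrom == chrom
        idx = np.flatnonzero(mask)
        a1 = hap_pop1.alleles[:, mask]
        a2 = hap_pop2.alleles[:, mask]
        pos = hap_pop1.positions[mask]
        freq = pooled[:, mask].mean(axis=0)
        all1 = np.ones(a1.shape[0], dtype=bool)
        all2 = np.ones(a2.shape[0], dtype=bool)
        for local in range(len(idx)):
            if min(freq[local], 1 - freq[local]) < min_maf:
                continue
            i1 = _site_ihh(a1, pos, local, all1, cutoff)
            i2 = _site_ihh(a2, pos, local, all2, cutoff)
            if i1 <= 0 or i2 <= 0:
                continue
            records.append({
                "chrom": chrom, "pos": int(pos[local]),
                "ihh_pop1": i1, "ihh_pop2": i2,
                "raw": float(np.log(i1 / i2)),
            })
    df = pd.DataFrame(records)
    if df.empty:
        return df
    sd = df["raw"].std(ddof=0)
    df["z"] = (df["raw"] - df["raw"].mean()) / sd if sd > 0 else np.nan
    df = df[np.isfinite(df["z"])].reset_index(drop=True)
    df["p_value"] = 2 * norm.sf(np.abs(df["z"]))
    return df


# ---------------------------------------------------------------------------
# Significance and sweep regions
# ---------------------------------------------------------------------------

def significance(
    p_values: np.ndarray, method: str = "bh", alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """q-values and significance flags under BH step-up or Bonferroni.

    The source workflow's "Bonferroni FDR" wording is ambiguous, so both
    procedures are available; BH is the default.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    method_map = {"bh": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in method_map:
        raise ValueError(f"method must be one of {sorted(method_map)}")
    reject, q, _, _ = multipletests(p, alpha=alpha, method=method_map[method])
    return q, reject


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    method: str
    population: str
    n_significant: int
    peak_score: float
    genes_within: list[str]
    genes_near: list[str]


def sweep_regions(
    scores: pd.DataFrame,
    merge_gap: int = 10_000,
    genes: list[GeneModel] | None = None,
    near: int = 5_000,
    method: str = "iHS",
    population: str = "",
) -> list[SweepRegion]:
    """Merge significant sites into regions and assign genes.

    ``scores`` needs chrom/pos/z plus a boolean ``significant`` column.
    Sites on one chromosome closer than ``merge_gap`` join one region
    (half-open span covering the outermost sites).  Genes overlapping the
    region are ``genes_within``; genes whose interval lies within ``near``
    bp of the region boundary (but does not overlap) are ``genes_near``.
    """
    sig = scores[scores["significant"]].sort_values(["chrom", "pos"])
    regions: list[SweepRegion] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        z = grp["z"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            start, end = int(pos[s]), int(pos[e]) + 1
            within, nearby = [], []
            for g in genes or []:
                if g.chrom != chrom:
                    continue
                if g.start < end and start < g.end:
                    within.append(g.gene_id)
                else:
                    gap = g.start - end if g.start >= end else start - g.end
                    if gap <= near:
                        nearby.append(g.gene_id)
            regions.append(SweepRegion(
                chrom=str(chrom), start=start, end=end, method=method,
                population=population, n_significant=int(e - s + 1),
                peak_score=float(np.max(np.abs(z[s : e + 1]))),
                genes_within=within, genes_near=nearby,
            ))
    return regions


def regions_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end, "method": r.method,
        "population": r.population, "n_significant": r.n_significant,
        "peak_score": r.peak_score,
        "genes_within": ",".join(r.genes_within),
        "genes_near": ",".join(r.genes_near),
    } for r in regions])
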