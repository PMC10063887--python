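"""VCF filtering and descriptive variant statistics.

Implements the pipeline's site filters (MAF >= 0.01, mean depth >= 2,
QUAL >= 20, vcftools ">=" boundary semantics), transition/transversion
bookkeeping, the folded allele-frequency spectrum, race-private SNP
detection with support tiers, and a minimal codon-level effect annotator
(synonymous / non-synonymous / start-stop changes with SnpEff-style
impact classes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as rio

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _site_maf(var) -> float | None:
    """Minor-allele frequency over non-missing alleles; None if no calls."""
    alleles = np.array([g[:2] for g in var.genotypes]).reshape(-1)
    called = alleles[alleles >= 0]
    if called.size == 0:
        return None
    f = called.mean()
    return float(min(f, 1 - f))


def _site_mean_depth(var) -> float | None:
    dp = var.format("DP")
    if dp is None:
        return None
    gts = np.array([g[:2] for g in var.genotypes])
    ok = (gts >= 0).all(axis=1)
    vals = dp.reshape(-1)[ok]
    vals = vals[vals >= 0]
    return float(vals.mean()) if vals.size else None


def filter_sites(
    vcf_path: str,
    out_path: str | None = None,
    maf: float = 0.01,
    min_mean_dp: float = 2.0,
    min_q: float = 20.0,
) -> tuple[int, pd.DataFrame]:
    """Keep sites with MAF >= maf, mean DP >= min_mean_dp, QUAL >= min_q.

    All thresholds are inclusive (vcftools semantics).  The drop log
    records the first failing criterion per dropped site, in filter-flag
    order (maf, then mean depth, then QUAL).  Filtering is idempotent.
    """
    from cyvcf2 import VCF, Writer

    vcf = VCF(vcf_path)
    writer = Writer(out_path, vcf) if out_path else None
    kept = 0
    dropped = []
    malformed = 0
    for var in vcf:
        try:
            site_maf = _site_maf(var)
            mean_dp = _site_mean_depth(var)
            qual = var.QUAL
        except Exception:
            malformed += 1
            continue
        reason = None
        if site_maf is None or site_maf < maf:
            reason = "maf"
        elif mean_dp is None or mean_dp < min_mean_dp:
            reason = "mean_depth"
        elif qual is None or qual < min_q:
            reason = "qual"
        if reason is None:
            kept += 1
            if writer:
                writer.write_record(var)
        else:
            dropped.append({"chrom": var.CHROM, "pos": var.POS, "reason": reason})
    if writer:
        writer.close()
    if malformed:
        warnings.warn(f"skipped {malformed} malformed records", stacklevel=2)
    return kept, pd.DataFrame(dropped, columns=["chrom", "pos", "reason"])


def tstv(vcf_path: str) -> tuple[int, int, float]:
    """Transition and transversion counts and their ratio over biallelic SNPs.

    A<->G and C<->T are transitions; the ratio is ``inf`` when no
    transversion is observed.
    """
    from cyvcf2 import VCF

    ts = tv = 0
    for var in VCF(vcf_path):
        if not var.is_snp or len(var.ALT) != 1:
            continue
        if frozenset((var.REF, var.ALT[0])) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    ratio = ts / tv if tv else float("inf")
    return ts, tv, ratio


MAF_BINS = [(0.0, 0.1), (0.1, 0.2), (0.2, 0.5)]


def maf_spectrum(vcf_path: str, samples: list[str] | None = None) -> dict[str, int]:
    """Folded site-frequency spectrum in the bins (0,0.1], (0.1,0.2], (0.2,0.5].

    MAF is computed over non-missing alleles of the selected samples;
    monomorphic sites are excluded.  Counts sum to the polymorphic sites.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    if samples is not None:
        vcf.set_samples(samples)
    counts = {f"({lo},{hi}]": 0 for lo, hi in MAF_BINS}
    for var in vcf:
        m = _site_maf(var)
        if m is None or m == 0:
            continue
        for lo, hi in MAF_BINS:
            if lo < m <= hi:
                counts[f"({lo},{hi}]"] += 1
                break
    return counts


def race_specific_snps(vcf_path: str, groups: dict[str, str]) -> pd.DataFrame:
    """Sites whose minor allele is carried only by samples of one group.

    Confidence tiers follow the support rule: > 10 carrier accessions is
    "high", < 5 is "low", in between "mid".
    """
    from cyvcf2 import VCF

    if len(set(groups.values())) < 2:
        raise ValueError("need at least two groups")
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    rows = []
    for var in vcf:
        gts = np.array([g[:2] for g in var.genotypes])
        called = gts[gts >= 0]
        if called.size == 0:
            continue
        f_alt = called.mean()
        if f_alt in (0.0, 1.0):
            continue
        minor = 1 if f_alt <= 0.5 else 0
        carrier_idx = np.flatnonzero(((gts == minor) & (gts >= 0)).any(axis=1))
        carrier_groups = {groups[samples[i]] for i in carrier_idx}
        if len(carrier_groups) != 1:
            continue
        n = carrier_idx.size
        tier = "high" if n > 10 else ("low" if n < 5 else "mid")
        rows.append({
            "chrom": var.CHROM, "pos": var.POS, "group": carrier_groups.pop(),
            "minor_allele": var.ALT[0] if minor == 1 else var.REF,
            "n_carriers": n, "tier": tier,
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "group", "minor_allele",
                                       "n_carriers", "tier"])


# ---------------------------------------------------------------------------
# Codon-level effect annotation
# ---------------------------------------------------------------------------

IMPACT_OF_EFFECT = {
    "synonymous": "low",
    "non_synonymous": "moderate",
    "start_lost": "high",
    "stop_gained": "high",
    "stop_lost": "high",
    "intronic": "modifier",
    "intergenic": "modifier",
}


@dataclass
class EffectCall:
    chrom: str
    pos: int          # 1-based, as printed in the VCF
    ref: str
    alt: str
    gene: str
    effect: str
    impact: str


def _cds_layout(gene: rio.GeneModel, reference: dict[str, str]) -> tuple[str, dict[int, int]]:
    """Coding sequence (translation orientation) and genome->CDS index map."""
    segs = sorted(gene.cds, key=lambda t: t[0])
    cds_seq = "".join(reference[gene.chrom][s:e] for s, e, _ in segs)
    genome_positions: list[int] = []
    for s, e, _ in segs:
        genome_positions.extend(range(s, e))
    if gene.strand == "-":
        cds_seq = rio.revcomp(cds_seq)
        genome_positions = genome_positions[::-1]
    phase = segs[0][2] if gene.strand == "+" else segs[-1][2]
    if phase:
        cds_seq = cds_seq[phase:]
        genome_positions = genome_positions[phase:]
    return cds_seq, {gpos: i for i, gpos in enumerate(genome_positions)}


def annotate_effects(
    vcf_path: str,
    reference: dict[str, str] | str,
    genes: list[rio.GeneModel] | str,
) -> tuple[pd.DataFrame, dict]:
    """Classify SNP effects by rewriting the affected codon.

    Returns the per-SNP effect table and a summary with impact tallies and
    the non-synonymous/synonymous count ratio (the ka/ks proxy).  Variants
    in genes without CDS overlap are "intronic"; reference CDSs containing
    an internal stop are flagged and their variants skipped.
    """
    from cyvcf2 import VCF
    from Bio.Seq import Seq

    if isinstance(reference, str):
        reference = rio.read_fasta(reference)
    if isinstance(genes, str):
        genes = rio.read_genes(genes)

    layouts = {}
    flagged_genes = set()
    for g in genes:
        if not g.cds:
            continue
        cds_seq, mapping = _cds_layout(g, reference)
        aa = str(Seq(cds_seq[: len(cds_seq) // 3 * 3]).translate())
        if "*" in aa[:-1]:
            flagged_genes.add(g.gene_id)
            continue
        layouts[g.gene_id] = (cds_seq, mapping)

    calls: list[EffectCall] = []
    for var in VCF(vcf_path):
        if not var.is_snp or len(var.ALT) != 1:
            continue
        pos0 = var.POS - 1  # VCF 1-based -> internal
        hits = [g for g in genes if g.chrom == var.CHROM and g.start <= pos0 < g.end]
        if not hits:
            calls.append(EffectCall(var.CHROM, var.POS, var.REF, var.ALT[0],
                                    "", "intergenic", "modifier"))
            continue
        for g in hits:
            if g.gene_id in flagged_genes:
                continue
            layout = layouts.get(g.gene_id)
            if layout is None or pos0 not in layout[1]:
                calls.append(EffectCall(var.CHROM, var.POS, var.REF, var.ALT[0],
                                        g.gene_id, "intronic", "modifier"))
                continue
            cds_seq, mapping = layout
            ci = mapping[pos0]
            alt = var.ALT[0] if g.strand == "+" else rio.revcomp(var.ALT[0])
            codon_i = ci // 3
            ref_codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
            if len(ref_codon) < 3:
                continue
            alt_codon = (ref_codon[: ci % 3] + alt + ref_codon[ci % 3 + 1 :])
            ref_aa = str(Seq(ref_codon).translate())
            alt_aa = str(Seq(alt_codon).translate())
            if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
                effect = "start_lost"
            elif ref_aa == "*" and alt_aa != "*":
                effect = "stop_lost"
            elif alt_aa == "*" and ref_aa != "*":
                effect = "stop_gained"
            elif ref_aa == alt_aa:
                effect = "synonymous"
            else:
                effect = "non_synonymous"
            calls.append(EffectCall(var.CHROM, var.POS, var.REF, var.ALT[0],
                                    g.gene_id, effect, IMPACT_OF_EFFECT[effect]))

    df = pd.DataFrame([c.__dict__ for c in calls],
                      columns=["chrom", "pos", "ref", "alt", "gene", "effect", "impact"])
    impact_tallies = df["impact"].value_counts().to_dict() if not df.empty else {}
    n_syn = int((df["effect"] == "synonymous").sum()) if not df.empty else 0
    n_non = int((df["effect"] == "non_synonymous").sum()) if not df.empty else 0
    summary = {
        "impact_tallies": impact_tallies,
        "n_synonymous": n_syn,
        "n_non_synonymous": n_non,
        "ka_ks_count_ratio": n_non / n_syn if n_syn else float("nan"),
        "flagged_genes": sorted(flagged_genes),
    }
    return df, summary
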