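"""Phased haplotype container shared by the diversity and scan modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HaplotypeMatrix:
    """Phased biallelic haplotypes: rows are haplotypes, columns sites.

    Alleles are 0 = ancestral, 1 = derived.  Haplotypes ``2*i`` and
    ``2*i + 1`` belong to diploid sample ``sample_ids[i]``.  Positions are
    0-based internally and strictly increasing within each chromosome.
    """

    chrom: np.ndarray          # (n_sites,) chromosome name per site
    positions: np.ndarray      # (n_sites,) 0-based bp
    alleles: np.ndarray        # (n_haplotypes, n_sites) int8 in {0, 1}
    sample_ids: list[str]
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("expected 2 haplotypes per diploid sample")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("positions/alleles site mismatch")
        for c in np.unique(self.chrom):
            pos = self.positions[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic shape -------------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def hap_populations(self) -> np.ndarray:
        """Population label per haplotype row."""
        per_sample = [self.populations.get(s, "pop") for s in self.sample_ids]
        return np.repeat(per_sample, 2)

    # -- views -------------------------------------------------------------
    def subset_population(self, pop: str) -> "HaplotypeMatrix":
        keep = [i for i, s in enumerate(self.sample_ids) if self.populations.get(s) == pop]
        if not keep:
            raise ValueError(f"no samples in population {pop!r}")
        rows = np.repeat(np.array(keep) * 2, 2) + np.tile([0, 1], len(keep))
        return HaplotypeMatrix(
            chrom=self.chrom, positions=self.positions,
            alleles=self.alleles[rows], sample_ids=[self.sample_ids[i] for i in keep],
            populations=self.populations,
        )

    def subset_chromosome(self, chrom: str) -> "HaplotypeMatrix":
        mask = self.chrom == chrom
        return HaplotypeMatrix(
            chrom=self.chrom[mask], positions=self.positions[mask],
            alleles=self.alleles[:, mask], sample_ids=self.sample_ids,
            populations=self.populations,
        )

    def subset_sites(self, mask: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            chrom=self.chrom[mask], positions=self.positions[mask],
            alleles=self.alleles[:, mask], sample_ids=self.sample_ids,
            populations=self.populations,
        )

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chrom.tolist()))

    # -- genotype dosages --------------------------------------------------
    def dosages(self) -> np.ndarray:
        """(n_samples, n_sites) derived-allele dosage matrix (0/1/2)."""
        a = self.alleles.astype(np.int16)
        return a[0::2] + a[1::2]

    def derived_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    # -- VCF ---------------------------------------------------------------
    @classmethod
    def from_vcf(
        cls,
        path: str,
        populations: dict[str, str] | None = None,
        ancestral_is_ref: bool = True,
    ) -> "HaplotypeMatrix":
        """Load phased biallelic SNPs from a VCF.

        With ``ancestral_is_ref`` the REF allele is taken as ancestral
        (the usual fallback when no explicit polarization is available).
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        chroms, positions, rows = [], [], []
        for var in vcf:
            if not var.is_snp or len(var.ALT) != 1:
                continue
            gts = np.array([g[:2] for g in var.genotypes], dtype=np.int8)
            if np.any(gts < 0):
                continue  # scans require complete phased data
            chroms.append(var.CHROM)
            positions.append(var.POS - 1)  # VCF 1-based -> internal 0-based
            rows.append(gts.reshape(-1))
        alleles = (
            np.array(rows, dtype=np.int8).T
            if rows else np.zeros((2 * len(samples), 0), dtype=np.int8)
        )
        return cls(
            chrom=np.array(chroms), positions=np.array(positions, dtype=np.int64),
            alleles=alleles, sample_ids=samples, populations=populations or {},
        )
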