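"""Synthetic structured populations with sweeps, PAVs and sequencing reads.

The generator emulates a panel of crop accessions drawn from a handful of
morphological races: allele frequencies diverge between populations under
the Balding–Nichols model (one divergence parameter per population, which
maps directly onto pairwise Fst), hard selective sweeps are imposed by
forcing a shared core haplotype around a focal site, and gene
presence–absence variation is created by deleting annotated genes from the
genomes of chosen populations.  Every product (frequencies, haplotypes,
VCF, genomes, annotation, reads) flows from one master seed through a
labelled stream-splitting scheme, so identical configurations are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import rng_for
from .haplotypes import HaplotypeMatrix
from . import io as rio

RACE_NAMES = ["bicolor", "caudatum", "durra", "guinea", "kafir"]

_BASES = np.array(list("ACGT"))


@dataclass
class SweepSpec:
    """A hard sweep: force a core haplotype around ``position`` in ``population``.

    ``strength`` in [0, 1] is the fraction of that population's haplotypes
    carrying the core haplotype (1.0 = fixed sweep).
    """

    population: str
    chrom: str
    position: int
    strength: float
    window_bp: int = 100_000


@dataclass
class PavSpec:
    """Delete ``gene_id`` from every accession of the listed populations."""

    gene_id: str
    absent_in: list[str]


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 200_000
    n_populations: int = 2
    pop_sizes: list[int] = field(default_factory=lambda: [20, 20])
    pop_names: list[str] | None = None
    fst_targets: np.ndarray | float | None = 0.1
    theta: float = 1e-3
    freq_model: str = "uniform"        # "uniform" (Balding–Nichols panel) | "neutral"
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    pav_specs: list[PavSpec] = field(default_factory=list)
    n_genes: int = 20
    gene_length: tuple[int, int] = (300, 900)
    pav_flank_bp: int = 60   # deletion breakpoints fall this far into the flanks
    read_length: int = 100
    coverage: float = 10.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.pop_names is None:
            if self.n_populations == 5:
                self.pop_names = list(RACE_NAMES)
            else:
                self.pop_names = [f"pop{i + 1}" for i in range(self.n_populations)]
        if len(self.pop_names) != self.n_populations:
            raise ValueError("pop_names length must equal n_populations")
        if len(self.pop_sizes) != self.n_populations:
            raise ValueError("pop_sizes length must equal n_populations")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.freq_model not in ("uniform", "neutral"):
            raise ValueError("freq_model must be 'uniform' or 'neutral'")
        F = self._fst_matrix()
        if not np.allclose(F, F.T) or np.any(np.diag(F) != 0):
            raise ValueError("fst_targets must be symmetric with zero diagonal")
        if np.any(F < 0) or np.any(F >= 1):
            raise ValueError("fst_targets must lie in [0, 1)")
        for sw in self.sweep_specs:
            if sw.chrom not in self.chrom_names():
                raise ValueError(f"sweep chromosome {sw.chrom!r} not simulated")
            if not (0 <= sw.position < self.chrom_length):
                raise ValueError("sweep position outside chromosome bounds")
            if not (0.0 <= sw.strength <= 1.0):
                raise ValueError("sweep strength must be in [0, 1]")
            if sw.population not in self.pop_names:
                raise ValueError(f"sweep population {sw.population!r} unknown")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def _fst_matrix(self) -> np.ndarray:
        r = self.n_populations
        if self.fst_targets is None:
            return np.zeros((r, r))
        if np.isscalar(self.fst_targets):
            F = np.full((r, r), float(self.fst_targets))
            np.fill_diagonal(F, 0.0)
            return F
        return np.asarray(self.fst_targets, dtype=float)

    def population_divergence(self) -> np.ndarray:
        """Per-population Balding–Nichols F solved from the pairwise targets.

        Under the model the expected pairwise Fst between populations i and
        j is approximately (F_i + F_j) / 2, so the per-population values are
        the least-squares solution of that linear system.
        """
        r = self.n_populations
        T = self._fst_matrix()
        if r == 1:
            return np.zeros(1)
        pairs = [(i, j) for i in range(r) for j in range(i + 1, r)]
        A = np.zeros((len(pairs), r))
        t = np.zeros(len(pairs))
        for row, (i, j) in enumerate(pairs):
            A[row, i] = A[row, j] = 0.5
            t[row] = T[i, j]
        f, *_ = np.linalg.lstsq(A, t, rcond=None)
        return np.clip(f, 0.0, 0.95)

    def sample_ids(self) -> list[str]:
        out = []
        for pop, n in zip(self.pop_names, self.pop_sizes):
            out.extend(f"{pop}_{i + 1}" for i in range(n))
        return out

    def population_map(self) -> dict[str, str]:
        return {
            s: s.rsplit("_", 1)[0] for s in self.sample_ids()
        }

    def n_sites_per_chrom(self) -> int:
        """Variant-site count matching the requested per-bp diversity.

        The per-candidate-site expected heterozygosity depends on the
        ancestral frequency model; the count is chosen so realized pooled
        pi per bp approximates theta (at F = 0).
        """
        if self.freq_model == "uniform":
            lo, hi = 0.05, 0.95
            e_het = 2 * ((hi + lo) / 2 - (hi**2 + hi * lo + lo**2) / 3)
        else:
            lo, hi = _NEUTRAL_PMIN, _NEUTRAL_PMAX
            log_r = np.log(hi / lo)
            e_het = 2 * ((hi - lo) - (hi**2 - lo**2) / 2) / log_r
        return max(1, int(round(self.theta * self.chrom_length / e_het)))


_NEUTRAL_PMIN = 1e-4
_NEUTRAL_PMAX = 0.9999


@dataclass
class FrequencyTable:
    """Ancestral and per-population derived-allele frequencies per site."""

    chrom: np.ndarray
    positions: np.ndarray
    p_ancestral: np.ndarray
    freqs: np.ndarray          # (n_sites, n_populations)
    pop_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.positions,
                           "p_ancestral": self.p_ancestral})
        for j, name in enumerate(self.pop_names):
            df[name] = self.freqs[:, j]
        return df


def _draw_ancestral(rng: np.random.Generator, n: int, model: str) -> np.ndarray:
    if model == "uniform":
        return rng.uniform(0.05, 0.95, size=n)
    # standing neutral spectrum: density proportional to 1/p (log-uniform draw)
    u = rng.uniform(size=n)
    return _NEUTRAL_PMIN * (_NEUTRAL_PMAX / _NEUTRAL_PMIN) ** u


def simulate_frequencies(config: SimConfig) -> FrequencyTable:
    """Draw per-population allele frequencies under Balding–Nichols drift.

    Each population's frequency at a site is Beta(p(1-F)/F, (1-p)(1-F)/F)
    around the ancestral frequency p; F = 0 copies p exactly (no drift).
    """
    F = config.population_divergence()
    if np.any(F >= 1):
        raise ValueError("population divergence F must be < 1")
    n_sites = config.n_sites_per_chrom()
    chroms, positions, p_all = [], [], []
    for ci, chrom in enumerate(config.chrom_names()):
        rng = rng_for(config.seed, "frequencies", ci)
        pos = np.sort(rng.choice(config.chrom_length, size=min(n_sites, config.chrom_length),
                                 replace=False))
        p = _draw_ancestral(rng, pos.size, config.freq_model)
        chroms.append(np.full(pos.size, chrom, dtype=object))
        positions.append(pos)
        p_all.append(p)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions).astype(np.int64)
    p = np.concatenate(p_all)
    freqs = np.empty((p.size, config.n_populations))
    for j in range(config.n_populations):
        rng = rng_for(config.seed, "drift", j)
        if F[j] == 0:
            freqs[:, j] = p
        else:
            a = p * (1 - F[j]) / F[j]
            b = (1 - p) * (1 - F[j]) / F[j]
            freqs[:, j] = rng.beta(a, b)
    return FrequencyTable(chrom=chrom_arr, positions=pos_arr, p_ancestral=p,
                          freqs=freqs, pop_names=list(config.pop_names))


@dataclass
class SweepTruth:
    population: str
    chrom: str
    start: int
    end: int
    focal_position: int


_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOP_CODONS = ["TAA", "TAG", "TGA"]


def ancestral_sequence(config: SimConfig, chrom_index: int) -> str:
    """Ancestral chromosome: random background with ORF-structured genes.

    Gene intervals carry a translatable reading frame (ATG, non-stop
    internal codons, terminal stop), reverse-complemented on minus-strand
    genes, so codon-level effect annotation behaves as on real genes.
    """
    rng = rng_for(config.seed, "ancestral", chrom_index)
    seq = list("".join(_BASES[rng.integers(0, 4, size=config.chrom_length)]))
    chrom = config.chrom_names()[chrom_index]
    for g in _place_genes(config):
        if g.chrom != chrom:
            continue
        orf_rng = rng_for(config.seed, "orf", g.gene_id)
        n_codons = g.length // 3
        body = [_NON_STOP_CODONS[i]
                for i in orf_rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 2)]
        orf = "ATG" + "".join(body) + _STOP_CODONS[orf_rng.integers(0, 3)]
        if g.strand == "-":
            orf = rio.revcomp(orf)
        seq[g.start : g.end] = orf
    return "".join(seq)


def _ref_alt_alleles(config: SimConfig, freqs: FrequencyTable) -> tuple[np.ndarray, np.ndarray]:
    """REF = ancestral base from the chromosome sequence, ALT a different base."""
    ref = np.empty(freqs.positions.size, dtype=object)
    alt = np.empty(freqs.positions.size, dtype=object)
    for ci, chrom in enumerate(config.chrom_names()):
        mask = freqs.chrom == chrom
        if not np.any(mask):
            continue
        seq = ancestral_sequence(config, ci)
        # alt codes indexed by position so any site subset gets the same allele
        codes = rng_for(config.seed, "alt", ci).integers(0, 3, size=config.chrom_length)
        for idx in np.flatnonzero(mask):
            pos = freqs.positions[idx]
            r = seq[pos]
            choices = [b for b in "ACGT" if b != r]
            ref[idx] = r
            alt[idx] = choices[codes[pos]]
    return ref, alt


def simulate_haplotypes(
    freqs: FrequencyTable,
    config: SimConfig,
    vcf_path: str | Path | None = None,
) -> tuple[HaplotypeMatrix, list[SweepTruth]]:
    """Sample phased haplotypes and impose configured sweeps.

    Returns the haplotype matrix (monomorphic sites dropped) and the truth
    intervals of every sweep.  Optionally writes a phased VCF v4.2.
    """
    n_sites = freqs.positions.size
    blocks = []
    for j, (pop, n_dip) in enumerate(zip(config.pop_names, config.pop_sizes)):
        rng = rng_for(config.seed, "haplotypes", j)
        blocks.append(
            (rng.uniform(size=(2 * n_dip, n_sites)) < freqs.freqs[:, j]).astype(np.int8)
        )
    alleles = np.vstack(blocks)
    pop_of_hap = np.repeat(config.pop_names, np.array(config.pop_sizes) * 2)

    truths: list[SweepTruth] = []
    for si, sw in enumerate(config.sweep_specs):
        half = sw.window_bp // 2
        start, end = max(0, sw.position - half), min(config.chrom_length, sw.position + half)
        in_window = (freqs.chrom == sw.chrom) & (freqs.positions >= start) & (freqs.positions < end)
        win_idx = np.flatnonzero(in_window)
        rows = np.flatnonzero(pop_of_hap == sw.population)
        n_carriers = int(round(sw.strength * rows.size))
        truths.append(SweepTruth(sw.population, sw.chrom, start, end, sw.position))
        if n_carriers == 0 or win_idx.size == 0:
            continue
        rng = rng_for(config.seed, "sweep", si)
        core = alleles[rows[0], win_idx].copy()
        # the focal site carries the derived (selected) allele on the core
        focal_local = np.argmin(np.abs(freqs.positions[win_idx] - sw.position))
        core[focal_local] = 1
        carriers = rng.choice(rows, size=n_carriers, replace=False)
        alleles[np.ix_(carriers, win_idx)] = core

    poly = (alleles.sum(axis=0) > 0) & (alleles.sum(axis=0) < alleles.shape[0])
    hap = HaplotypeMatrix(
        chrom=freqs.chrom[poly], positions=freqs.positions[poly],
        alleles=alleles[:, poly], sample_ids=config.sample_ids(),
        populations=config.population_map(),
    )
    if vcf_path is not None:
        sub = FrequencyTable(freqs.chrom[poly], freqs.positions[poly],
                             freqs.p_ancestral[poly], freqs.freqs[poly],
                             freqs.pop_names)
        ref, alt = _ref_alt_alleles(config, sub)
        n_samp = len(hap.sample_ids)
        gts = hap.alleles.T.reshape(hap.n_sites, n_samp, 2)
        rng = rng_for(config.seed, "vcfmeta")
        depth = rng.poisson(max(config.coverage, 1.0), size=(hap.n_sites, n_samp)).astype(int)
        qual = np.round(rng.uniform(30, 90, size=hap.n_sites), 1)
        rio.write_vcf(
            vcf_path, hap.chrom, hap.positions, ref, alt, gts, hap.sample_ids,
            qual=qual, depth=depth,
            contig_lengths={c: config.chrom_length for c in config.chrom_names()},
        )
    return hap, truths


# ---------------------------------------------------------------------------
# Genomes, genes and PAVs
# ---------------------------------------------------------------------------

@dataclass
class PrivateSegment:
    gene_id: str
    group: str
    ancestral_seq: str
    realized_seqs: dict[str, str]   # accession -> realized gene sequence


@dataclass
class GenomePanel:
    reference: dict[str, str]                  # ancestral/pan-reference
    genes: list[rio.GeneModel]
    genomes: dict[str, dict[str, str]]         # accession -> chrom -> sequence
    pav_truth: pd.DataFrame                    # genes x accessions, 1 = present
    private_segments: list[PrivateSegment]
    populations: dict[str, str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rio.write_fasta(out / "reference.fa", self.reference)
        rio.write_gff3(out / "genes.gff3", self.genes)
        for acc, chroms in self.genomes.items():
            rio.write_fasta(out / f"{acc}.fa", chroms)
        self.pav_truth.to_csv(out / "pav_truth.tsv", sep="\t")
        rio.write_populations(out / "populations.tsv", self.populations)
        with open(out / "private_segments.tsv", "w") as fh:
            fh.write("gene_id\tgroup\tancestral_seq\n")
            for seg in self.private_segments:
                fh.write(f"{seg.gene_id}\t{seg.group}\t{seg.ancestral_seq}\n")


def _place_genes(config: SimConfig) -> list[rio.GeneModel]:
    rng = rng_for(config.seed, "genes")
    genes: list[rio.GeneModel] = []
    chroms = config.chrom_names()
    per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    gi = 0
    for chrom in chroms:
        if gi >= config.n_genes:
            break
        n_here = min(per_chrom, config.n_genes - gi)
        slot = config.chrom_length // max(n_here, 1)
        margin = config.pav_flank_bp + 1
        for s in range(n_here):
            lo, hi = config.gene_length
            length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3  # CDS length multiple of 3
            max_start = slot - length - margin
            if max_start <= margin:
                raise ValueError("chromosome too short for requested gene count/length")
            start = s * slot + int(rng.integers(margin, max_start))
            strand = "+" if rng.uniform() < 0.5 else "-"
            gid = f"gene{gi + 1:04d}"
            genes.append(rio.GeneModel(gid, chrom, start, start + length, strand,
                                       cds=[(start, start + length, 0)]))
            gi += 1
    return genes


def simulate_genomes(
    config: SimConfig,
    hap: HaplotypeMatrix | None = None,
    out_dir: str | Path | None = None,
) -> GenomePanel:
    """Build per-accession genomes with substitutions and PAV gene deletions.

    Each accession's genome is its first haplotype applied to the ancestral
    sequence; genes named in ``pav_specs`` are deleted from every accession
    of the listed populations.  Truth tables record all PAVs and, for genes
    retained by exactly one population, the group-private segments.
    """
    if hap is None:
        hap, _ = simulate_haplotypes(simulate_frequencies(config), config)
    genes = _place_genes(config)
    by_id = {g.gene_id: g for g in genes}
    for spec in config.pav_specs:
        if spec.gene_id not in by_id:
            raise ValueError(f"pav gene {spec.gene_id!r} not simulated")
        for pop in spec.absent_in:
            if pop not in config.pop_names:
                raise ValueError(f"pav population {pop!r} unknown")
    # overlapping deletions are rejected (gene placement is non-overlapping,
    # but guard against hand-edited configs)
    spans = sorted((by_id[s.gene_id].chrom, by_id[s.gene_id].start, by_id[s.gene_id].end)
                   for s in config.pav_specs)
    for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
        if c1 == c2 and s2 < e1:
            raise ValueError("overlapping gene deletions are not supported")

    reference = {chrom: ancestral_sequence(config, ci)
                 for ci, chrom in enumerate(config.chrom_names())}
    _, alt = _ref_alt_alleles(
        config, FrequencyTable(hap.chrom, hap.positions,
                               np.zeros(hap.n_sites), np.zeros((hap.n_sites, 1)),
                               ["_"]))

    pops = config.population_map()
    absent: dict[str, set[str]] = {s.gene_id: set(s.absent_in) for s in config.pav_specs}
    pav = pd.DataFrame(1, index=[g.gene_id for g in genes],
                       columns=hap.sample_ids, dtype=int)
    realized: dict[str, dict[str, str]] = {s.gene_id: {} for s in config.pav_specs}

    genomes: dict[str, dict[str, str]] = {}
    for si, acc in enumerate(hap.sample_ids):
        hap_row = hap.alleles[2 * si]
        acc_genome: dict[str, str] = {}
        for chrom in config.chrom_names():
            seq = list(reference[chrom])
            mask = (hap.chrom == chrom) & (hap_row == 1)
            for idx in np.flatnonzero(mask):
                seq[hap.positions[idx]] = alt[idx]
            seq = "".join(seq)
            # record realized gene sequences before any deletion shifts coordinates
            for spec in config.pav_specs:
                g = by_id[spec.gene_id]
                if g.chrom == chrom and pops[acc] not in absent[spec.gene_id]:
                    realized[spec.gene_id][acc] = seq[g.start:g.end]
            deletions = sorted(
                (by_id[s.gene_id] for s in config.pav_specs
                 if by_id[s.gene_id].chrom == chrom and pops[acc] in absent[s.gene_id]),
                key=lambda g: -g.start)
            flank = config.pav_flank_bp
            for g in deletions:
                # breakpoints fall in the flanks: the deleted interval is the
                # gene plus a small buffer, so junction-spanning k-mers can
                # never coincide with annotated gene-edge sequence
                lo = max(0, g.start - flank)
                hi = min(len(seq), g.end + flank)
                seq = seq[:lo] + seq[hi:]
                pav.loc[g.gene_id, acc] = 0
            acc_genome[chrom] = seq
        genomes[acc] = acc_genome

    private: list[PrivateSegment] = []
    for spec in config.pav_specs:
        retained = [p for p in config.pop_names if p not in absent[spec.gene_id]]
        if len(retained) == 1:
            g = by_id[spec.gene_id]
            private.append(PrivateSegment(
                gene_id=spec.gene_id, group=retained[0],
                ancestral_seq=reference[g.chrom][g.start:g.end],
                realized_seqs=dict(realized[spec.gene_id]),
            ))

    panel = GenomePanel(reference=reference, genes=genes, genomes=genomes,
                        pav_truth=pav, private_segments=private, populations=pops)
    if out_dir is not None:
        panel.write(out_dir)
    return panel


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: dict[str, str] | str | Path,
    coverage: float,
    read_length: int,
    error_rate: float,
    seed: int,
    out_fastq: str | Path | None = None,
) -> list[tuple[str, str, str]]:
    """Uniform single-end reads with per-base substitution errors.

    Phred+33 qualities are constant and consistent with ``error_rate``
    (Q40 cap for error-free reads).  Reads come off both strands.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if isinstance(genome, (str, Path)):
        genome = rio.read_fasta(genome)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms])
    if read_length > lengths.max():
        raise ValueError("read_length exceeds every chromosome length")
    usable = np.maximum(lengths - read_length + 1, 0)
    total = int(lengths.sum())
    n_reads = int(np.ceil(coverage * total / read_length))
    rng = rng_for(seed, "reads")
    rng_err = rng_for(seed, "reads", "errors")  # placements identical at any error rate
    q = 40 if error_rate <= 0 else int(np.clip(round(-10 * np.log10(error_rate)), 2, 40))
    qual = chr(33 + q) * read_length
    chrom_idx = rng.choice(len(chroms), size=n_reads, p=usable / usable.sum())
    reads: list[tuple[str, str, str]] = []
    for i in range(n_reads):
        c = chroms[chrom_idx[i]]
        start = int(rng.integers(0, usable[chrom_idx[i]]))
        seq = genome[c][start : start + read_length]
        if rng.uniform() < 0.5:
            seq = rio.revcomp(seq)
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            err = np.flatnonzero(rng_err.uniform(size=read_length) < error_rate)
            for pos in err:
                cur = chr(arr[pos])
                alts = [b for b in "ACGT" if b != cur]
                arr[pos] = ord(alts[rng_err.integers(0, 3)])
            seq = arr.tobytes().decode()
        reads.append((f"read{i + 1}", seq, qual))
    if out_fastq is not None:
        rio.write_fastq(out_fastq, reads)
    return reads
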