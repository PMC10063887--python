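"""Shared I/O layer: sequence, variant, annotation and interval formats.

All coordinate conversions live here.  Internally everything is 0-based
half-open; VCF is written/read 1-based, GFF3 1-based inclusive, BED
0-based half-open.  Keeping the conversions in one module means no other
module ever adds or subtracts 1.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    from Bio import SeqIO

    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(path: str | Path, records: dict[str, str], width: int = 80) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in records.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def iter_sequences(source) -> Iterator[str]:
    """Yield raw sequence strings from flexible input.

    Accepts a FASTA/FASTQ path (optionally .gz), an iterable of strings,
    or a single string that is itself a sequence.
    """
    from Bio import SeqIO

    if isinstance(source, (str, Path)):
        if str(source) == "":
            return
        p = Path(source)
        try:
            is_file = p.exists()
        except OSError:  # raw sequence longer than the filename limit
            is_file = False
        if is_file:
            name = p.name[:-3] if p.name.endswith(".gz") else p.name
            fmt = "fastq" if name.endswith((".fq", ".fastq")) else "fasta"
            with _open_text(p) as handle:
                for rec in SeqIO.parse(handle, fmt):
                    yield str(rec.seq).upper()
            return
        yield str(source).upper()
        return
    for seq in source:
        yield str(seq).upper()


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (name, sequence, quality-string) triples as Phred+33 FASTQ."""
    with _open_text(path, "wt") as out:
        for name, seq, qual in reads:
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3 1-based inclusive <-> internal 0-based half-open)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with optional CDS structure, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        for s, e, _ in self.cds:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: CDS outside gene bounds")

    @property
    def length(self) -> int:
        return self.end - self.start

    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)


def write_gff3(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            # internal half-open -> GFF3 1-based inclusive
            out.write(
                f"{g.chrom}\tracesig\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for s, e, phase in g.cds:
                out.write(
                    f"{g.chrom}\tracesig\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID=cds-{g.gene_id};Parent={g.gene_id}\n"
                )


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene + CDS features from GFF3 into GeneModel records."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        cds = []
        for c in db.children(feat, featuretype="CDS", order_by="start"):
            phase = int(c.frame) if c.frame not in (None, ".") else 0
            cds.append((c.start - 1, c.end, phase))  # GFF3 1-based inclusive -> half-open
        genes.append(
            GeneModel(
                gene_id=gid, chrom=feat.seqid, start=feat.start - 1, end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+", cds=cds,
            )
        )
    return genes


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene intervals from GFF3 or BED, by extension."""
    p = Path(path)
    if p.suffix.lower() in (".bed",):
        genes = []
        for chrom, start, end, label in read_bed(p):
            genes.append(GeneModel(gene_id=label, chrom=chrom, start=start, end=end))
        return genes
    return read_genes_gff3(p)


# ---------------------------------------------------------------------------
# BED (0-based half-open, same as internal)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    rows = []
    with _open_text(path) as handle:
        for i, line in enumerate(handle):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            label = parts[3] if len(parts) > 3 else f"region{i}"
            rows.append((parts[0], int(parts[1]), int(parts[2]), label))
    return rows


def write_bed(path: str | Path, rows: Iterable[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as out:
        for chrom, start, end, label in rows:
            out.write(f"{chrom}\t{start}\t{end}\t{label}\n")


# ---------------------------------------------------------------------------
# VCF writing (v4.2, phased GT + DP).  Reading goes through cyvcf2.
# ---------------------------------------------------------------------------

def write_vcf(
    path: str | Path,
    chroms: np.ndarray,
    positions: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    genotypes: np.ndarray,
    sample_ids: list[str],
    qual: np.ndarray | None = None,
    depth: np.ndarray | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write phased biallelic SNPs.

    ``positions`` are internal 0-based and converted to 1-based here.
    ``genotypes`` is (n_sites, n_samples, 2) of 0/1 allele indices
    (-1 for missing).  ``depth`` is (n_sites, n_samples) integer DP.
    """
    n_sites, n_samples, _ = genotypes.shape
    if qual is None:
        qual = np.full(n_sites, 60.0)
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=racesig\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                out.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(np.asarray(chroms).tolist()):
                out.write(f"##contig=<ID={name}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for i in range(n_sites):
            fields = [
                str(chroms[i]), str(int(positions[i]) + 1), ".",
                str(ref[i]), str(alt[i]), f"{float(qual[i]):g}", "PASS", ".", "GT:DP",
            ]
            for s in range(n_samples):
                a, b = genotypes[i, s]
                gt = "./." if a < 0 or b < 0 else f"{a}|{b}"
                dp = int(depth[i, s]) if depth is not None else 20
                fields.append(f"{gt}:{dp}")
            out.write("\t".join(fields) + "\n")


def read_populations(path: str | Path) -> dict[str, str]:
    """Read a two-column sample<TAB>population assignment table."""
    out: dict[str, str] = {}
    with _open_text(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            out[sample] = pop
    return out


def write_populations(path: str | Path, pops: dict[str, str]) -> None:
    with open(path, "w") as out:
        for sample, pop in pops.items():
            out.write(f"{sample}\t{pop}\n")
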