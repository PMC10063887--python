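import numpy as np
import pytest

from racesig.io import GeneModel, revcomp
from racesig.variants import (
    annotate_effects,
    filter_sites,
    maf_spectrum,
    race_specific_snps,
    tstv,
)

HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, rows, samples):
    with open(path, "w") as fh:
        fh.write(HEADER.format(samples="\t".join(samples)))
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return str(path)


def gt(pairs, dp=20):
    return ["%d|%d:%d" % (a, b, dp) for a, b in pairs]


class TestFilterSemantics:
    def _toy(self, tmp_path):
        samples = [f"s{i}" for i in range(10)]
        het = gt([(0, 1)] * 10)                      # maf 0.5
        # one failure per criterion plus one clean site
        rows = [
            ["chr1", 100, ".", "A", "G", 60, "PASS", ".", "GT:DP"] + gt([(0, 0)] * 10),
            ["chr1", 200, ".", "C", "T", 60, "PASS", ".", "GT:DP"] + gt([(0, 1)] * 10, dp=1),
            ["chr1", 300, ".", "G", "A", 19, "PASS", ".", "GT:DP"] + het,
            ["chr1", 400, ".", "T", "C", 60, "PASS", ".", "GT:DP"] + het,
        ]
        return write_vcf(tmp_path / "toy.vcf", rows, samples)

    def test_exactly_the_clean_site_survives(self, tmp_path):
        path = self._toy(tmp_path)
        out = str(tmp_path / "filtered.vcf")
        kept, log = filter_sites(path, out)
        assert kept == 1
        assert list(log["reason"]) == ["maf", "mean_depth", "qual"]
        assert list(log["pos"]) == [100, 200, 300]

    def test_filtering_is_idempotent(self, tmp_path):
        path = self._toy(tmp_path)
        out1 = str(tmp_path / "f1.vcf")
        out2 = str(tmp_path / "f2.vcf")
        kept1, _ = filter_sites(path, out1)
        kept2, log2 = filter_sites(out1, out2)
        assert kept2 == kept1
        assert len(log2) == 0

    def test_inclusive_boundaries(self, tmp_path):
        samples = [f"s{i}" for i in range(100)]
        one_het = gt([(0, 0)] * 100)
        one_het[0] = "0|1:20"                         # maf exactly 0.005
        two_het = gt([(0, 0)] * 100)
        two_het[0] = two_het[1] = "0|1:20"            # maf exactly 0.01
        rows = [
            ["chr1", 100, ".", "A", "G", 20, "PASS", ".", "GT:DP"] + one_het,
            ["chr1", 200, ".", "A", "G", 20, "PASS", ".", "GT:DP"] + two_het,
            ["chr1", 300, ".", "A", "G", 20, "PASS", ".", "GT:DP"]
            + gt([(0, 1)] * 100, dp=2),
        ]
        path = write_vcf(tmp_path / "edges.vcf", rows, samples)
        kept, log = filter_sites(path)
        # maf 0.005 dropped; maf 0.01, QUAL 20 and DP 2 all kept (>= rule)
        assert kept == 2
        assert list(log["pos"]) == [100]


class TestTstv:
    def test_hand_tally(self, tmp_path):
        samples = ["s0"]
        rows = [
            ["chr1", 100, ".", "A", "G", 60, "PASS", ".", "GT:DP", "0|1:20"],
            ["chr1", 200, ".", "C", "T", 60, "PASS", ".", "GT:DP", "0|1:20"],
            ["chr1", 300, ".", "A", "C", 60, "PASS", ".", "GT:DP", "0|1:20"],
        ]
        path = write_vcf(tmp_path / "t.vcf", rows, samples)
        assert tstv(path) == (2, 1, 2.0)

    def test_no_transversions_gives_infinity(self, tmp_path):
        rows = [["chr1", 100, ".", "A", "G", 60, "PASS", ".", "GT:DP", "0|1:20"]]
        path = write_vcf(tmp_path / "t.vcf", rows, ["s0"])
        assert tstv(path)[2] == float("inf")

    def test_matches_bruteforce_on_random_vcf(self, tmp_path):
        rng = np.random.default_rng(50)
        bases = "ACGT"
        rows, expected_ts, expected_tv = [], 0, 0
        for i in range(500):
            ref, alt = rng.choice(list(bases), size=2, replace=False)
            rows.append(["chr1", 100 + i, ".", ref, alt, 60, "PASS", ".",
                         "GT:DP", "0|1:20"])
            if {ref, alt} in ({"A", "G"}, {"C", "T"}):
                expected_ts += 1
            else:
                expected_tv += 1
        path = write_vcf(tmp_path / "r.vcf", rows, ["s0"])
        ts, tv, _ = tstv(path)
        assert (ts, tv) == (expected_ts, expected_tv)


class TestMafSpectrum:
    def test_bin_assignment_and_monomorphic_exclusion(self, tmp_path):
        samples = [f"s{i}" for i in range(10)]
        three_alt = gt([(0, 0)] * 10)
        three_alt[0], three_alt[1] = "0|1:20", "1|1:20"  # 3 of 20 alleles: 0.15
        rows = [
            ["chr1", 100, ".", "A", "G", 60, "PASS", ".", "GT:DP"] + three_alt,
            ["chr1", 200, ".", "A", "G", 60, "PASS", ".", "GT:DP"] + gt([(0, 0)] * 10),
        ]
        path = write_vcf(tmp_path / "m.vcf", rows, samples)
        spec = maf_spectrum(path)
        assert spec == {"(0.0,0.1]": 0, "(0.1,0.2]": 1, "(0.2,0.5]": 0}

    def test_counts_sum_to_polymorphic_sites(self, two_pop_vcf):
        cfg, hap, path = two_pop_vcf
        spec = maf_spectrum(path)
        assert sum(spec.values()) == hap.n_sites


class TestRaceSpecific:
    def test_tiers_and_exclusions(self, tmp_path):
        samples = [f"a{i}" for i in range(15)] + [f"b{i}" for i in range(15)]
        groups = {s: s[0] for s in samples}
        twelve = gt([(0, 1)] * 12 + [(0, 0)] * 3 + [(0, 0)] * 15)
        two = gt([(0, 1)] * 2 + [(0, 0)] * 13 + [(0, 0)] * 15)
        shared = gt([(0, 1)] * 5 + [(0, 0)] * 10 + [(0, 1)] * 2 + [(0, 0)] * 13)
        rows = [
            ["chr1", 100, ".", "A", "G", 60, "PASS", ".", "GT:DP"] + twelve,
            ["chr1", 200, ".", "A", "G", 60, "PASS", ".", "GT:DP"] + two,
            ["chr1", 300, ".", "A", "G", 60, "PASS", ".", "GT:DP"] + shared,
        ]
        path = write_vcf(tmp_path / "rs.vcf", rows, samples)
        df = race_specific_snps(path, groups)
        assert len(df) == 2
        assert df.set_index("pos").loc[100, "tier"] == "high"     # 12 > 10
        assert df.set_index("pos").loc[200, "tier"] == "low"      # 2 < 5
        assert 300 not in set(df["pos"])                          # two groups

    def test_single_group_rejected(self, tmp_path):
        rows = [["chr1", 100, ".", "A", "G", 60, "PASS", ".", "GT:DP", "0|1:20"]]
        path = write_vcf(tmp_path / "x.vcf", rows, ["s0"])
        with pytest.raises(ValueError, match="two groups"):
            race_specific_snps(path, {"s0": "only"})

    def test_simulated_private_alleles_all_recovered(self, two_pop_vcf):
        cfg, hap, path = two_pop_vcf
        df = race_specific_snps(path, cfg.population_map())
        # brute-force recount straight off the haplotype matrix
        labels = hap.hap_populations()
        expected = 0
        for j in range(hap.n_sites):
            col = hap.alleles[:, j]
            minor = 1 if col.mean() <= 0.5 else 0
            carrier_pops = set(labels[col == minor])
            if len(carrier_pops) == 1:
                expected += 1
        assert len(df) == expected


class TestEffects:
    def _setup(self, tmp_path, strand="+"):
        # gene with CDS ATG GGA TAT TAC TGA on the requested strand
        cds = "ATGGGATATTACTGA"
        flank5, flank3 = "GATTACAGAT", "CCGGTTAACC"
        if strand == "+":
            seq = flank5 + cds + flank3
        else:
            seq = flank5 + revcomp(cds) + flank3
        ref = {"chr1": seq}
        gene = GeneModel("g1", "chr1", 10, 25, strand=strand,
                         cds=[(10, 25, 0)])
        return ref, [gene]

    def _annotate(self, tmp_path, ref, genes, pos, ref_b, alt_b):
        rows = [["chr1", pos, ".", ref_b, alt_b, 60, "PASS", ".", "GT:DP",
                 "0|1:20"]]
        path = write_vcf(tmp_path / "e.vcf", rows, ["s0"])
        df, summary = annotate_effects(path, ref, genes)
        return df.iloc[0], summary

    def test_synonymous_low(self, tmp_path):
        ref, genes = self._setup(tmp_path)
        # GGA -> GGG (Gly->Gly): third codon base at 0-based 15 (VCF POS 16)
        call, _ = self._annotate(tmp_path, ref, genes, 16, "A", "G")
        assert (call["effect"], call["impact"]) == ("synonymous", "low")

    def test_stop_gained_high(self, tmp_path):
        ref, genes = self._setup(tmp_path)
        # TAT -> TAA at codon 3: base 0-based 18 (VCF POS 19)
        call, _ = self._annotate(tmp_path, ref, genes, 19, "T", "A")
        assert (call["effect"], call["impact"]) == ("stop_gained", "high")

    def test_start_lost_high(self, tmp_path):
        ref, genes = self._setup(tmp_path)
        # ATG -> ATA: 0-based 12 (VCF POS 13)
        call, _ = self._annotate(tmp_path, ref, genes, 13, "G", "A")
        assert (call["effect"], call["impact"]) == ("start_lost", "high")

    def test_stop_lost_high(self, tmp_path):
        ref, genes = self._setup(tmp_path)
        # TGA -> TGG: 0-based 24 (VCF POS 25)
        call, _ = self._annotate(tmp_path, ref, genes, 25, "A", "G")
        assert (call["effect"], call["impact"]) == ("stop_lost", "high")

    def test_minus_strand_consistency(self, tmp_path):
        ref, genes = self._setup(tmp_path, strand="-")
        # the synonymous GGA->GGG change: CDS base 5 maps to genome
        # position 10 + (15 - 1 - 5) = 19 (VCF POS 20), alt complemented
        call, _ = self._annotate(tmp_path, ref, genes, 20, "T", "C")
        assert (call["effect"], call["impact"]) == ("synonymous", "low")

    def test_intergenic_and_intronic_modifiers(self, tmp_path):
        ref, genes = self._setup(tmp_path)
        call, _ = self._annotate(tmp_path, ref, genes, 2, "A", "C")
        assert (call["effect"], call["impact"]) == ("intergenic", "modifier")

    def test_impact_tallies_partition_calls(self, two_pop_vcf, race_panel):
        cfg, hap, path = two_pop_vcf
        from racesig import simulate as sim

        panel = sim.simulate_genomes(cfg, hap=hap)
        df, summary = annotate_effects(path, panel.reference, panel.genes)
        assert sum(summary["impact_tallies"].values()) == len(df)
        assert summary["n_non_synonymous"] + summary["n_synonymous"] <= len(df)
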