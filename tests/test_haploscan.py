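import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_haplotypes
from racesig import simulate as sim
from racesig.haploscan import (
    ehh,
    ihh,
    ihs,
    significance,
    sweep_regions,
    xpehh,
)
from racesig.haplotypes import HaplotypeMatrix


def _hap(alleles, positions=None, pops=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    n_sites = alleles.shape[1]
    if positions is None:
        positions = np.arange(n_sites) * 1000
    n_samp = alleles.shape[0] // 2
    ids = [f"s{i}" for i in range(n_samp)]
    return HaplotypeMatrix(
        chrom=np.array(["chr1"] * n_sites), positions=np.array(positions),
        alleles=alleles, sample_ids=ids,
        populations=pops or {i: "p" for i in ids})


class TestEhh:
    def test_focal_value_is_one(self):
        rng = np.random.default_rng(30)
        hap = _hap(random_haplotypes(rng, 8, 9))
        focal = 4
        if hap.alleles[:, focal].sum() < 2:
            hap.alleles[:2, focal] = 1
        curve = ehh(hap, focal, allele=1)
        assert curve.loc[curve["pos"] == hap.positions[focal], "ehh"].item() == 1.0

    def test_four_carriers_splitting_two_two(self):
        # carriers split 2+2 at the next site: EHH = (1+1)/C(4,2) = 1/3
        alleles = np.array([
            [1, 0], [1, 0], [1, 1], [1, 1], [0, 0], [0, 1],
        ])
        hap = _hap(alleles)
        curve = ehh(hap, 0, allele=1)
        assert curve.loc[curve["pos"] == 1000, "ehh"].item() == pytest.approx(1 / 3)

    def test_identical_carriers_stay_at_one(self):
        alleles = np.vstack([np.ones((4, 6), dtype=np.int8),
                             random_haplotypes(np.random.default_rng(31), 4, 6)])
        hap = _hap(alleles)
        curve = ehh(hap, 3, allele=1, carriers=np.array([True] * 4 + [False] * 4))
        assert (curve["ehh"] == 1.0).all()

    def test_fewer_than_two_carriers_rejected(self):
        alleles = np.zeros((6, 4), dtype=np.int8)
        alleles[0, 1] = 1
        with pytest.raises(ValueError, match="carrier"):
            ehh(_hap(alleles), 1, allele=1)

    def test_monotone_nonincreasing_away_from_focal(self):
        rng = np.random.default_rng(32)
        for _ in range(20):
            hap = _hap(random_haplotypes(rng, 12, 10))
            focal = int(rng.integers(0, 10))
            if hap.alleles[:, focal].sum() < 2:
                continue
            curve = ehh(hap, focal, allele=1)
            fi = int(np.flatnonzero(curve["pos"].to_numpy()
                                    == hap.positions[focal])[0])
            vals = curve["ehh"].to_numpy()
            assert np.all(np.diff(vals[fi:]) <= 1e-12)
            assert np.all(np.diff(vals[:fi + 1]) >= -1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(33)
        checked = 0
        while checked < 50:
            n_hap = int(rng.integers(4, 13)) // 2 * 2
            n_sites = int(rng.integers(3, 11))
            block = random_haplotypes(rng, n_hap, n_sites)
            focal = int(rng.integers(0, n_sites))
            allele = int(rng.integers(0, 2))
            if (block[:, focal] == allele).sum() < 2:
                continue
            hap = _hap(block)
            curve = ehh(hap, focal, allele=allele)
            expected = oracles.ehh_enumeration(block, hap.positions, focal, allele)
            for pos, val in zip(curve["pos"], curve["ehh"]):
                assert val == pytest.approx(expected[int(pos)], abs=1e-12)
            checked += 1


class TestIhh:
    def test_constant_curve_integrates_to_span(self):
        curve = pd.DataFrame({"pos": [0, 2500, 5000, 7500, 10000],
                              "ehh": [1.0] * 5})
        assert ihh(curve, focal_pos=5000) == pytest.approx(10_000)

    def test_truncation_at_first_below_cutoff_site(self):
        curve = pd.DataFrame({"pos": [0, 1000, 2000, 3000],
                              "ehh": [0.01, 1.0, 0.04, 0.5]})
        # rightward: include the 1000->2000 trapezoid then stop; leftward same
        expected = 0.5 * (1.0 + 0.04) * 1000 + 0.5 * (1.0 + 0.01) * 1000
        assert ihh(curve, focal_pos=1000) == pytest.approx(expected)

    def test_hand_built_trapezoid_sum(self):
        curve = pd.DataFrame({"pos": [0, 400, 1000, 1800],
                              "ehh": [0.3, 0.8, 1.0, 0.6]})
        left = 0.5 * (1.0 + 0.8) * 600 + 0.5 * (0.8 + 0.3) * 400
        right = 0.5 * (1.0 + 0.6) * 800
        assert ihh(curve, focal_pos=1000) == pytest.approx(left + right)

    def test_invariant_to_collinear_insertion(self):
        curve = pd.DataFrame({"pos": [0, 1000, 2000], "ehh": [0.5, 1.0, 0.5]})
        dense = pd.DataFrame({"pos": [0, 500, 1000, 1500, 2000],
                              "ehh": [0.5, 0.75, 1.0, 0.75, 0.5]})
        assert ihh(curve, 1000) == pytest.approx(ihh(dense, 1000))


class TestIhs:
    def test_symmetric_structure_gives_zero_raw(self):
        # derived and ancestral carrier classes with mirrored haplotype
        # structure around the focal site: iHH_A == iHH_D so ln ratio is 0
        half = np.array([[0, 1, 0, 1, 0], [1, 1, 1, 1, 1],
                         [0, 0, 0, 0, 0], [1, 0, 1, 0, 1]], dtype=np.int8)
        focal_col = np.array([1, 1, 0, 0])
        alleles = np.column_stack([half[:, :2], focal_col, half[:, 2:]])
        hap = _hap(alleles)
        focal_pos = int(hap.positions[2])
        ihh_d = ihh(ehh(hap, 2, allele=1), focal_pos)
        ihh_a = ihh(ehh(hap, 2, allele=0), focal_pos)
        assert np.log(ihh_a / ihh_d) == pytest.approx(0.0, abs=1e-12)

    def test_bin_standardization_moments(self, neutral_hap):
        cfg, hap = neutral_hap
        df = ihs(hap.subset_sites(hap.positions < 300_000))
        for _, grp in df.groupby("bin"):
            if len(grp) >= 2:
                assert abs(grp["z"].mean()) < 1e-9
                assert grp["z"].std(ddof=0) == pytest.approx(1.0, abs=1e-6)

    def test_low_maf_sites_excluded(self):
        rng = np.random.default_rng(34)
        block = random_haplotypes(rng, 40, 30)
        block[:, 5] = 0
        block[0, 5] = 1  # maf 1/40 < 0.05
        hap = _hap(block)
        df = ihs(hap, min_maf=0.05, min_bin_sites=1)
        assert int(hap.positions[5]) not in set(df["pos"])


class TestXpehh:
    def _two_pops(self, seed=35, n_sites=40):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(20)]
        pops = {s: ("A" if i < 10 else "B") for i, s in enumerate(ids)}
        alleles = random_haplotypes(rng, 40, n_sites)
        hap = HaplotypeMatrix(
            chrom=np.array(["chr1"] * n_sites),
            positions=np.arange(n_sites) * 500, alleles=alleles,
            sample_ids=ids, populations=pops)
        return hap.subset_population("A"), hap.subset_population("B")

    def test_same_population_gives_zero(self):
        a, _ = self._two_pops()
        df = xpehh(a, a)
        assert np.allclose(df["raw"], 0.0, atol=1e-12)

    def test_antisymmetry_exact(self):
        a, b = self._two_pops()
        ab = xpehh(a, b)
        ba = xpehh(b, a)
        assert np.allclose(ab["raw"].to_numpy(), -ba["raw"].to_numpy(), atol=1e-12)
        assert np.allclose(ab["z"].to_numpy(), -ba["z"].to_numpy(), atol=1e-10)

    def test_mismatched_sites_rejected(self):
        a, b = self._two_pops()
        with pytest.raises(ValueError, match="same sites"):
            xpehh(a, b.subset_sites(b.positions > 0))

    def test_sweep_in_pop1_scores_positive(self):
        cfg = sim.SimConfig(
            seed=40, chrom_length=500_000, n_populations=2,
            pop_sizes=[25, 25], fst_targets=0.02, theta=5e-4,
            freq_model="neutral",
            sweep_specs=[sim.SweepSpec("pop1", "chr1", 250_000, 0.9,
                                       window_bp=80_000)])
        hap, truths = sim.simulate_haplotypes(sim.simulate_frequencies(cfg), cfg)
        df = xpehh(hap.subset_population("pop1"), hap.subset_population("pop2"))
        tr = truths[0]
        win = (df["pos"] >= tr.start) & (df["pos"] < tr.end)
        assert df.loc[win, "z"].max() > 2


class TestSignificance:
    def test_bh_stepup_cascade(self):
        # p_(4) = 0.04 <= 4 * 0.05 / 4 -> all four rejected
        q, rej = significance(np.array([0.01, 0.02, 0.03, 0.04]), "bh", 0.05)
        assert rej.all()
        assert q.max() <= 0.05

    def test_bonferroni_arithmetic(self):
        p = np.full(100, 0.5)
        p[0] = 0.0004
        q, rej = significance(p, "bonferroni", 0.05)
        assert rej[0] and rej.sum() == 1
        assert q[0] == pytest.approx(0.04)

    def test_null_uniform_bh_rarely_rejects(self):
        rng = np.random.default_rng(36)
        fdr = []
        for _ in range(20):
            p = rng.uniform(size=2000)
            _, rej = significance(p, "bh", 0.05)
            fdr.append(rej.sum() > 0)
        assert np.mean(fdr) <= 0.1

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            significance(np.array([0.5, 1.2]), "bh")


class TestSweepRegions:
    def _scores(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "z"])
        df["significant"] = True
        return df

    def test_nearby_sites_merge(self):
        regs = sweep_regions(self._scores([("chr1", 10_000, 3.0),
                                           ("chr1", 15_000, 4.0)]),
                             merge_gap=10_000)
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end) == (10_000, 15_001)
        assert regs[0].n_significant == 2
        assert regs[0].peak_score == 4.0

    def test_distant_sites_split(self):
        regs = sweep_regions(self._scores([("chr1", 10_000, 3.0),
                                           ("chr1", 30_000, 3.0)]),
                             merge_gap=10_000)
        assert len(regs) == 2

    def test_gene_five_kb_boundary(self):
        from racesig.io import GeneModel

        scores = self._scores([("chr1", 10_000, 3.0)])
        near_gene = GeneModel("near", "chr1", 10_001 + 4_999, 10_001 + 5_500)
        far_gene = GeneModel("far", "chr1", 10_001 + 5_001, 10_001 + 5_600)
        inside = GeneModel("inside", "chr1", 9_990, 10_050)
        regs = sweep_regions(scores, genes=[near_gene, far_gene, inside], near=5_000)
        assert regs[0].genes_within == ["inside"]
        assert regs[0].genes_near == ["near"]

    def test_truth_interval_recovered_from_simulated_sweep(self):
        # the sweep window must be a small fraction of the scanned genome,
        # else the swept sites inflate the genome-wide standardization
        cfg = sim.SimConfig(
            seed=41, chrom_length=2_000_000, n_populations=2,
            pop_sizes=[25, 25], fst_targets=0.02, theta=4e-4,
            freq_model="neutral",
            sweep_specs=[sim.SweepSpec("pop1", "chr1", 1_000_000, 0.9)])
        hap, truths = sim.simulate_haplotypes(sim.simulate_frequencies(cfg), cfg)
        df = xpehh(hap.subset_population("pop1"), hap.subset_population("pop2"))
        df["q_value"], df["significant"] = significance(df["p_value"].to_numpy())
        regs = sweep_regions(df, merge_gap=10_000)
        tr = truths[0]
        inter = sum(max(0, min(r.end, tr.end) - max(r.start, tr.start))
                    for r in regs)
        union = sum(r.end - r.start for r in regs) + (tr.end - tr.start) - inter
        assert inter / union >= 0.5
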