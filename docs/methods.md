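# Methods

This note documents the models behind `racesig`, the defaults that
matter, what the synthetic panels do and do not emulate, and the
numerical conventions a user auditing results should know.

## Population model of the simulator

Accession panels are generated under the Balding–Nichols island model.
Each variant site gets an ancestral derived-allele frequency *p*; each
population *i* with divergence parameter *F_i* draws its frequency from
Beta(p(1−F_i)/F_i, (1−p)(1−F_i)/F_i), which has mean *p* and variance
*F_i·p(1−p)*. *F_i* maps directly onto differentiation: the expected
pairwise Weir–Cockerham Fst between populations *i* and *j* is
approximately (F_i + F_j)/2, so per-population values are solved from a
requested pairwise target matrix by least squares (clipped to
[0, 0.95]). *F* = 0 copies *p* exactly; *F* ≥ 1 is rejected. Haplotypes
are then drawn site-independently (binomially) from the population
frequencies, so the background carries no linkage disequilibrium — see
Limitations.

Two ancestral-frequency spectra are available:

- `freq_model="uniform"` (default): *p* ~ Uniform(0.05, 0.95). This is
  the generic structured-panel setting used for Fst recovery and PAV
  studies.
- `freq_model="neutral"`: *p* drawn with density ∝ 1/p on
  [10⁻⁴, 0.9999] (log-uniform draw). Binomial sampling of *n* haplotypes
  from this spectrum yields an expected site-frequency spectrum
  E[ξ_j] ∝ 1/j — the standing neutral spectrum — which is what makes
  Tajima's D centre at zero. A uniform ancestral spectrum
  over-represents intermediate frequencies and pushes D strongly
  positive, so every neutrality-calibration study uses this model. The
  truncation at 10⁻⁴ loses ~1% of singleton mass for n = 100, a bias
  far below the ±0.3 calibration window.

The number of candidate sites is chosen so that realized pooled π per bp
matches the requested θ at *F* = 0: n_sites = θ·L / E[2p(1−p)] under the
chosen spectrum (E[2p(1−p)] = 0.365 for the uniform model; the
closed-form log-uniform moment otherwise). π̂ per site is unbiased for
2p(1−p), so recovery holds in expectation; within a population with
divergence *F*, diversity shrinks by (1−F).

**Sweeps** are imposed, not forward-simulated: around the focal position
a window (default 100 kb) of the target population's haplotypes is
overwritten with one core haplotype in a `strength` fraction of
haplotypes (the focal site forced to the derived allele on the core).
Strength 1 fixes the window; strength 0 is a no-op. This gives exact,
deterministic control of the planted signal for power studies, at the
cost of realism in the sweep's flanking decay.

**PAVs** delete whole annotated genes from every accession of the listed
populations. The deletion interval extends `pav_flank_bp` (default
60 bp) into the flanks: real deletion breakpoints rarely coincide with
annotated gene boundaries, and the buffer guarantees that
junction-spanning k-mers can never coincidentally reproduce gene-edge
sequence (without it, a 1–3 bp edge coincidence occurs at rate ~1/4 per
junction and can fabricate presence support). Gene placement leaves a
matching margin so buffered deletions never touch neighbouring genes.
Genes carry proper reading frames (ATG, non-stop codons, terminal stop,
strand-oriented) so the codon-level effect annotator behaves as on real
annotation.

**Reads** are uniform single-end with i.i.d. substitution errors and
constant Phred+33 qualities consistent with the error rate. Read
placement and error injection use separate seeded streams, so the same
seed yields identical placements at any error rate — useful for paired
clean/noisy comparisons. All randomness flows from one master seed via
SHA-256-labelled `SeedSequence` spawning; identical configurations are
byte-identical across runs and platforms.

## K-mer track

k must be odd (a palindromic even-k-mer equals its own reverse
complement, making canonical counting ambiguous). Two field presets are
kept, k = 47 for distinct-k-mer comparisons and k = 31 for hash-based
counting; both are ordinary config values. The singleton filter
(`min_count=2`) drops k-mers seen once, the usual proxy for
sequencing-error k-mers.

Sketches hash canonical k-mers with splitmix64 over the 2-bit packing
(folded limb-wise beyond 32 bases), seeded with a recorded constant, and
keep the bottom-s values. The Jaccard estimate compares the bottom-s
sketch of the union against both sketches; the Mash distance is
−(1/k)·ln(2j/(1+j)), defined as 1 when j = 0 and 0 on identity. At
s = 1000 the binomial error of ĵ is ~0.016 at j = 0.5, which the
acceptance study confirms empirically.

`choose_k` maximises the count of distinct k-mers with abundance ≥
min_count — a deliberate simplification of histogram-model optimal-k
estimators that returns the same argmax on low-error data, with ties
broken toward smaller k.

PAV calling replaces read mapping with exact canonical k-mer lookup:
deterministic, dependency-free, and at k = 31/47 the chance of a
spurious 1-mismatch-free placement is negligible. Multi-mapping k-mers
support every gene they hit (presence evidence, not quantification);
`min_support` counts distinct k-mers, default 3. An optional horizontal-
coverage gate exists but is off by default — the presence rule is the
3-k-mer criterion alone.

## Variant and diversity track

Filter thresholds use inclusive (≥) comparisons, matching vcftools flag
semantics; the drop log records the first failing criterion in flag
order (MAF, mean depth, QUAL), and filtering is idempotent. MAF and
depth denominators exclude missing genotypes.

Tajima's D uses the full 1989 constants; D is reported as NaN when
S = 0, and as 0 in the degenerate n = 2 case where the numerator
vanishes identically and the variance is 0. Windows are fixed-width,
non-overlapping, 100 kb by default (a free parameter — the source
workflow never states its bin width). Weir–Cockerham Fst implements the
1984 two-level variance components from sample sizes, allele frequencies
and observed heterozygosities; single-site estimates may be negative and
are reported as-is, multi-site summaries use the ratio of sums
Σa/Σ(a+b+c). "Significantly low" Fst in the composite classifier is an
empirical quantile (default bottom 5%) — no distributional test is
implied. The composite classifier reports the raw Tajima quantile class
and the low-Fst flag separately; the interpretive labels
(purifying_or_expansion for negative-D, balancing_or_contraction for
positive-D windows that also sit in the low-Fst tail) are a configurable
aliasing layer, since mapping D sign to selection mode is
context-dependent.

LD decay computes r² on haplotype alleles when phased (genotype-dosage
correlation otherwise), bins pairs by distance, and applies no monotone
smoothing. Independent sites show the familiar 1/n finite-sample floor.

The effect annotator rewrites the affected codon respecting strand and
phase and classifies synonymous / non-synonymous / start_lost /
stop_gained / stop_lost with SnpEff-style impact classes (high /
moderate / low / modifier); reference CDSs with internal stops are
flagged and skipped. Start-gain calls would require annotated 5'UTRs and
are not reported. Multi-allelic records are out of scope; the VCFs the
simulator writes are biallelic SNPs with phased GT and per-sample DP.

## Haplotype scans

EHH among the n_c carriers of an allele at a focal site is
Σ_h C(n_h,2)/C(n_c,2) over distinct extended haplotypes h; it is 1 at
the focal site and monotone non-increasing outward. iHH integrates the
curve by trapezoids over bp distance on each side, stopping after the
first site whose EHH falls below the cutoff (default 0.05; that final
trapezoid is included). No gap-scaling penalty is applied between
distant markers — distances enter only through trapezoid widths.

iHS = ln(iHH_ancestral/iHH_derived) is standardized within 50
equal-width derived-allele-frequency bins, adjacent bins merged until
each holds ≥ 10 sites; sites below 5% MAF, with < 2 carriers of either
allele, or with a zero one-sided class iHH are excluded. XP-EHH uses the
all-haplotype site EHH per population and genome-wide standardization
(the standard choice for XP-EHH); positive scores mean longer haplotypes
in population 1, and swapping populations negates scores exactly.
p = 2Φ(−|z|) in both scans. Both BH and Bonferroni corrections are
provided (the workflow wording "Bonferroni FDR" is ambiguous); BH at
α = 0.05 is the default and the choice is recorded in CLI output
headers. Allele polarity comes from the simulator's truth channel;
loading a VCF treats REF as ancestral, which callers on real data should
treat as a stated assumption.

Significant sites within 10 kb on a chromosome merge into one sweep
region (merge gap is a free parameter — no published rule defines how
sites become regions); genes are partitioned into those overlapping the
region and those within 5 kb of its boundary.

Sweep power and region recovery are measured on a 2 Mb chromosome with a
100 kb sweep window. The window must be a small fraction of the scanned
genome: standardized scores are genome-relative, and a sweep occupying a
large share of sites inflates its own standardization variance — which
is also why genuine scans run genome-wide. Region recovery is scored as
the Jaccard index between the union of called regions and the truth
window.

## Cross-population comparison

Interval algebra is 0-based half-open throughout (GFF3 converted at the
I/O boundary, VCF positions at the parser). Two regions from different
populations count as "the same region" when they overlap reciprocally by
≥ 50% of each — an explicit operationalisation, since region identity
across populations has no standard definition. Venn-style tallies are
connected-component counts under that relation and always partition the
clusters.

Relatedness uses the allele-sharing distance 1 − IBS =
mean(|g_i − g_j|)/2 over co-non-missing sites (the distance behind the
NJ tree is rarely stated in applied work; allele sharing is the common
default). NJ and PCoA are delegated to scikit-bio: Saitou–Nei
agglomeration with negative branch lengths clamped to zero, and
double-centred Gower eigendecomposition with negative eigenvalues
reported rather than dropped. Bootstrap support resamples sites (not
samples) with replacement and counts bipartition recovery.

## Problem sizes used in the checks

The test and acceptance studies run at desk scale, chosen to make every
statistical property measurable in minutes on one core: ~10,000 sites ×
2 × 50 diploids for Fst recovery; a 1 Mb neutral chromosome (200 windows
of 5 kb) for calibration; 20 replicates of a 2 Mb chromosome for sweep
power; 60 genes on 72 kb with 50 planted PAVs at 10× / 1% error for PAV
recovery; sketch size 1,000 on 20 kb sequences for Mash accuracy.

## Limitations

- **No background LD**: sites are independent given population
  frequencies, so neutral iHH values are small and sweep contrast is
  sharper than in recombining genomes. Passing the power studies shows
  the estimators rank and localise planted signals correctly; it does
  not measure power under realistic recombination. A coalescent
  simulator (e.g. msprime) is the natural cross-check when LD realism
  matters.
- No demography beyond the island model, no recombination maps, no
  indels beyond whole-gene deletion, no gene flow or admixture.
- Exact k-mer placement tolerates no mismatches; diverged-but-present
  genes in real data need mapping-based evidence.
- Variant calling itself (and phasing) are upstream of this package:
  VCF input is assumed filtered-ready and phased where the scans need
  it.
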