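"""K-mer signatures across five simulated races.

Builds a small five-race panel with race-private gene deletions, counts
canonical 31-mers per accession, decomposes the union into sharing
classes and pulls out the k-mers private to each race.
"""

from racesig import simulate as sim
from racesig.kmers import count_kmers, group_specific_kmers, sharing_decomposition

# genes 1-10 each survive in exactly one race: a race-private signature
pavs = [
    sim.PavSpec(f"gene{g:04d}",
                [p for p in sim.RACE_NAMES if p != sim.RACE_NAMES[g % 5]])
    for g in range(1, 11)
]
cfg = sim.SimConfig(seed=7, chrom_length=60_000, n_populations=5,
                    pop_sizes=[2] * 5, fst_targets=0.1, theta=1e-3,
                    n_genes=20, pav_specs=pavs)
panel = sim.simulate_genomes(cfg)

tables = [count_kmers(list(g.values()), k=31, source=acc)
          for acc, g in panel.genomes.items()]
profile = sharing_decomposition(tables)

print("sharing classes (how many accessions carry each k-mer):")
print(profile.class_table().to_string(index=False))
# the top class (all 10 accessions) is the conserved core; the bottom
# class holds accession-unique sequence from drift and deletions

private = group_specific_kmers(profile, panel.populations)
print("\nrace-private k-mers (carried only by accessions of one race):")
for race, kmers in private.items():
    print(f"  {race:10s} {len(kmers):6d}")
# races that exclusively retain a deleted gene gain its whole k-mer set
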