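"""MinHash sketch distances and a neighbor-joining tree.

Sketches each accession's genome (bottom-1000 MinHash of canonical
21-mers), computes the pairwise Mash distance matrix and summarises the
panel's relatedness with an NJ tree.
"""

from skbio import DistanceMatrix

from racesig import simulate as sim
from racesig.kmers import distance_matrix, sketch
from racesig.relatedness import nj_tree

cfg = sim.SimConfig(seed=21, chrom_length=80_000, n_populations=3,
                    pop_sizes=[2, 2, 2], fst_targets=0.15, theta=2e-3)
panel = sim.simulate_genomes(cfg)

sketches = [sketch(list(g.values()), k=21, s=1000, name=acc)
            for acc, g in panel.genomes.items()]
dist = distance_matrix(sketches)
print("Mash distance matrix (0 = identical k-mer content):")
print(dist.round(4).to_string())

tree, newick = nj_tree(DistanceMatrix(dist.to_numpy(), ids=list(dist.index)))
print("\nNJ tree over Mash distances:")
print(newick)
# accessions of the same population pair up: within-population distances
# are driven by theta, between-population distances also by drift (Fst)
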