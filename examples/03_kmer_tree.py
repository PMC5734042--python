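"""Alignment-free phylogeny of a gene family.

Generates a small family of diverged gene copies, computes the pairwise
fractional-common-k-mer distance (k = 15) on their CDSs, and resolves the
matrix into an unrooted neighbor-joining tree.
"""

from aadscan.phylo import kmer_distance_matrix, neighbor_joining, write_newick
from aadscan.seq_core import NucleotideSequence
from aadscan.synthetic_data import LesionSpec, generate_ancestor, generate_family

ancestor = generate_ancestor(n_codons=200, gc_target=0.40, seed=3)
loci, _ = generate_family(
    ancestor,
    lesions=[LesionSpec()] * 5,
    divergence_sub_rate=0.04,
    flank_nt=0,
    seed=9,
    labels=[f"copy{i}" for i in range(1, 6)],
)
cds = [NucleotideSequence(l.label, l.forward().cds.residues) for l in loci]

dm = kmer_distance_matrix(cds, k=15)
print("k-mer distance matrix (d = 1 - shared/min profile size):")
for i, a in enumerate(dm.labels):
    row = " ".join(f"{dm.values[i, j]:.3f}" for j in range(len(dm)))
    print(f"  {a}: {row}")

tree = neighbor_joining(dm)
print("\nneighbor-joining tree (unrooted, Newick):")
print(" ", write_newick(tree))
print("\nDistances near 0 mean the copies share most 15-mers.  Two copies at"
      "\n4% divergence each differ pairwise by ~8%, so a 15-mer survives in"
      "\nboth with probability ~0.92^15 = 0.29 -- distances of 0.6-0.8 are"
      "\nexpected between copies.")
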