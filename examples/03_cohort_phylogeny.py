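"""Alignment-free phylogeny of a synthetic two-group cohort.

Generates 4 eukaryote-like and 4 prokaryote-like proteomes, computes all
pairwise fingerprint distances and reconstructs the neighbor-joining tree,
then checks that the two groups come out as clades.
"""

import ldfingerprint as ld

part = ld.default_partition(10, 10)

specs = [ld.eukaryote_like(f"euk{k}", seed=10 + k) for k in range(4)]
specs += [ld.prokaryote_like(f"prok{k}", seed=20 + k) for k in range(4)]

fps = [
    ld.compute_fingerprint(ld.sample_proteome(s).proteome(), part) for s in specs
]
dm = ld.distance_matrix(fps)
print("pairwise fingerprint distances:")
print(dm.to_data_frame().round(3).to_string())

tree = ld.nj_tree(dm)
print("\nneighbor-joining tree (Newick):")
print(ld.to_newick(tree).strip())

euk_clade = ld.clade_check(tree, {f"euk{k}" for k in range(4)})
prok_clade = ld.clade_check(tree, {f"prok{k}" for k in range(4)})
print(f"\neukaryote-like group forms a clade: {euk_clade}")
print(f"prokaryote-like group forms a clade: {prok_clade}")
print(
    "\nSmall within-group distances and the clean two-clade topology show "
    "that the density fingerprints separate the two proteome architectures."
)
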