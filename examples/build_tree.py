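"""Neighbor-joining tree with bootstrap support from an aligned FASTA.

Builds a small aligned protein set in memory, computes p-distances under
pairwise gap deletion, runs NJ, bootstraps 200 column resamples, and
prints the newick string.
"""

import genefamkit as gk

rows = {
    "PtrX1": "MKVWDERYHALCNQTSGPFI",
    "PtrX2": "MKVWDERYHALCNQTSGPFV",
    "VvX1":  "MKVWDERFHALCNQTAGPFI",
    "AtX1":  "MRVWEERFHSLCNKTAGPFI",
    "OsX1":  "MRIWEHRFNSLCDKTAGAFI",
}
aln = gk.Alignment(
    [gk.SequenceRecord(name, "", seq, aligned=True) for name, seq in rows.items()]
)

tree = gk.bootstrap_support(aln, reps=200, rng_seed=42)
print(tree.to_newick())
# internal labels are bootstrap percentages: how often each grouping
# reappears when alignment columns are resampled

species = {name: name[:2] for name in rows}
for a, b, kind in gk.sister_pairs(tree, species):
    print(f"cherry ({a}, {b}): {kind}")
# same-species cherries are paralogs (duplicates); cross-species are
# orthologs separated by speciation
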