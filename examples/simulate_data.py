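"""Write a full synthetic input set to disk: GFF3 gene maps, a homology
table, and the planted-feature truth table.

The outputs round-trip through the package's own readers, so they double
as end-to-end fixtures.
"""

from pathlib import Path

import genefamkit as gk

outdir = Path("scratch/simulated_genomes")
sim = gk.simulate_genome_pair(gk.GenomeSimSpec(rng_seed=42))
sim.write(outdir)
print("wrote", sorted(p.name for p in outdir.iterdir()))

models = gk.read_gff3(outdir / "genome_a.gff3")
hom = gk.read_homology_table(outdir / "homology.tsv")
print(f"genome A: {len(models)} genes; homology entries after E<1e-10 filter: {len(hom)}")
# the background noise pairs are weaker than 1e-10 and vanish at read
# time; only planted block and tandem homologies survive
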