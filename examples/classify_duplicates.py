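"""Tandem vs segmental duplication calls on simulated genomes.

Tandem: <=5 intervening genes within 100 kb on one chromosome.
Segmental: >=5 flanking gene pairs that are mutual best non-self matches.
Tandem is tested first; segmental only for non-tandem pairs.
"""

import genefamkit as gk

sim = gk.simulate_genome_pair(gk.GenomeSimSpec(rng_seed=7))
hom = sim.homology()

for a, b in sim.truth["tandem_pairs"]:
    call = gk.classify_pair(a, b, sim.genome_a, sim.genome_a, hom)
    print(f"{a}/{b}: {call.mode} "
          f"({call.intervening_genes} intervening, {call.span_bp:,} bp apart)")
# adjacent homologs a few kb apart -> tandem

for blk in sim.truth["blocks"]:
    a, b = blk["anchor"]
    call = gk.classify_pair(a, b, sim.genome_a, sim.genome_b, hom)
    print(f"{a}/{b}: {call.mode} ({call.n_flanking_pairs} flanking best-match pairs)")
# anchors of planted blocks carry 5 flanking reciprocal best matches ->
# segmental (large-scale) duplication
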