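"""Physical properties of a protein and family-level summaries.

Computes molecular weight and isoelectric point for a short peptide, then
summarizes the shipped 57-member WRKY III reference table.
"""

import genefamkit as gk

peptide = gk.SequenceRecord("demo", "", "MKVWDERYHALCNQTSGPFI")
print(f"{peptide.id}: {gk.compute_mol_wt(peptide):.2f} Da, pI {gk.compute_pi(peptide):.2f}")
# ~2396 Da for 20 residues; pI ~7.4 — near-neutral with one His/Arg pair
# balancing the two acidic side chains

table = gk.load_gene_table()
props = [
    gk.ProteinProps(r.name, int(r.length_aa), float(r.mol_wt_da), float(r.pi))
    for r in table.itertuples(index=False)
]
s = gk.summarize_props(props)
print(
    f"family of {s['n']}: longest {s['length_max_aa']} aa ({s['length_max_gene']}), "
    f"MW {s['mol_wt_min_kda']}-{s['mol_wt_max_kda']} kDa, "
    f"{s['n_alkaline']} alkaline (pI > 7)"
)
# the three alkaline members stand out in an otherwise acidic family
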