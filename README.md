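# genefamkit

A comparative-evolution toolkit for plant gene families, built around the
analyses a family-wide genomics study chains together: physical protein
properties, exon/intron structure, neighbor-joining phylogeny with
bootstrap, microsynteny and relative syntenic quality, tandem vs
segmental duplication classification, NG86 Ka/Ks with sliding windows and
synonymous-clock dating, and 2^−ΔΔCT qPCR quantification. It ships with
reference tables for the 57-member group III WRKY transcription-factor
family of poplar (*Populus trichocarpa*), grape, *Arabidopsis*, and rice,
plus synthetic-data generators so every stage can be exercised — and its
error rates measured — without any genome downloads.

It is a library for people doing gene-family evolution analyses in
Python: the public functions and the `examples/` scripts are the
interface.

## The methods in brief

**Microsynteny.** A family gene pair anchors a putative block; windows of
15 genes upstream and downstream of each anchor are compared, and a block
is called when ≥ 3 conserved homolog pairs (anchor included, homology
filtered at E < 10⁻¹⁰) link the windows. Relative syntenic quality is
100·2m/(Nₐ+N_b), the fraction of window genes in conserved pairs after
excluding transposons and collapsing tandem runs.

**Duplication modes.** Tandem: same chromosome, ≤ 5 intervening genes
*and* ≤ 100 kb apart (conjunctive). Segmental: ≥ 5 flanking gene pairs
around the anchor point that are each other's best non-self match. Tandem
takes precedence.

**Ka/Ks and dating.** Nei–Gojobori (1986) counting with equal-weight
pathway averaging and Jukes–Cantor correction d = −¾ ln(1 − 4p/3);
Ks > 2.0 is treated as saturated and excluded. Duplications are dated
with a synonymous clock, T = Ks / (2 × 9.1×10⁻⁹) × 10⁻⁶ Mya, applied to
the mean Ks of a block's conserved flanking genes. Sliding windows
(150 bp / 9 bp, snapped to codons) profile selection along a gene.

**Phylogeny.** p-distances under pairwise gap deletion, Saitou–Nei
neighbor joining with deterministic tie-breaks, bootstrap bipartition
support over column resamples, and cherry extraction into
paralog/ortholog pairs.

**Expression.** 2^−ΔΔCT with technical replicates averaged before
biological ones, normalized to a reference gene and an untreated control
set to 1.

## A worked example

```python
import genefamkit as gk

# date the family's duplicated blocks from their published mean flanking Ks
for row in gk.load_duplication_dates().itertuples(index=False):
    print(f"{row.pair}: Ks {row.ks_mean:.4f} -> {gk.date_from_ks(row.ks_mean):.2f} Mya")
```

```
PtrWRKY41/53: Ks 0.2958 -> 16.25 Mya
PtrWRKY62/89: Ks 0.3045 -> 16.73 Mya
PtrWRKY64/63: Ks 0.2857 -> 15.70 Mya
PtrWRKY64/53: Ks 1.0270 -> 56.43 Mya
PtrWRKY63/53: Ks 1.1829 -> 64.99 Mya
PtrWRKY41/64: Ks 1.2803 -> 70.35 Mya
PtrWRKY41/63: Ks 1.2109 -> 66.53 Mya
PtrWRKY90/55: Ks 0.2635 -> 14.48 Mya
```

Each line converts a block's mean synonymous distance into an age: the
poplar WRKY III duplications fall into a recent (~14–17 Mya) and an older
(~56–70 Mya) episode. All eight mean Ka/Ks ratios are below 0.4, i.e.
strong purifying selection. The scripts in `examples/` walk through the
other capabilities one at a time (properties, structure, trees, synteny,
duplication calls, sliding windows, qPCR, simulation); each prints a few
numbers and says what they mean.

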