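# Methods

This note documents the models and procedures genefamkit implements, the
defaults it ships with, the choices made where conventions diverge, and
what the synthetic-data tests do and do not demonstrate.

## Configuration

All thresholds live in `RunConfig`; defaults encode the study conditions
the package is built around.

| parameter | default | meaning |
|---|---|---|
| `window_genes` | 15 | genes scanned up- and downstream of a synteny anchor (31-gene window) |
| `min_conserved_pairs` | 3 | conserved homolog pairs (anchor included) required to call a block |
| `tandem_max_intervening` | 5 | max genes between a tandem pair |
| `tandem_max_span_bp` | 100 000 | max intergenic distance for a tandem pair (bp) |
| `segmental_min_flanking_pairs` | 5 | best-non-self-matched flanking pairs required for a segmental call |
| `significance_cutoff` | 1e-10 | homology E-value filter, strict `<` applied at read time |
| `ks_max` | 2.0 | Ks saturation boundary; strictly greater values are discarded |
| `clock_rate` | 9.1e-9 | synonymous substitutions/site/year for the molecular clock |
| `sw_window_bp`, `sw_step_bp` | 150, 9 | sliding-window size and step, snapped down to whole codons (50 / 3) |
| `bootstrap_reps` | 1000 | bootstrap replicates |
| `rng_seed` | 42 | seed for every randomized operation |

## Protein properties

Molecular weight is the sum of average residue masses plus one water
(18.01524 Da); monoisotopic masses are deliberately not used. `X`
residues are rejected here (undefined mass) but allowed in lengths. The
isoelectric point is the root of the composition-only
Henderson–Hasselbalch net charge over both termini and the D, E, C, Y,
H, K, R side chains, found by bisection on [0, 14] stopping at
|charge| < 10⁻⁴ or an interval below 10⁻⁴. The default pKa set is the
EMBOSS one and is a keyword argument: published pKa sets (EMBOSS,
Bjellqvist, …) disagree by ~0.1 pH unit, so pI values from different
tools should only ever be compared as printed, and the reference-table
tests compare against the table's printed column, not a recomputation.
Near the pI the charge curve is nearly flat, so the |charge| stopping
rule can return a pH ~0.01 away from the analytic root; this is inside
any cross-tool disagreement.

## Gene models and coordinates

Coordinates are 1-based inclusive (GFF3). Exon intervals include UTR
exons; coding sequence is only used by the Ka/Ks machinery. The
intergenic gap between two genes is start(downstream) − end(upstream),
so adjacent intervals [1,10] and [11,20] are 1 bp apart and overlapping
genes are 0 — this convention reproduces the reference family's printed
tandem-pair distance (20,112 bp) exactly. When a GFF3 gene carries
several mRNAs the lexicographically first mRNA id is taken, a
deterministic stand-in for a primary-transcript flag the format does not
guarantee. Transposons are recognized by the keywords
{transposon, retrotransposon, transposable_element} in `biotype`/`Note`
attributes.

## Phylogeny

Distances are p-distances under pairwise gap deletion (per pair, only
columns ungapped in both rows are compared), with a Poisson correction
available. Neighbor joining follows Saitou–Nei: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·), ties broken by the smallest
sorted pair of representative ids (smallest leaf label per cluster) so
runs are reproducible; branch lengths use the standard formulas, and a
negative length is clamped to zero with its deficit moved to the sister
branch, conserving the joined distance. On additive matrices this
recovers the generating topology and all path lengths exactly (verified
over random additive trees of 5–10 taxa). Bootstrap support is the
percentage of column-resample replicates whose NJ tree contains the same
bipartition; replicates in which some pair has no comparable columns are
skipped and logged rather than counted as zeros. Multiple sequence
alignment construction is out of scope — tree building consumes a
pre-aligned FASTA; the pairwise BLOSUM62/affine aligner exists for the
codon pipeline.

## Microsynteny and syntenic quality

Windows are anchor rank ± `window_genes` on the chromosome gene order,
truncated at chromosome ends. Conserved pairs are a greedy one-to-one
matching of window genes over the filtered homology table, highest
scores first with id tie-breaks; the anchor pair always counts. Greedy
matching (rather than optimal bipartite matching) is deterministic and
near-optimal at window scale. Quality is 100·2m/(Nₐ+N_b) with the
denominators cleaned in two ways: transposon-flagged genes are removed,
and runs of consecutive window genes that are homologs of each other
within the tandem span are collapsed to one. The aggregation used for
family tables is: clade means per species pair → pair average = mean of
clade means → overall = mean of pair averages, with half-up rounding to
two decimals on output only (intermediate values stay unrounded). Empty
groups are omitted, never treated as zero.

## Duplication classification

The tandem rule is conjunctive (gene-count and distance conditions must
both hold); it is symmetric and tested exhaustively against a brute-force
restatement. The segmental rule counts flanking pairs where *either*
gene's best non-self match (lowest significance, then highest score,
then smallest id) is the other — the inclusive reading of a directional
"best match" criterion — with each gene used at most once. Tandem is
evaluated first; a pair is never both.

## NG86 Ka/Ks

Per codon, each position contributes a synonymous-site fraction equal to
the share of its three single-nucleotide changes that are synonymous;
changes creating stop codons count as neither synonymous nor
nonsynonymous (the denominator stays 3). S is averaged over the two
sequences; N = 3L − S, so sites always partition 3 per compared codon.
Observed differences are averaged with equal weight over all mutational
orderings that avoid stops; codon pairs with a gap, a stop, or all
pathways blocked are excluded from both sites and differences.
Proportions are Jukes–Cantor corrected; p ≥ 3/4 marks saturation and the
corrected value is NaN, as is the Ka/Ks ratio whenever Ks is zero or
saturated — undefined ratios propagate as missing values, never as 0 or
infinity. This convention matches the Biopython NG86 implementation on
the worked single-codon example, and agrees to 10⁻¹² with an
independently written brute-force oracle across random codon pairs.
Counting methods like NG86 sit below likelihood codon models in
sophistication; dating, however, depends only on a Ks estimate, and the
package's clock arithmetic is validated against the reference family's
printed mean-Ks → date column (agreement to ~0.02%, the residual being
the rounding of the printed means).

Sliding windows are given in bp and snapped down to whole codons
(150 → 50, 9 → 3) because Ka/Ks is codon-defined. Windows advance by the
step until one reaches the alignment end; the last window is truncated
there, and a window longer than the alignment degenerates to one
full-length window. Non-overlapping windows recombine exactly to the
whole-gene site and difference counts.

Block dating takes the mean and sample SD (n−1) over a block's
unsaturated flanking estimates; a single usable estimate reports SD 0
with an explicit flag, and a block whose flanking estimates are all
saturated is an error, not a date.

## qPCR

2^−ΔΔCT with a fixed averaging order: technical replicates are averaged
within each biological replicate first, ΔCT = CT(target) − CT(reference)
per biological replicate, ΔΔCT subtracts the control sample's mean ΔCT,
and the reported fold is the mean of 2^−ΔΔCT over biological replicates
with its sample SD. The SD is taken on the fold scale (of 2^−ΔΔCT), not
back-transformed from ΔΔCT. With one biological replicate the control is
exactly 1; with several noisy replicates its mean is slightly above 1
(Jensen's inequality) — a property of the estimator, not a bug. The
reference gene is caller-named. Up/down calls at ≥2-fold and ≤0.5-fold
are conventions and configurable. Tissue maxima break exact ties in a
fixed tissue order (roots, young leaves, mature leaves, stems, xylem,
phloem).

## Synthetic data

The genome simulator emulates ordered gene maps: chromosomes of genes
with 200–5,000 bp intergenic gaps (so 100-kb tandem spans stay
meaningful at toy scale), 1–5 exons each, planted syntenic blocks
(conserved-order homolog runs at significance 10⁻⁵⁰), tandem arrays
(adjacent strong homologs), Bernoulli transposon flags, and background
homology noise strictly weaker than the read-time filter. Defaults are
2 chromosomes × 60 genes per genome, 2 blocks of 6 pairs, 2 tandem
arrays, 10% transposons. The truth table it emits is sufficient to score
recall and false positives without re-deriving ground truth. It does
*not* simulate inversions, translocations, gene loss, or homology
detection noise above the filter — so passing detection tests show the
rules are implemented correctly and separate signal from weak noise, not
that they are robust to real rearranged genomes.

The codon simulator draws a random sense-codon ancestor and places
Poisson numbers of synonymous and nonsynonymous events (expectations
target·sites on the ancestor) uniformly over eligible single-nucleotide
changes down two lineages, rejecting stop-creating changes. This is
count-targeted placement, not a continuous-time substitution model: it
gives direct control of realized divergence for recovery tests, at the
price of not modeling transition/transversion bias or codon frequencies.
Median NG86 recovery on this generator is within 10% for Ks ≤ 1 and 15%
for ω (100 seeded replicates per setting, 500 codons), which also bounds
the method's mild counting bias under these conditions.

The CT-table simulator writes 3 biological × 3 technical replicates per
cell with reference CT 20 plus Gaussian cycle noise and target CT offset
by −log₂(fold); with zero noise the estimator returns designed folds
exactly, closing the loop on the ΔΔCT arithmetic.

All generators are pure functions of (spec, seed); identical calls give
byte-identical outputs.

## Problem sizes

The shipped test-suite and acceptance-script runs use the generator
defaults above: 100-replicate detection simulations on 120-gene genome
pairs, 100-replicate × 9-setting codon recovery at 500 codons, 50
additive matrices for NJ, and 50–100 qPCR seeds. These sizes give the
quoted guarantees sub-minute runtimes while keeping binomial noise on
the measured rates well inside the asserted bounds.

## Known limitations

- Homology is consumed as a precomputed score table; running BLAST-like
  searches, and multiple sequence alignment, are out of scope.
- The syntenic-quality denominator follows the verbal definition above;
  other tools draw window boundaries and collapse tandems differently,
  so absolute percentages are comparable only within one convention.
- NG86 has no transition/transversion or codon-frequency weighting;
  likelihood models (GY94-style) will differ, most at high divergence.
- The clock rate is a constant; dates inherit its uncertainty wholesale.
- Reference-table pI/MW columns are printed values from their source and
  are internally inconsistent for a few rows; they are treated as fixture
  facts, and the package's own property calculators are validated
  independently (hand sums, closed forms, cross-checks).
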