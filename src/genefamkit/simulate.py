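"""Synthetic-data generators with the statistical structure each pipeline
stage assumes, so every stage is testable without genome downloads.

Three generators, all pure functions of (spec, seed):

* ordered gene maps for two genomes with planted syntenic blocks, tandem
  arrays, transposon flags and background homology noise, plus a ground
  truth table sufficient to score detection without re-deriving it;
* duplicate codon-sequence pairs evolved to target Ka and Ks by
  count-targeted Poisson placement of synonymous/nonsynonymous events
  (direct control of realized divergence for recovery tests — deliberately
  not a continuous-time substitution-model simulator);
* replicated qPCR CT tables with known fold changes and Gaussian cycle
  noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genes import GeneModel
from .io import HomologyTable, SequenceRecord
from .kaks import NT, SENSE_CODONS, STOP_CODONS, _aa, codon_syn_fraction
from .synteny import Genome

# ---------------------------------------------------------------------------
# Genome pairs with planted structure


@dataclass
class GenomeSimSpec:
    n_chromosomes: int = 2
    genes_per_chromosome: int = 60
    n_planted_blocks: int = 2
    block_size: int = 6  # conserved pairs per block, anchor included
    n_tandem_arrays: int = 2
    array_span_bp: int = 100_000
    transposon_fraction: float = 0.1
    background_homology_rate: float = 0.02
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.genes_per_chromosome) < 1:
            raise ValueError("need at least one chromosome and one gene")
        for frac in (self.transposon_fraction, self.background_homology_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass
class GenomeSim:
    spec: GenomeSimSpec
    genome_a: Genome
    genome_b: Genome
    homology_records: list[tuple[str, str, float, float]]
    truth: dict

    def homology(self, significance_cutoff: float = 1e-10) -> HomologyTable:
        return HomologyTable.from_records(self.homology_records, significance_cutoff)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for genome, name in ((self.genome_a, "genome_a"), (self.genome_b, "genome_b")):
            lines = ["##gff-version 3"]
            for m in sorted(genome.models.values(), key=lambda g: (g.chromosome, g.start)):
                attrs = f"ID={m.gene_id}"
                if m.is_transposon:
                    attrs += ";biotype=transposable_element"
                lines.append(
                    "\t".join(
                        [m.chromosome, "sim", "gene", str(m.start), str(m.end), ".",
                         m.strand, ".", attrs]
                    )
                )
                mrna = f"{m.gene_id}.t1"
                lines.append(
                    "\t".join(
                        [m.chromosome, "sim", "mRNA", str(m.start), str(m.end), ".",
                         m.strand, ".", f"ID={mrna};Parent={m.gene_id}"]
                    )
                )
                for es, ee in m.exons:
                    lines.append(
                        "\t".join(
                            [m.chromosome, "sim", "exon", str(es), str(ee), ".",
                             m.strand, ".", f"Parent={mrna}"]
                        )
                    )
            (outdir / f"{name}.gff3").write_text("\n".join(lines) + "\n")
        hom = pd.DataFrame(
            self.homology_records, columns=["gene_a", "gene_b", "score", "significance"]
        )
        hom.to_csv(outdir / "homology.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))


def _build_genome(label: str, spec: GenomeSimSpec, rng: np.random.Generator) -> Genome:
    models: list[GeneModel] = []
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = 1000
        for gi in range(spec.genes_per_chromosome):
            pos += int(rng.integers(200, 5001))  # intergenic gap 200-5000 bp
            glen = int(rng.integers(600, 3001))
            start, end = pos, pos + glen - 1
            n_ex = int(rng.integers(1, 6))
            piece = glen // (2 * n_ex - 1)
            if piece < 1:
                n_ex = 1
            exons = [
                (start + 2 * k * piece, start + 2 * k * piece + piece - 1)
                for k in range(n_ex)
            ] if n_ex > 1 else [(start, end)]
            exons[-1] = (exons[-1][0], end)
            models.append(
                GeneModel(
                    gene_id=f"{label}_{chrom}_g{gi:03d}",
                    chromosome=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    start=start,
                    end=end,
                    exons=exons,
                    is_transposon=bool(rng.random() < spec.transposon_fraction),
                )
            )
            pos = end
    return Genome.from_models(label, models)


def simulate_genome_pair(spec: GenomeSimSpec, window_genes: int = 15) -> GenomeSim:
    """Two ordered genomes with planted syntenic blocks (strong conserved
    homology in matching windows), tandem arrays in genome A, transposon
    flags, and background homology noise too weak to pass the read-time
    significance filter. The truth table lists every planted feature."""
    rng = np.random.default_rng(spec.rng_seed)
    gen_a = _build_genome("ga", spec, rng)
    gen_b = _build_genome("gb", spec, rng)

    half = spec.block_size // 2
    slot = 2 * window_genes + spec.block_size + 4
    per_chrom = max(1, spec.genes_per_chromosome // slot)
    if spec.n_planted_blocks > per_chrom * spec.n_chromosomes:
        raise ValueError(
            f"cannot pack {spec.n_planted_blocks} blocks of window {window_genes} "
            f"into {spec.n_chromosomes} x {spec.genes_per_chromosome} genes"
        )

    records: list[tuple[str, str, float, float]] = []
    truth: dict = {"blocks": [], "tandem_pairs": [], "transposons": sorted(
        m.gene_id for g in (gen_a, gen_b) for m in g.models.values() if m.is_transposon
    )}
    # offsets around the anchor: 0, +1, -1, +2, -2, ...
    offsets = [0]
    for k in range(1, spec.block_size):
        offsets.append((k + 1) // 2 * (1 if k % 2 else -1))
    reserved_a: set[str] = set()

    for bi in range(spec.n_planted_blocks):
        chrom = f"chr{(bi % spec.n_chromosomes) + 1}"
        center = window_genes + half + 1 + (bi // spec.n_chromosomes) * slot
        map_a = gen_a.maps[chrom]
        map_b = gen_b.maps[chrom]
        if center + window_genes + half >= len(map_a.ordered_gene_ids):
            raise ValueError("cannot pack planted block near chromosome end")
        pairs = []
        for off in offsets:
            a_id = map_a.ordered_gene_ids[center + off]
            b_id = map_b.ordered_gene_ids[center + off]
            records.append((a_id, b_id, float(rng.integers(300, 600)), 1e-50))
            pairs.append([a_id, b_id])
            reserved_a.add(a_id)
        truth["blocks"].append({"anchor": pairs[0], "pairs": pairs})

    # tandem arrays: adjacent homologous gene pairs in genome A, placed on
    # the last chromosome tail, clear of planted block windows
    tail_map = gen_a.maps[f"chr{spec.n_chromosomes}"]
    free = [
        i
        for i in range(len(tail_map.ordered_gene_ids) - 1)
        if tail_map.ordered_gene_ids[i] not in reserved_a
        and tail_map.ordered_gene_ids[i + 1] not in reserved_a
    ]
    for ti in range(spec.n_tandem_arrays):
        if len(free) < 1:
            break
        pick = int(rng.integers(0, len(free)))
        i = free[pick]
        a1 = tail_map.ordered_gene_ids[i]
        a2 = tail_map.ordered_gene_ids[i + 1]
        records.append((a1, a2, float(rng.integers(300, 600)), 1e-40))
        truth["tandem_pairs"].append([a1, a2])
        free = [f for f in free if abs(f - i) > 1]

    # background noise: weak pairs that the E-value filter must drop
    all_ids = sorted(gen_a.models) + sorted(gen_b.models)
    n_noise = rng.binomial(len(all_ids), spec.background_homology_rate)
    for _ in range(int(n_noise)):
        x, y = rng.choice(len(all_ids), size=2, replace=False)
        sig = 10.0 ** float(rng.uniform(-9, -2))  # always > 1e-10
        records.append((all_ids[int(x)], all_ids[int(y)], float(rng.integers(30, 80)), sig))

    return GenomeSim(spec, gen_a, gen_b, records, truth)


# ---------------------------------------------------------------------------
# Codon pairs evolved to target Ka / Ks


@dataclass
class CodonSimSpec:
    n_codons: int = 500
    target_ks: float = 0.3
    target_ka: float = 0.1
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")
        if self.target_ks < 0 or self.target_ka < 0:
            raise ValueError("targets must be >= 0")


@dataclass
class CodonPairSim:
    cds_a: SequenceRecord
    cds_b: SequenceRecord
    protein_a: SequenceRecord
    protein_b: SequenceRecord
    truth: dict = field(default_factory=dict)


def _place_event(codons: list[str], synonymous: bool, rng: np.random.Generator) -> tuple:
    """One random single-nucleotide change of the requested class, uniform
    over eligible (codon, position, nucleotide) choices via rejection."""
    for _ in range(2000):
        ci = int(rng.integers(0, len(codons)))
        pos = int(rng.integers(0, 3))
        nt = NT[int(rng.integers(0, 4))]
        codon = codons[ci]
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if alt in STOP_CODONS:
            continue
        if (_aa(alt) == _aa(codon)) != synonymous:
            continue
        codons[ci] = alt
        return ci, pos, codon, alt
    raise RuntimeError("no eligible change found")


def simulate_codon_pair(spec: CodonSimSpec) -> CodonPairSim:
    """Evolve a random ancestral CDS down two lineages with Poisson numbers
    of synonymous / nonsynonymous events (expectations target_ks * S and
    target_ka * N on the ancestor's site counts), events split evenly
    between lineages at random. The truth records the realized event log."""
    from .kaks import translate_cds

    rng = np.random.default_rng(spec.rng_seed)
    for attempt in range(100):
        ancestor = [SENSE_CODONS[int(i)] for i in rng.integers(0, len(SENSE_CODONS), spec.n_codons)]
        s_sites = sum(codon_syn_fraction(c) for c in ancestor)
        n_sites = 3.0 * spec.n_codons - s_sites
        n_syn = int(rng.poisson(spec.target_ks * s_sites))
        n_nonsyn = int(rng.poisson(spec.target_ka * n_sites))
        lineages = {"a": list(ancestor), "b": list(ancestor)}
        events = [(True, "a" if rng.random() < 0.5 else "b") for _ in range(n_syn)]
        events += [(False, "a" if rng.random() < 0.5 else "b") for _ in range(n_nonsyn)]
        events = [events[int(i)] for i in rng.permutation(len(events))]
        log = []
        try:
            for synonymous, lineage in events:
                ci, pos, old, new = _place_event(lineages[lineage], synonymous, rng)
                log.append(
                    {"lineage": lineage, "codon": ci, "position": pos,
                     "from": old, "to": new, "synonymous": bool(synonymous)}
                )
        except RuntimeError:
            continue
        cds_a = "".join(lineages["a"])
        cds_b = "".join(lineages["b"])
        truth = {
            "ancestor": "".join(ancestor),
            "s_sites_ancestor": s_sites,
            "n_sites_ancestor": n_sites,
            "n_synonymous_events": n_syn,
            "n_nonsynonymous_events": n_nonsyn,
            "events": log,
        }
        return CodonPairSim(
            cds_a=SequenceRecord("sim_a", "simulated CDS", cds_a),
            cds_b=SequenceRecord("sim_b", "simulated CDS", cds_b),
            protein_a=SequenceRecord("sim_a", "", translate_cds(cds_a)),
            protein_b=SequenceRecord("sim_b", "", translate_cds(cds_b)),
            truth=truth,
        )
    raise ValueError("could not place the requested events in 100 attempts")


# ---------------------------------------------------------------------------
# qPCR CT tables


def simulate_ct_table(
    design: dict[str, dict[str, float]],
    noise_sd_cycles: float = 0.1,
    rng_seed: int = 42,
    reference: str = "UBQ",
    baseline_offset: float = 2.0,
    n_bio: int = 3,
    n_tech: int = 3,
) -> pd.DataFrame:
    """CT table for ``design[gene][sample] = fold`` (fold 1 in the control).

    Reference CT is 20 plus Gaussian cycle noise; each target CT is the
    matching reference draw plus a baseline offset minus log2(fold) plus
    its own noise, so with zero noise the 2^-ddCT estimate returns the
    designed fold exactly."""
    if noise_sd_cycles < 0:
        raise ValueError("noise_sd_cycles must be >= 0")
    if not design:
        raise ValueError("empty design")
    rng = np.random.default_rng(rng_seed)
    samples: list[str] = sorted({s for gene in design.values() for s in gene})
    rows = []
    for sample in samples:
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                ref_ct = 20.0 + rng.normal(0.0, noise_sd_cycles) if noise_sd_cycles else 20.0
                rows.append(
                    {"sample": sample, "gene": reference, "replicate_bio": bio,
                     "replicate_tech": tech, "ct": ref_ct}
                )
                for gene, folds in sorted(design.items()):
                    if sample not in folds:
                        continue
                    fold = folds[sample]
                    if fold <= 0:
                        raise ValueError(f"fold for {gene!r} in {sample!r} must be > 0")
                    noise = rng.normal(0.0, noise_sd_cycles) if noise_sd_cycles else 0.0
                    rows.append(
                        {"sample": sample, "gene": gene, "replicate_bio": bio,
                         "replicate_tech": tech,
                         "ct": ref_ct + baseline_offset - math.log2(fold) + noise}
                    )
    return pd.DataFrame(rows)
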