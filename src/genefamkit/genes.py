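"""Gene models, chromosome gene ordering, and genomic distance utilities.

Coordinates are 1-based inclusive throughout (GFF3 convention). Exon
intervals include UTR exons; coding sequence is only consulted by the
Ka/Ks machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneModel:
    """One annotated gene: location, strand, and its ordered exons."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    is_transposon: bool = False

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have at least one exon")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start {s} > end {e}")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: exon [{s}, {e}] outside gene span "
                    f"[{self.start}, {self.end}]"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons at {s}")
            prev_end = e


@dataclass
class ChromosomeMap:
    """Genes of one chromosome in positional order, with ordinal ranks."""

    chromosome: str
    ordered_gene_ids: list[str]
    rank: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_models(cls, models: list[GeneModel], chromosome: str | None = None) -> "ChromosomeMap":
        if chromosome is None:
            chroms = {m.chromosome for m in models}
            if len(chroms) != 1:
                raise ValueError(f"models span several chromosomes: {sorted(chroms)}")
            chromosome = chroms.pop()
        on_chrom = [m for m in models if m.chromosome == chromosome]
        if not on_chrom:
            raise ValueError(f"no genes on chromosome {chromosome!r}")
        # strictly by start; ties broken by end, then id, so ranks are total
        on_chrom.sort(key=lambda m: (m.start, m.end, m.gene_id))
        ids = [m.gene_id for m in on_chrom]
        return cls(chromosome, ids, {g: i for i, g in enumerate(ids)})

    def __post_init__(self) -> None:
        if not self.rank:
            self.rank = {g: i for i, g in enumerate(self.ordered_gene_ids)}

    def window(self, gene_id: str, half_width: int) -> list[str]:
        """Gene ids within ``half_width`` ranks of ``gene_id`` (inclusive of
        the gene itself), truncated at chromosome ends."""
        r = self.rank[gene_id]
        lo = max(0, r - half_width)
        hi = min(len(self.ordered_gene_ids), r + half_width + 1)
        return self.ordered_gene_ids[lo:hi]


def build_maps(models: list[GeneModel]) -> dict[str, ChromosomeMap]:
    """One ChromosomeMap per chromosome present in ``models``."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    return {c: ChromosomeMap.from_models(ms, c) for c, ms in by_chrom.items()}


def exon_count(gene: GeneModel) -> int:
    return len(gene.exons)


def exon_diff(pair: tuple[GeneModel, GeneModel]) -> int:
    """Signed exon-count difference, first minus second. Positive values mean
    the second gene has fewer exons (e.g. a lineage-specific intron-exon
    loss)."""
    a, b = pair
    return exon_count(a) - exon_count(b)


def intergenic_gap_bp(a: GeneModel, b: GeneModel) -> int:
    """Base pairs separating two genes on the same chromosome: start of the
    downstream gene minus end of the upstream one (end-exclusive, so adjacent
    intervals [1,10] and [11,20] are 1 bp apart). Overlapping genes -> 0."""
    if a.chromosome != b.chromosome:
        raise ValueError(
            f"{a.gene_id} ({a.chromosome}) and {b.gene_id} ({b.chromosome}) "
            "are on different chromosomes"
        )
    up, down = (a, b) if a.start <= b.start else (b, a)
    return max(0, down.start - up.end)


def intervening_gene_count(a: GeneModel | str, b: GeneModel | str, cmap: ChromosomeMap) -> int:
    """Number of genes strictly between ``a`` and ``b`` in map order."""
    ida = a if isinstance(a, str) else a.gene_id
    idb = b if isinstance(b, str) else b.gene_id
    for g in (ida, idb):
        if g not in cmap.rank:
            raise KeyError(f"gene {g!r} not on chromosome map {cmap.chromosome!r}")
    return abs(cmap.rank[ida] - cmap.rank[idb]) - 1
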