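"""Microsynteny detection around anchor genes and relative syntenic quality.

A syntenic block is declared when, within a window of ``window_genes``
genes upstream and downstream of each anchor (31 genes per window at the
default 15), at least ``min_conserved_pairs`` conserved homolog pairs are
found — the anchor pair itself counts toward that threshold. Conserved
pairs are a greedy one-to-one matching of window genes over the filtered
homology table, strongest scores first.

Relative syntenic quality of a block is the percentage of window genes
that take part in conserved pairs, 100 * 2*m / (Na + Nb), after excluding
transposon-flagged genes from the denominators and collapsing tandem runs
(consecutive window genes homologous to each other within the tandem span)
to a single gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .config import RunConfig
from .genes import ChromosomeMap, GeneModel, build_maps, intergenic_gap_bp
from .io import HomologyTable


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (printed tables round 0.005 upward)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(round(float(x), ndigits + 4))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Genome:
    """Gene models of one genome, indexed by id and by chromosome order."""

    label: str
    models: dict[str, GeneModel]
    maps: dict[str, ChromosomeMap]

    @classmethod
    def from_models(cls, label: str, models: list[GeneModel]) -> "Genome":
        if not models:
            raise ValueError(f"genome {label!r}: no gene models")
        by_id = {m.gene_id: m for m in models}
        if len(by_id) != len(models):
            raise ValueError(f"genome {label!r}: duplicate gene ids")
        return cls(label, by_id, build_maps(models))

    def map_of(self, gene_id: str) -> ChromosomeMap:
        if gene_id not in self.models:
            raise KeyError(f"gene {gene_id!r} not in genome {self.label!r}")
        return self.maps[self.models[gene_id].chromosome]


@dataclass
class AnchorPair:
    gene_a: str
    gene_b: str
    genome_a: str
    genome_b: str

    def __post_init__(self) -> None:
        if self.genome_a == self.genome_b and self.gene_a == self.gene_b:
            raise ValueError("intragenome anchor pair must join two distinct genes")


@dataclass
class SyntenyBlock:
    anchor: AnchorPair
    window_a: list[str]
    window_b: list[str]
    conserved_pairs: list[tuple[str, str]]
    quality_pct: float = float("nan")
    species_pair: str = ""
    clade: str = ""

    @property
    def n_conserved(self) -> int:
        return len(self.conserved_pairs)


def detect_block(
    anchor: AnchorPair,
    genome_a: Genome,
    genome_b: Genome,
    homology: HomologyTable,
    cfg: RunConfig | None = None,
) -> SyntenyBlock | None:
    """Detect a microsyntenic block anchored at ``anchor``; None when fewer
    than ``cfg.min_conserved_pairs`` conserved pairs (anchor included) are
    found. Windows are rank +/- ``window_genes`` on each chromosome map,
    truncated at chromosome ends."""
    cfg = cfg or RunConfig()
    window_a = genome_a.map_of(anchor.gene_a).window(anchor.gene_a, cfg.window_genes)
    window_b = genome_b.map_of(anchor.gene_b).window(anchor.gene_b, cfg.window_genes)
    set_b = set(window_b)

    candidates = []
    for x in window_a:
        if x == anchor.gene_a:
            continue
        for row in homology.entries_for(x):
            y = row.gene_b if row.gene_a == x else row.gene_a
            if y == anchor.gene_b or y not in set_b or y == x:
                continue
            candidates.append((-row.score, *sorted((x, y)), x, y))
    candidates.sort()

    used_a = {anchor.gene_a}
    used_b = {anchor.gene_b}
    pairs: list[tuple[str, str]] = [(anchor.gene_a, anchor.gene_b)]
    for _, _, _, x, y in candidates:
        if x in used_a or y in used_b:
            continue
        used_a.add(x)
        used_b.add(y)
        pairs.append((x, y))
    if len(pairs) < cfg.min_conserved_pairs:
        return None
    return SyntenyBlock(anchor, window_a, window_b, pairs)


def _effective_window_size(
    window: list[str],
    genome: Genome,
    homology: HomologyTable,
    cfg: RunConfig,
) -> int:
    """Window gene count after dropping transposon-flagged genes and
    collapsing consecutive tandem-duplicated genes (mutual homologs within
    the tandem span) to one."""
    kept: list[str] = []
    for gid in window:
        model = genome.models[gid]
        if model.is_transposon:
            continue
        if kept:
            prev = genome.models[kept[-1]]
            if (
                prev.chromosome == model.chromosome
                and homology.are_homologs(prev.gene_id, gid)
                and intergenic_gap_bp(prev, model) <= cfg.tandem_max_span_bp
            ):
                continue  # same tandem run as the previous kept gene
        kept.append(gid)
    return len(kept)


def synteny_quality(
    block: SyntenyBlock,
    genome_a: Genome,
    genome_b: Genome,
    homology: HomologyTable,
    cfg: RunConfig | None = None,
) -> float:
    """Relative syntenic quality in percent; also stored on the block."""
    cfg = cfg or RunConfig()
    na = _effective_window_size(block.window_a, genome_a, homology, cfg)
    nb = _effective_window_size(block.window_b, genome_b, homology, cfg)
    if na + nb == 0:
        raise ValueError("empty effective windows: quality undefined")
    block.quality_pct = 100.0 * (2.0 * block.n_conserved) / (na + nb)
    return block.quality_pct


@dataclass
class QualitySummary:
    """Aggregation of per-block qualities: species-pair x clade means, the
    per-pair mean of clade means, and the overall mean of pair means.
    Values are kept unrounded; ``table()`` renders the 2-decimal view."""

    clade_means: pd.DataFrame
    pair_means: pd.Series
    overall: float

    def table(self) -> pd.DataFrame:
        out = self.clade_means.copy()
        out["average"] = self.pair_means
        return out.map(lambda v: round_half_up(v) if pd.notna(v) else v)

    @property
    def overall_rounded(self) -> float:
        return round_half_up(self.overall)


def summarize_quality(records) -> QualitySummary:
    """Aggregate quality percentages grouped by species pair and clade.

    ``records`` is a DataFrame (or convertible) with columns species_pair,
    clade, quality_pct — one row per block (or per published clade-level
    value). Empty groups are omitted, never counted as zero."""
    df = pd.DataFrame(records)
    required = {"species_pair", "clade", "quality_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if df.empty:
        raise ValueError("no quality records to summarize")
    clade_means = (
        df.groupby(["species_pair", "clade"])["quality_pct"].mean().unstack("clade")
    )
    pair_means = clade_means.mean(axis=1, skipna=True)
    overall = float(pair_means.mean())
    return QualitySummary(clade_means, pair_means, overall)
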