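"""Classification of duplicate gene pairs as tandem or segmental.

Tandem: the two genes sit on the same chromosome, separated by at most
``tandem_max_intervening`` genes (default 5) AND by at most
``tandem_max_span_bp`` (default 100 kb) of intergenic distance — the two
conditions are conjunctive. Segmental (large-scale) duplication: at least
``segmental_min_flanking_pairs`` (default 5) flanking gene pairs around
the anchor point are each other's best non-self homology match (either
direction suffices). Tandem takes precedence: segmental evidence is only
consulted for non-tandem pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig
from .genes import intergenic_gap_bp, intervening_gene_count
from .io import HomologyTable
from .synteny import AnchorPair, Genome


@dataclass
class DuplicationCall:
    gene_a: str
    gene_b: str
    mode: str  # tandem | segmental | unclassified
    intervening_genes: int | None = None
    span_bp: int | None = None
    n_flanking_pairs: int | None = None


def classify_tandem(
    a: str, b: str, genome: Genome, cfg: RunConfig | None = None
) -> tuple[bool, dict]:
    """Conjunctive tandem test with evidence; genes on different
    chromosomes are simply not tandem."""
    cfg = cfg or RunConfig()
    ma, mb = genome.models[a], genome.models[b]
    if ma.chromosome != mb.chromosome:
        return False, {"intervening_genes": None, "span_bp": None}
    cmap = genome.maps[ma.chromosome]
    intervening = intervening_gene_count(a, b, cmap)
    span = intergenic_gap_bp(ma, mb)
    ok = intervening <= cfg.tandem_max_intervening and span <= cfg.tandem_max_span_bp
    return ok, {"intervening_genes": intervening, "span_bp": span}


def best_nonself_match(gene: str, homology: HomologyTable) -> str | None:
    """Partner with the lowest significance (ties: highest score, then
    smallest id); None when the gene has no homology entries."""
    best: tuple | None = None
    for row in homology.entries_for(gene):
        partner = row.gene_b if row.gene_a == gene else row.gene_a
        key = (row.significance, -row.score, partner)
        if best is None or key < best[0]:
            best = (key, partner)
    return None if best is None else best[1]


def detect_segmental(
    anchor: AnchorPair,
    genome_a: Genome,
    genome_b: Genome,
    homology: HomologyTable,
    cfg: RunConfig | None = None,
) -> tuple[bool, dict]:
    """Count flanking (non-anchor) gene pairs across the two anchor windows
    where either gene's best non-self match is the other, each gene used at
    most once; segmental iff the count reaches
    ``segmental_min_flanking_pairs``."""
    cfg = cfg or RunConfig()
    window_a = genome_a.map_of(anchor.gene_a).window(anchor.gene_a, cfg.window_genes)
    window_b = genome_b.map_of(anchor.gene_b).window(anchor.gene_b, cfg.window_genes)
    set_a = set(window_a) - {anchor.gene_a}
    set_b = set(window_b) - {anchor.gene_b}

    candidates = []
    for x in set_a:
        for row in homology.entries_for(x):
            y = row.gene_b if row.gene_a == x else row.gene_a
            if y not in set_b or y == x:
                continue
            if best_nonself_match(x, homology) == y or best_nonself_match(y, homology) == x:
                candidates.append((-row.score, *sorted((x, y)), x, y))
    candidates.sort()

    used_a: set[str] = set()
    used_b: set[str] = set()
    n_pairs = 0
    for _, _, _, x, y in candidates:
        if x in used_a or y in used_b:
            continue
        used_a.add(x)
        used_b.add(y)
        n_pairs += 1
    return n_pairs >= cfg.segmental_min_flanking_pairs, {"n_flanking_pairs": n_pairs}


def classify_pair(
    a: str,
    b: str,
    genome_a: Genome,
    genome_b: Genome,
    homology: HomologyTable,
    cfg: RunConfig | None = None,
) -> DuplicationCall:
    """Tandem first (intragenome only), then segmental, else unclassified."""
    cfg = cfg or RunConfig()
    evidence: dict = {}
    if genome_a.label == genome_b.label:
        tandem, evidence = classify_tandem(a, b, genome_a, cfg)
        if tandem:
            return DuplicationCall(a, b, "tandem", **evidence)
    anchor = AnchorPair(a, b, genome_a.label, genome_b.label)
    segmental, seg_ev = detect_segmental(anchor, genome_a, genome_b, homology, cfg)
    mode = "segmental" if segmental else "unclassified"
    return DuplicationCall(a, b, mode, **evidence, **seg_ev)
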