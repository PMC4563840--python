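"""Nei-Gojobori (1986) Ka/Ks estimation, codon back-translation, sliding
windows, selection classification, and synonymous-clock dating.

The NG86 counting method works per codon: each of the three positions
contributes a synonymous-site fraction equal to the share of its three
possible nucleotide changes that are synonymous (changes creating a stop
codon count as neither); S is that total averaged over the two sequences
and N = 3L - S. Observed differences between codons differing at 1-3
positions are averaged with equal weight over all mutational pathways that
avoid stop codons. The resulting proportions ps = Sd/S and pn = Nd/N are
corrected for multiple hits with the Jukes-Cantor formula
d = -(3/4) ln(1 - (4/3) p), undefined (saturated) at p >= 3/4.

Under a synonymous molecular clock with rate r substitutions per
synonymous site per year, a duplication with mean flanking Ks dates to
T = Ks / (2 r) years; Ks above ``ks_max`` (default 2.0) is considered
saturated and excluded from dating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .io import GAP, SequenceRecord
from .phylo import Alignment

NT = "ACGT"
SENSE_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.forward_table))
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_AA = dict(standard_dna_table.forward_table)


def _aa(codon: str) -> str | None:
    return _AA.get(codon)


# ---------------------------------------------------------------------------
# Codon alignments


@dataclass
class CodonAlignment:
    """Two gap-aligned nucleotide sequences whose gap runs respect codon
    boundaries; stripping gaps and translating reproduces the proteins the
    alignment was derived from."""

    rows: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.rows) != 2:
            raise ValueError("codon alignment holds exactly 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("codon alignment rows differ in length")
        if self.length_bp % 3:
            raise ValueError("codon alignment length not divisible by 3")
        for r in self.rows:
            for i in range(0, len(r.residues), 3):
                codon = r.residues[i : i + 3]
                ngap = codon.count(GAP)
                if ngap not in (0, 3):
                    raise ValueError(
                        f"{r.id}: gap run not a codon multiple at position {i + 1}"
                    )

    @property
    def length_bp(self) -> int:
        return len(self.rows[0])

    @property
    def n_codons(self) -> int:
        return self.length_bp // 3

    def codon_pairs(self) -> list[tuple[str, str]]:
        a, b = self.rows[0].residues, self.rows[1].residues
        return [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]

    def slice_codons(self, start: int, end: int) -> "CodonAlignment":
        rows = [
            SequenceRecord(r.id, r.description, r.residues[start * 3 : end * 3], aligned=True)
            for r in self.rows
        ]
        return CodonAlignment(rows)


def backtranslate(
    protein_aln: Alignment, cds_a: SequenceRecord, cds_b: SequenceRecord
) -> CodonAlignment:
    """Thread each CDS onto its row of a 2-row protein alignment: every
    amino-acid column expands to its source codon and every gap to '---'.
    A trailing stop codon on a CDS is trimmed; any translation mismatch is
    an error naming the codon index."""
    if len(protein_aln.records) != 2:
        raise ValueError("backtranslate expects a 2-row protein alignment")
    out_rows: list[SequenceRecord] = []
    for prot_row, cds in zip(protein_aln.records, (cds_a, cds_b)):
        cds_seq = cds.residues.upper().replace("U", "T")
        if len(cds_seq) % 3:
            raise ValueError(f"{cds.id}: CDS length {len(cds_seq)} not divisible by 3")
        codons = [cds_seq[i : i + 3] for i in range(0, len(cds_seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        protein = prot_row.ungapped()
        if len(codons) != len(protein):
            raise ValueError(
                f"{cds.id}: CDS codes for {len(codons)} residues but protein row "
                f"{prot_row.id!r} has {len(protein)}"
            )
        built = []
        idx = 0
        for col, aa in enumerate(prot_row.residues):
            if aa == GAP:
                built.append(GAP * 3)
                continue
            codon = codons[idx]
            translated = _aa(codon)
            if translated is None:
                raise ValueError(f"{cds.id}: internal stop codon at codon {idx + 1}")
            if aa != "X" and translated != aa:
                raise ValueError(
                    f"{cds.id}: codon {idx + 1} ({codon}) translates to "
                    f"{translated}, protein row has {aa}"
                )
            built.append(codon)
            idx += 1
        out_rows.append(SequenceRecord(cds.id, cds.description, "".join(built), aligned=True))
    return CodonAlignment(out_rows)


# ---------------------------------------------------------------------------
# NG86 counting


def codon_syn_fraction(codon: str) -> float:
    """Synonymous-site count of a sense codon: per position, the fraction of
    its three single-nucleotide changes that are synonymous (stop-creating
    changes count as neither synonymous nor nonsynonymous)."""
    if codon in STOP_CODONS or codon not in _AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        for nt in NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            if _aa(alt) == _aa(codon):
                s += 1.0 / 3.0
    return s


_PATH_CACHE: dict[tuple[str, str], tuple[float, float] | None] = {}


def pathway_differences(c1: str, c2: str) -> tuple[float, float] | None:
    """Synonymous/nonsynonymous difference counts between two sense codons,
    averaged with equal weight over all mutational orderings that avoid stop
    codons; None when every pathway is blocked."""
    key = (c1, c2)
    if key in _PATH_CACHE:
        return _PATH_CACHE[key]
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        _PATH_CACHE[key] = (0.0, 0.0)
        return 0.0, 0.0
    tot_s = tot_n = 0.0
    n_paths = 0
    for order in permutations(positions):
        cur = c1
        s = nsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                s += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            tot_s += s
            tot_n += nsyn
            n_paths += 1
    result = None if n_paths == 0 else (tot_s / n_paths, tot_n / n_paths)
    _PATH_CACHE[key] = result
    return result


def jukes_cantor(p: float) -> float:
    """JC multiple-hit correction; nan at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsEstimate:
    ka: float
    ks: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    saturated: bool
    label: str = ""

    @property
    def ratio(self) -> float:
        """Ka/Ks; nan when undefined (Ks zero or saturated)."""
        if math.isnan(self.ks) or math.isnan(self.ka) or self.ks == 0:
            return float("nan")
        return self.ka / self.ks


def ng86(codon_aln: CodonAlignment, ks_max: float = 2.0) -> KaKsEstimate:
    """NG86 Ka/Ks for a pairwise codon alignment.

    Codon pairs with a gap or stop codon in either row, or whose mutational
    pathways are all blocked by stops, are excluded from both sites and
    differences. Raises when no comparable codon pair remains.
    """
    S = sd = nd = 0.0
    comparable = 0
    for c1, c2 in codon_aln.codon_pairs():
        if GAP in c1 or GAP in c2:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        path = pathway_differences(c1, c2)
        if path is None:
            continue
        S += (codon_syn_fraction(c1) + codon_syn_fraction(c2)) / 2.0
        sd += path[0]
        nd += path[1]
        comparable += 1
    if comparable == 0:
        raise ValueError("no comparable codon pairs in alignment")
    N = 3.0 * comparable - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = math.isnan(ks) or math.isnan(ka) or ks > ks_max
    label = f"{codon_aln.rows[0].id}/{codon_aln.rows[1].id}"
    return KaKsEstimate(
        ka=ka, ks=ks, n_sites=N, s_sites=S, nd=nd, sd=sd, saturated=saturated, label=label
    )


def sliding_window_kaks(
    codon_aln: CodonAlignment,
    window_bp: int = 150,
    step_bp: int = 9,
    ks_max: float = 2.0,
) -> pd.DataFrame:
    """Per-window NG86 estimates along the alignment.

    Window and step are given in bp and snapped down to whole codons
    (150 bp -> 50 codons, 9 bp -> 3 codons). Windows advance until one
    reaches the alignment end; the last window is truncated there, and a
    window longer than the alignment degenerates to a single full-length
    window. Undefined values are reported as NaN (missing), never 0.
    Columns: start_bp, end_bp (1-based alignment coordinates), ka, ks,
    ratio.
    """
    win = max(1, window_bp // 3)
    step = max(1, step_bp // 3)
    total = codon_aln.n_codons
    rows = []
    start = 0
    while True:
        end = min(start + win, total)
        try:
            est = ng86(codon_aln.slice_codons(start, end), ks_max=ks_max)
            ka, ks, ratio = est.ka, est.ks, est.ratio
        except ValueError:
            ka = ks = ratio = float("nan")
        rows.append(
            {"start_bp": start * 3 + 1, "end_bp": end * 3, "ka": ka, "ks": ks, "ratio": ratio}
        )
        if end >= total:
            break
        start += step
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Selection and dating


def classify_selection(estimate: KaKsEstimate | float, tol: float = 1e-9) -> str:
    """'purifying' (ratio < 1), 'neutral' (= 1 within tol), or 'positive'."""
    ratio = estimate.ratio if isinstance(estimate, KaKsEstimate) else float(estimate)
    if math.isnan(ratio):
        raise ValueError("Ka/Ks ratio undefined; cannot classify selection")
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


def date_from_ks(ks: float, clock_rate: float = 9.1e-9, ks_max: float = 2.0) -> float:
    """Divergence time in Mya from a synonymous distance:
    T = Ks / (2 r) / 1e6 with r in substitutions/site/year."""
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    if ks > ks_max:
        raise ValueError(f"saturated: Ks {ks} exceeds {ks_max}")
    return ks / (2.0 * clock_rate) / 1e6


@dataclass
class BlockDate:
    label: str
    n_flanking: int
    mean_ks: float
    sd_ks: float
    mean_kaks: float
    sd_kaks: float
    date_mya: float
    sd_defined: bool


def date_block(
    flanking_estimates: list[KaKsEstimate],
    label: str = "",
    clock_rate: float = 9.1e-9,
    ks_max: float = 2.0,
) -> BlockDate:
    """Date a duplicated block from its conserved flanking gene pairs:
    mean/SD of the unsaturated flanking Ks (and of the defined Ka/Ks
    ratios), then the clock applied to the mean Ks. SD is the sample SD
    (n-1); with a single estimate it is reported as 0 and flagged."""
    usable = [
        e
        for e in flanking_estimates
        if not math.isnan(e.ks) and e.ks <= ks_max and not math.isnan(e.ka)
    ]
    if not usable:
        raise ValueError(f"{label or 'block'}: all flanking estimates are saturated")
    ks_vals = np.array([e.ks for e in usable])
    ratios = np.array([e.ratio for e in usable])
    ratios = ratios[~np.isnan(ratios)]
    sd_defined = len(ks_vals) > 1
    return BlockDate(
        label=label,
        n_flanking=len(usable),
        mean_ks=float(ks_vals.mean()),
        sd_ks=float(ks_vals.std(ddof=1)) if sd_defined else 0.0,
        mean_kaks=float(ratios.mean()) if len(ratios) else float("nan"),
        sd_kaks=float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        date_mya=date_from_ks(float(ks_vals.mean()), clock_rate, ks_max),
        sd_defined=sd_defined,
    )


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (helper for generators and validation)."""
    return str(Seq(cds.replace("-", "")).translate())
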