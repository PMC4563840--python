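"""Physical properties of proteins: length, average molecular weight, and
isoelectric point (pI), plus family-level summaries.

Molecular weight is the sum of average (not monoisotopic) residue masses
plus one water. The pI is the pH at which the net Henderson-Hasselbalch
charge over the termini and the ionizable side chains (D, E, C, Y, H, K, R)
vanishes, located by bisection on [0, 14]. The default pKa set is the
EMBOSS one; pass another mapping to use e.g. Bjellqvist constants —
published tools differ by ~0.1 pH unit, so printed reference values should
be compared as printed, not recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import SequenceRecord

# Average residue (amino acid minus water) masses in daltons.
AVERAGE_RESIDUE_MASS_DA: dict[str, float] = {
    "A": 71.07880, "R": 156.18748, "N": 114.10384, "D": 115.08860,
    "C": 103.13880, "E": 129.11548, "Q": 128.13072, "G": 57.05192,
    "H": 137.14108, "I": 113.15944, "L": 113.15944, "K": 128.17408,
    "M": 131.19256, "F": 147.17656, "P": 97.11668, "S": 87.07820,
    "T": 101.10508, "W": 186.21320, "Y": 163.17596, "V": 99.13256,
}
WATER_MASS_DA = 18.01524

# EMBOSS pKa values; "nterm"/"cterm" are the free termini.
EMBOSS_PKA: dict[str, float] = {
    "nterm": 8.6, "cterm": 3.6,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    "H": 6.5, "K": 10.8, "R": 12.5,
}
ACIDIC_GROUPS = ("cterm", "D", "E", "C", "Y")
BASIC_GROUPS = ("nterm", "H", "K", "R")


@dataclass
class ProteinProps:
    gene_id: str
    length_aa: int
    mol_wt_da: float
    pi: float
    acidity: str = ""

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise ValueError(f"{self.gene_id}: length_aa must be >= 1")
        if self.mol_wt_da <= 0:
            raise ValueError(f"{self.gene_id}: mol_wt_da must be positive")
        if not 0 < self.pi < 14:
            raise ValueError(f"{self.gene_id}: pi must be in (0, 14)")
        self.acidity = "alkaline" if self.pi > 7 else "acidic"


def _check_residues(seq: str, where: str) -> str:
    seq = seq.upper()
    for pos, aa in enumerate(seq, start=1):
        if aa not in AVERAGE_RESIDUE_MASS_DA:
            raise ValueError(f"{where}: unknown residue {aa!r} at position {pos}")
    return seq


def compute_mol_wt(protein: SequenceRecord | str) -> float:
    """Average molecular weight in daltons: residue masses plus one water."""
    seq, name = (protein, "sequence") if isinstance(protein, str) else (protein.residues, protein.id)
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = _check_residues(seq, name)
    return sum(AVERAGE_RESIDUE_MASS_DA[aa] for aa in seq) + WATER_MASS_DA


def net_charge(seq: str, ph: float, pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Net Henderson-Hasselbalch charge at a given pH (composition only)."""
    counts = {g: seq.count(g) for g in "DECYHKR"}
    counts["nterm"] = counts["cterm"] = 1
    pos = sum(
        counts.get(g, 0) / (1.0 + 10.0 ** (ph - pka[g])) for g in BASIC_GROUPS
    )
    neg = sum(
        counts.get(g, 0) / (1.0 + 10.0 ** (pka[g] - ph)) for g in ACIDIC_GROUPS
    )
    return pos - neg


def compute_pi(
    protein: SequenceRecord | str, pka: Mapping[str, float] = EMBOSS_PKA
) -> float:
    """pH of zero net charge, by bisection to |charge| < 1e-4 or an interval
    narrower than 1e-4. Net charge is monotone decreasing in pH."""
    seq, name = (protein, "sequence") if isinstance(protein, str) else (protein.residues, protein.id)
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = _check_residues(seq, name)
    lo, hi = 0.0, 14.0
    while hi - lo >= 1e-4:
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid, pka)
        if abs(q) < 1e-4:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def compute_props(protein: SequenceRecord, pka: Mapping[str, float] = EMBOSS_PKA) -> ProteinProps:
    return ProteinProps(
        gene_id=protein.id,
        length_aa=len(protein.ungapped()),
        mol_wt_da=compute_mol_wt(protein),
        pi=compute_pi(protein, pka),
    )


def summarize_props(props: Iterable[ProteinProps]) -> dict:
    """Family-level summary: length and molecular-weight extrema (with the
    gene ids attaining them), means, and the count of alkaline (pI > 7)
    proteins. Molecular-weight extrema are also reported in kDa rounded to
    one decimal."""
    props = list(props)
    if not props:
        raise ValueError("summarize_props: empty property list")
    by_len_min = min(props, key=lambda p: p.length_aa)
    by_len_max = max(props, key=lambda p: p.length_aa)
    by_mw_min = min(props, key=lambda p: p.mol_wt_da)
    by_mw_max = max(props, key=lambda p: p.mol_wt_da)
    n = len(props)
    return {
        "n": n,
        "length_min_aa": by_len_min.length_aa,
        "length_min_gene": by_len_min.gene_id,
        "length_max_aa": by_len_max.length_aa,
        "length_max_gene": by_len_max.gene_id,
        "length_mean_aa": sum(p.length_aa for p in props) / n,
        "mol_wt_min_da": by_mw_min.mol_wt_da,
        "mol_wt_min_gene": by_mw_min.gene_id,
        "mol_wt_max_da": by_mw_max.mol_wt_da,
        "mol_wt_max_gene": by_mw_max.gene_id,
        "mol_wt_mean_da": sum(p.mol_wt_da for p in props) / n,
        "mol_wt_min_kda": round(by_mw_min.mol_wt_da / 1000.0, 1),
        "mol_wt_max_kda": round(by_mw_max.mol_wt_da / 1000.0, 1),
        "n_alkaline": sum(1 for p in props if p.pi > 7),
    }
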