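"""Readers and writers for the external formats the pipeline consumes.

FASTA (plain and aligned) is handled through Bio.SeqIO; GFF3 through
gffutils (with a pre-validation pass so malformed lines are reported by
number); homology score tables through pandas; newick through the tree
classes in :mod:`genefamkit.phylo` (dendropy on the read side).

Every reader rejects an empty file with an explicit error rather than
silently returning an empty collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .genes import GeneModel

PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_LETTERS = set("ACGTUN")
GAP = "-"

# GFF3 attribute values that mark a gene as a mobile element; genes so
# flagged are excluded from syntenic-quality denominators.
TRANSPOSON_KEYWORDS = ("transposon", "retrotransposon", "transposable_element")


class ParseError(ValueError):
    """Malformed input file content."""


@dataclass
class SequenceRecord:
    """A named protein or nucleotide sequence (possibly aligned)."""

    id: str
    description: str = ""
    residues: str = ""
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


def _validate_protein(rec: SequenceRecord) -> None:
    allowed = PROTEIN_LETTERS | {"X"} | ({GAP} if rec.aligned else set())
    bad = set(rec.residues.upper()) - allowed
    if bad:
        raise ParseError(f"{rec.id}: non-protein letters {sorted(bad)}")


def read_fasta(
    path: str | Path, alphabet: str = "protein", aligned: bool = False
) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords; ids must be unique within the file."""
    path = Path(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        raise ParseError(f"empty FASTA file: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for sr in SeqIO.parse(str(path), "fasta"):
        if sr.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {sr.id!r}")
        seen.add(sr.id)
        rec = SequenceRecord(
            id=sr.id,
            description=sr.description[len(sr.id):].strip(),
            residues=str(sr.seq).upper(),
            aligned=aligned,
        )
        if alphabet == "protein":
            _validate_protein(rec)
        records.append(rec)
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    if aligned and len({len(r) for r in records}) > 1:
        raise ParseError(f"{path}: aligned FASTA rows differ in length")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _flag_transposon(attributes: dict) -> bool:
    for key in ("biotype", "Note", "note"):
        for val in attributes.get(key, []):
            low = val.lower()
            if any(kw in low for kw in TRANSPOSON_KEYWORDS):
                return True
    return False


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features into GeneModels.

    When a gene carries several mRNAs, the exons of the lexicographically
    first mRNA id are used (a deterministic stand-in for a primary
    transcript). A gene whose chosen transcript has no exon features is a
    validation error.
    """
    import gffutils

    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"empty GFF3 file: {path}")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        ncols = len(line.split("\t"))
        if ncols != 9:
            raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns, got {ncols}")

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: f.id)
        parent = mrnas[0] if mrnas else gene
        exons = sorted(
            (f.start, f.end) for f in db.children(parent, featuretype="exon")
        )
        if not exons:
            raise ParseError(f"{path}: gene {gene.id!r} has no exon features")
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons,
                is_transposon=_flag_transposon(dict(gene.attributes)),
            )
        )
    if not models:
        raise ParseError(f"{path}: no gene features found")
    return models


# ---------------------------------------------------------------------------
# Homology tables


@dataclass
class HomologyTable:
    """Scored gene-gene similarity relation.

    One entry per unordered pair, no self pairs; ``significance`` is an
    E-value-like quantity (smaller = stronger support).
    """

    entries: pd.DataFrame  # columns: gene_a, gene_b, score, significance
    _by_gene: dict = field(default_factory=dict, repr=False)

    COLUMNS = ("gene_a", "gene_b", "score", "significance")

    def __post_init__(self) -> None:
        df = self.entries
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"homology table missing columns: {sorted(missing)}")
        if (df["gene_a"] == df["gene_b"]).any():
            raise ValueError("homology table contains self pairs")
        self.entries = df.reset_index(drop=True)
        self._index()

    def _index(self) -> None:
        self._by_gene = {}
        for row in self.entries.itertuples(index=False):
            self._by_gene.setdefault(row.gene_a, []).append(row)
            self._by_gene.setdefault(row.gene_b, []).append(row)

    def __len__(self) -> int:
        return len(self.entries)

    def entries_for(self, gene: str) -> list:
        return self._by_gene.get(gene, [])

    def get(self, a: str, b: str):
        """The entry for an unordered pair, or None."""
        for row in self._by_gene.get(a, []):
            if row.gene_a == b or row.gene_b == b:
                return row
        return None

    def are_homologs(self, a: str, b: str) -> bool:
        return a != b and self.get(a, b) is not None

    @classmethod
    def from_records(cls, records, significance_cutoff: float = float("inf")) -> "HomologyTable":
        """Build from (gene_a, gene_b, score, significance) tuples, applying
        the read-time rules: drop self pairs and entries at or above the
        significance cutoff (strict ``<`` keeps a row); collapse duplicate
        unordered pairs keeping lowest significance, ties by highest score."""
        best: dict[frozenset, tuple] = {}
        for ga, gb, score, sig in records:
            score = float(score)
            sig = float(sig)
            if score < 0 or sig < 0:
                raise ValueError(f"negative score/significance for pair ({ga}, {gb})")
            if ga == gb or not sig < significance_cutoff:
                continue
            key = frozenset((ga, gb))
            cur = best.get(key)
            if cur is None or (sig, -score) < (cur[3], -cur[2]):
                a, b = sorted((ga, gb))
                best[key] = (a, b, score, sig)
        df = pd.DataFrame(
            sorted(best.values()), columns=list(cls.COLUMNS)
        )
        return cls(df)


def read_homology_table(path: str | Path, significance_cutoff: float = 1e-10) -> HomologyTable:
    """Read a 4+-column TSV (header required: gene_a, gene_b, score,
    significance) and apply the read-time filtering rules."""
    path = Path(path)
    if not path.read_text().strip():
        raise ParseError(f"empty homology table: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse homology TSV: {exc}") from exc
    missing = set(HomologyTable.COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("score", "significance"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in column {col!r}") from exc
    return HomologyTable.from_records(
        df[list(HomologyTable.COLUMNS)].itertuples(index=False, name=None),
        significance_cutoff,
    )


def write_homology_table(table: HomologyTable, path: str | Path) -> None:
    table.entries.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree, path: str | Path) -> None:
    """Write a phylogeny.Tree as newick: branch lengths to 6 decimals,
    integer bootstrap labels on internal nodes."""
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path: str | Path):
    from .phylo import Tree

    path = Path(path)
    if not path.read_text().strip():
        raise ParseError(f"empty newick file: {path}")
    return Tree.from_newick(path.read_text())
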