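"""Published reference tables for the group III WRKY transcription-factor
family of poplar (Ptr), grape (Vv), Arabidopsis (At) and rice (Os).

Three small tables ship with the package:

* ``load_gene_table`` — the 57 family members with chromosome
  coordinates, ORF length, protein length, pI, molecular weight and exon
  count. These are printed reference values (some rows are internally
  inconsistent in the source, e.g. rice molecular weights are inflated
  relative to protein length); treat them as fixture facts, not as
  recomputation targets.
* ``load_synteny_quality`` — per species-pair, per-clade relative
  syntenic quality percentages for the family's microsyntenic regions.
* ``load_duplication_dates`` — the eight poplar duplicated pairs with
  their conserved flanking gene counts and flanking mean/SD Ka/Ks and Ks,
  plus the published molecular-clock dates in Mya.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genes import GeneModel

SPECIES_NAMES = {"Ptr": "Populus trichocarpa", "Vv": "Vitis vinifera",
                 "At": "Arabidopsis thaliana", "Os": "Oryza sativa"}


def _read(name: str) -> pd.DataFrame:
    with resources.files("genefamkit").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_gene_table() -> pd.DataFrame:
    return _read("wrky3_gene_table.tsv")


def load_synteny_quality() -> pd.DataFrame:
    return _read("wrky3_synteny_quality.tsv")


def load_duplication_dates() -> pd.DataFrame:
    return _read("wrky3_duplication_dates.tsv")


def gene_models_from_table(table: pd.DataFrame | None = None) -> list[GeneModel]:
    """GeneModels from the reference gene table, one single-span exon per
    printed exon count (the table states counts, not intervals). Chromosome
    labels are prefixed with the species tag so the four genomes never
    collide."""
    if table is None:
        table = load_gene_table()
    models = []
    for row in table.itertuples(index=False):
        span = row.end - row.start + 1
        n_ex = int(row.exons)
        piece = max(1, span // (2 * n_ex - 1))
        exons = [
            (row.start + 2 * k * piece,
             min(row.start + 2 * k * piece + piece - 1, row.end))
            for k in range(n_ex)
        ]
        exons[-1] = (exons[-1][0], row.end)
        models.append(
            GeneModel(
                gene_id=row.name,
                chromosome=f"{row.species}_chr{row.chromosome}",
                strand="+",
                start=int(row.start),
                end=int(row.end),
                exons=exons,
            )
        )
    return models
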