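"""Relative qPCR expression by the 2^-ddCT method.

For each biological replicate, technical replicates are averaged first;
dCT = mean CT(target) - mean CT(reference); ddCT subtracts the mean dCT of
the untreated control sample; the reported fold change is the mean of
2^-ddCT over biological replicates (so the control itself averages to 1
when it has a single biological replicate, and to >= 1 — Jensen's
inequality — with several noisy ones). The SD is the sample SD of the
per-replicate 2^-ddCT values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

CT_COLUMNS = ("sample", "gene", "replicate_bio", "replicate_tech", "ct")
TISSUE_ORDER = ("R", "YL", "ML", "ST", "X", "Phl")  # documented tie-break order


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("CT table is empty")
    ct = pd.to_numeric(df["ct"], errors="raise")
    if ((ct <= 0) | (ct >= 45)).any():
        raise ValueError("CT values must lie in (0, 45) cycles")
    return df


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.read_text().strip():
        raise ValueError(f"empty CT table: {path}")
    return validate_ct_table(pd.read_csv(path))


@dataclass
class ExpressionResult:
    gene: str
    sample: str
    rel_expr: float
    sd: float
    regulation: str = ""

    def __post_init__(self) -> None:
        if self.rel_expr <= 0:
            raise ValueError("relative expression must be positive")


def _delta_ct(df: pd.DataFrame, sample: str, target: str, reference: str) -> pd.Series:
    """dCT per biological replicate (technical replicates averaged first)."""
    sub = df[df["sample"] == sample]
    tgt = sub[sub["gene"] == target].groupby("replicate_bio")["ct"].mean()
    ref = sub[sub["gene"] == reference].groupby("replicate_bio")["ct"].mean()
    if ref.empty:
        raise ValueError(f"reference gene {reference!r} missing in sample {sample!r}")
    if tgt.empty:
        raise ValueError(f"target gene {target!r} missing in sample {sample!r}")
    dct = (tgt - ref).dropna()
    if dct.empty:
        raise ValueError(
            f"no biological replicate measures both {target!r} and {reference!r} "
            f"in sample {sample!r}"
        )
    return dct


def delta_delta_ct(
    ct_table: pd.DataFrame, target: str, reference: str, control_sample: str
) -> list[ExpressionResult]:
    """2^-ddCT fold change of ``target`` vs ``reference`` for every sample,
    normalized so the untreated control is the unit."""
    df = validate_ct_table(ct_table)
    control_dct = _delta_ct(df, control_sample, target, reference).mean()
    results = []
    for sample in pd.unique(df["sample"]):
        dct = _delta_ct(df, sample, target, reference)
        folds = 2.0 ** (-(dct - control_dct))
        results.append(
            ExpressionResult(
                gene=target,
                sample=sample,
                rel_expr=float(folds.mean()),
                sd=float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
            )
        )
    return results


def classify_regulation(
    result: ExpressionResult | float, up_threshold: float = 2.0, down_threshold: float = 0.5
) -> str:
    """'up' at >= up_threshold-fold, 'down' at <= down_threshold-fold, else
    'unchanged'. Thresholds are conventions, not measurements."""
    fold = result.rel_expr if isinstance(result, ExpressionResult) else float(result)
    if math.isnan(fold):
        raise ValueError("fold change undefined")
    if fold >= up_threshold:
        return "up"
    if fold <= down_threshold:
        return "down"
    return "unchanged"


def tissue_max(profile: dict[str, dict[str, float]]) -> dict[str, str]:
    """Tissue of maximal expression per gene; exact ties resolved by the
    documented tissue order (roots, young leaves, mature leaves, stems,
    xylem, phloem)."""
    if not profile:
        raise ValueError("empty expression profile")
    out: dict[str, str] = {}
    for gene, tissues in profile.items():
        if not tissues:
            raise ValueError(f"gene {gene!r} has no tissue measurements")

        def order(t: str) -> int:
            return TISSUE_ORDER.index(t) if t in TISSUE_ORDER else len(TISSUE_ORDER)

        out[gene] = max(sorted(tissues, key=order), key=lambda t: tissues[t])
    return out
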