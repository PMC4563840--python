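"""Run configuration: every tunable threshold of the pipeline in one place.

The defaults encode the study conditions of the comparative analysis this
package implements: a 15-gene flanking window with >=3 conserved homolog
pairs defines a microsyntenic block; tandem duplicates are <=5 intervening
genes within 100 kb; segmental (large-scale) duplication requires >=5
best-non-self-matched flanking pairs at E < 1e-10; Ks > 2.0 is treated as
saturated; the synonymous molecular clock ticks at 9.1e-9
substitutions/site/year; sliding windows are 150 bp advanced by 9 bp;
bootstrap uses 1000 replicates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    window_genes: int = 15
    min_conserved_pairs: int = 3
    tandem_max_intervening: int = 5
    tandem_max_span_bp: int = 100_000
    segmental_min_flanking_pairs: int = 5
    significance_cutoff: float = 1e-10
    ks_max: float = 2.0
    clock_rate: float = 9.1e-9  # substitutions / synonymous site / year
    sw_window_bp: int = 150
    sw_step_bp: int = 9
    bootstrap_reps: int = 1000
    rng_seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "window_genes",
            "min_conserved_pairs",
            "tandem_max_span_bp",
            "segmental_min_flanking_pairs",
            "sw_window_bp",
            "sw_step_bp",
            "bootstrap_reps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.tandem_max_intervening < 0:
            raise ValueError("tandem_max_intervening must be >= 0")
        if self.significance_cutoff < 0:
            raise ValueError("significance_cutoff must be >= 0")
        if self.ks_max <= 0:
            raise ValueError("ks_max must be positive")
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be positive")
        # Ka/Ks is codon-defined, so bp windows must translate to whole codons.
        if self.sw_window_bp % 3 or self.sw_step_bp % 3:
            raise ValueError("sw_window_bp and sw_step_bp must be multiples of 3")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a plain-text ``key = value`` config (one pair per line,
        ``#`` starts a comment). Keyword overrides win over file values."""
        path = Path(path)
        text = path.read_text()
        if not text.strip():
            raise ValueError(f"empty config file: {path}")
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        values: dict = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            caster = int if fields[key] in ("int", int) else float
            try:
                values[key] = caster(float(val)) if caster is int else caster(val)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value for {key}: {val!r}") from exc
        values.update(overrides)
        return cls(**values)
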