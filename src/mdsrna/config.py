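"""Pipeline configuration: every stage's thresholds in one serializable place.

Defaults follow the published filtering rules (mean phred >= 28, minimum
length 50 nt after trimming, N fraction < 5%, contigs >= 300 nt) and the
package's own choices where the protocol left them open (assembly k, overlap
and consensus thresholds for terminal extension, motif and hairpin scans).
The config is echoed into every run log so a run is reproducible from its
log alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    # read QC
    min_mean_phred: float = 28.0
    min_length: int = 50
    max_n_fraction: float = 0.05
    quality_statistic: str = "mean"  # mean|min

    # assembly
    k: int = 31
    min_contig: int = 300
    min_kmer_coverage: int = 2

    # terminal extension
    min_overlap: int = 31
    min_support: int = 3
    consensus_fraction: float = 0.8
    max_rounds: int = 50

    # map-back consensus
    seed_length: int = 31
    max_mismatches: int = 3

    # annotation
    polya_min_run: int = 12
    polya_purity: float = 0.9
    hairpin_window: int = 120
    min_stem: int = 4
    allow_wobble: bool = False

    # motif discovery
    motif_k: int = 24
    motif_max_mismatch: int = 4
    motif_min_genomes: int = 2

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.max_n_fraction <= 1):
            raise ValueError("max_n_fraction must be in [0, 1]")
        if self.quality_statistic not in ("mean", "min"):
            raise ValueError("quality_statistic must be 'mean' or 'min'")
        if self.k % 2 == 0 or not (15 <= self.k <= 99):
            raise ValueError("k must be odd and in [15, 99]")
        if self.min_overlap < 15:
            raise ValueError("min_overlap must be >= 15")
        if not (0.5 <= self.consensus_fraction <= 1.0):
            raise ValueError("consensus_fraction must be in [0.5, 1.0]")
        if self.min_support < 1 or self.max_rounds < 1:
            raise ValueError("min_support and max_rounds must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML (or flat key=value lines)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if isinstance(data, str):  # flat key=value fallback
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                data[key.strip()] = yaml.safe_load(val.strip())
        return cls.from_dict(data or {})

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
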