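"""Pipeline configuration.

Every tunable of the analysis lives here with its default, so that a run is
fully described by one :class:`PipelineConfig`. Defaults are the published
procedure constants: 600 bp contact bins, the 8–40 kb separation band,
focal-spot criteria (center ≥ 5 reads, ≥ 1.2× the second-highest neighbour,
neighbourhood median < 40% of the center), the TMC coldfield score exponent
1.3 with a 5-bin diagonal search over 20 positions per direction (±57 kb),
±11 kb TE flanks scanned with 21 overlapping 2 kb windows, 10 kb TE index
buckets, and the 1 M / 800 K / 2.5 M systematic read-sampling plan.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # contact binning
    bin_size: int = 600
    min_sep: int = 8_000
    max_sep: int = 40_000
    # hotspot criteria on the 5x5 grid (corners excluded -> 21 cells)
    min_center: int = 5
    excess: float = 1.2
    median_frac: float = 0.4
    # coldfield search
    tmc_exponent: float = 1.3
    step_bins: int = 5
    n_positions: int = 20
    # TE indexing and flank windows
    te_bucket: int = 10_000
    flank: int = 11_000
    window_width: int = 2_000
    window_step: int = 1_000
    # pairing summaries
    top_k: int = 30
    product_counting: bool = False  # element-pair products instead of presence
    # systematic sampling of the .pairs stream (raw data lines)
    initial_skip: int = 1_000_000
    take: int = 800_000
    cycle_skip: int = 2_500_000
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not 0 <= self.min_sep <= self.max_sep:
            raise ValueError("need 0 <= min_sep <= max_sep")
        if self.take <= 0:
            raise ValueError("take must be positive")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        """Short stable digest, recorded in output headers for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)
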