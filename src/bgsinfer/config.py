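"""Declarative run configuration: one key/value file driving a simulation.

A config names the genome layout, DFE, demography, rates, rescaling
factor and seed; its hash is stamped into output files so that any
artifact can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .genomes import (
    Demography,
    DiscreteDFE,
    Epoch,
    GenomeLayout,
    NAMED_DFES,
    build_genome_layout,
    named_dfe,
    preset_demography,
)

__all__ = ["RunConfig"]

_GENOME_PRESETS = {
    "genome5": (3000, 31000),
    "genome10": (1500, 15750),
    "genome20": (600, 6300),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated simulation configuration (see ``from_yaml``)."""

    engine: str = "coalescent"  # "coalescent" | "forward"
    demography: str = "equilibrium"
    genome: str | None = None  # genome5/genome10/genome20 (forward engine)
    chrom_bp: float = 1_000_000
    dfe: str = "neutral"
    mu: float = 1e-8
    rec: float = 1e-8
    Q: float = 1.0
    n_sample: int = 50
    seed: int = 1
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.engine not in ("coalescent", "forward"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.genome is not None and self.genome not in _GENOME_PRESETS:
            raise ValueError(f"unknown genome preset {self.genome!r}")
        if self.dfe not in NAMED_DFES:
            raise ValueError(f"unknown DFE {self.dfe!r}")
        if self.mu < 0 or self.rec < 0 or self.Q < 1:
            raise ValueError("rates must be >= 0 and Q >= 1")
        if self.chrom_bp <= 0 or self.n_sample < 1:
            raise ValueError("chrom_bp and n_sample must be positive")
        preset_demography(self.demography)  # validates the name

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extras = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extras=extras)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def build_layout(self) -> GenomeLayout:
        intron, intergenic = _GENOME_PRESETS[self.genome or "genome20"]
        return build_genome_layout(350, 8, intron, intergenic, self.chrom_bp)

    def build_dfe(self, Nanc: int) -> DiscreteDFE:
        return named_dfe(self.dfe, Nanc)

    def build_demography(self) -> Demography:
        return preset_demography(self.demography)
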