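"""Pipeline configuration: one plain-text (YAML) file with documented keys,
round-tripping unchanged through serialization. Command-line flags override
individual keys.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import NATURAL_13C
from .nanosims import DEFAULT_PIXEL_SIZE_UM, ENRICHMENT_THRESHOLD
from .proteinsip import CORRELATION_THRESHOLD, DEFAULT_PPM, RIA_MARGIN
from .rates import DEFAULT_RHO_C

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All pipeline parameters and input/output paths.

    Keys (units): ``k_s`` substrate ¹³C atom fraction; ``k_na`` natural ¹³C
    atom fraction; ``rho_c`` carbon density fg/μm³; ``t_h`` incubation time
    h; ``pixel_size_um`` μm/px; ``enrichment_threshold`` K_A cutoff for the
    enriched call; ``ppm`` envelope mass window; ``correlation_threshold``
    labeled-call minimum fit correlation; ``ria_margin`` labeled-call RIA
    excess over natural; ``seed`` master seed for all randomness.
    """

    # mass-balance / geometry parameters
    k_s: float = 0.10
    k_na: float = NATURAL_13C
    rho_c: float = DEFAULT_RHO_C
    t_h: float = 96.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    # thresholds
    enrichment_threshold: float = ENRICHMENT_THRESHOLD
    ppm: float = DEFAULT_PPM
    correlation_threshold: float = CORRELATION_THRESHOLD
    ria_margin: float = RIA_MARGIN
    # reproducibility
    seed: int = 0
    # inputs (optional depending on subcommand)
    identifications: str | None = None
    peak_dir: str | None = None
    bins: dict[str, str] = field(default_factory=dict)  # bin id -> FASTA path
    stack: str | None = None
    mask: str | None = None
    # outputs
    out_dir: str = "sipquant_out"

    def __post_init__(self) -> None:
        if not 0 < self.ppm <= 100:
            raise ValueError("ppm must lie in (0, 100]")
        if not 0 <= self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must lie in [0, 1]")
        if not 0 <= self.enrichment_threshold < 1:
            raise ValueError("enrichment_threshold must lie in [0, 1)")
        if self.k_s <= self.k_na:
            raise ValueError("k_s must exceed k_na")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def as_dict(self) -> dict:
        return asdict(self)
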