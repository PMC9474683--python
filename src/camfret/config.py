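"""Pipeline configuration: analysis constants, protocols, paths, seed.

Every run freezes the resolved configuration (JSON + SHA-256 hash) into
its report so results are attributable to an exact constant set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .errors import ValidationError
from .kinetics import KineticsOptions

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Resolved configuration of a simulation + analysis run."""

    genotypes: tuple = ("WT", "P212L")
    n_per_genotype: int = 19
    protocol: dict = field(default_factory=lambda: {"n_pulses": 50, "frequency": 20.0, "onset_time": 5.0})
    seed: int = 1
    # analysis constants (assay defaults)
    peak_window_s: float = 20.0
    rolling_window: int = 5
    artifact_mad_k: float = 5.0
    exclusion_cfp_hard: float = 0.85
    exclusion_cfp_soft: float = 0.90
    exclusion_yfp_soft: float = 0.85
    exclusion_rcamp_sd_mult: float = 2.0
    gaussian_sigma: float = 1.0
    spine_peak_frames: int = 5
    soma_avg_frames: int = 10
    min_ca_peak_dff0: float = 0.2
    welch: bool = False
    outdir: str = "camfret_out"

    def __post_init__(self):
        for name in (
            "peak_window_s",
            "artifact_mad_k",
            "exclusion_cfp_hard",
            "exclusion_cfp_soft",
            "exclusion_yfp_soft",
            "exclusion_rcamp_sd_mult",
            "gaussian_sigma",
            "min_ca_peak_dff0",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.rolling_window < 1 or self.rolling_window % 2 == 0:
            raise ValidationError("rolling_window must be odd and >= 1")
        if self.n_per_genotype < 1:
            raise ValidationError("n_per_genotype must be >= 1")
        self.genotypes = tuple(self.genotypes)

    def kinetics_options(self) -> KineticsOptions:
        return KineticsOptions(
            peak_window_s=self.peak_window_s,
            rolling_window=self.rolling_window,
            artifact_mad_k=self.artifact_mad_k,
            min_ca_peak_dff0=self.min_ca_peak_dff0,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
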