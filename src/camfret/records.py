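"""Core record containers shared between the simulator and the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ValidationError
from .protocol import StimulusProtocol

__all__ = ["TraceRecord"]


@dataclass
class TraceRecord:
    """Raw three-channel per-ROI intensity time series.

    Channels are CFP and YFP (the FRET donor/acceptor pair of the kinase
    sensor) and RFP (the red Ca2+ indicator).  Background is a scalar or a
    per-frame series per channel, measured from a cell-free region.  The
    baseline window is the pre-stimulus interval used to define R0 and F0.
    """

    roi_id: str
    genotype: str
    protocol: Optional[StimulusProtocol]
    frame_times: np.ndarray
    cfp: np.ndarray
    yfp: np.ndarray
    rfp: np.ndarray
    background_cfp: float | np.ndarray = 0.0
    background_yfp: float | np.ndarray = 0.0
    background_rfp: float | np.ndarray = 0.0
    baseline_window: tuple[float, float] | None = None
    #: simulator-only ground truth: frames carrying an uncaging-light artifact
    artifact_truth: Optional[np.ndarray] = None
    #: simulator-only ground truth metrics (noise-free activation curve)
    ground_truth: dict = field(default_factory=dict)
    #: provenance flags accumulated by processing steps
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.cfp = np.asarray(self.cfp, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        self.rfp = np.asarray(self.rfp, dtype=float)
        n = len(self.frame_times)
        for name in ("cfp", "yfp", "rfp"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length {len(getattr(self, name))} != frame_times length {n}")
        if n >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise ValidationError("frame_times must be strictly increasing")
        if self.baseline_window is None:
            onset = self.protocol.onset_time if self.protocol is not None else self.frame_times[-1]
            self.baseline_window = (float(self.frame_times[0]), float(onset))
        t0, t1 = self.baseline_window
        if self.protocol is not None and t1 > self.protocol.onset_time + 1e-9:
            raise ValidationError(
                f"baseline_window must end at or before stimulus onset ({self.protocol.onset_time} s), got {t1}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.frame_times)))

    def baseline_mask(self) -> np.ndarray:
        t0, t1 = self.baseline_window
        return (self.frame_times >= t0) & (self.frame_times <= t1)

    def channels(self) -> dict[str, np.ndarray]:
        return {"cfp": self.cfp, "yfp": self.yfp, "rfp": self.rfp}

    def with_channels(self, cfp=None, yfp=None, rfp=None, extra_flags=()) -> "TraceRecord":
        """Copy with replaced channel data (arrays are not shared)."""
        rec = replace(
            self,
            cfp=self.cfp if cfp is None else np.asarray(cfp, dtype=float),
            yfp=self.yfp if yfp is None else np.asarray(yfp, dtype=float),
            rfp=self.rfp if rfp is None else np.asarray(rfp, dtype=float),
        )
        rec.flags = list(self.flags) + list(extra_flags)
        return rec
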