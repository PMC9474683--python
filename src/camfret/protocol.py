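"""Stimulus protocols: regularly spaced glutamate-uncaging pulse trains.

A protocol is a train of ``n_pulses`` pulses delivered at ``frequency`` Hz
starting at ``onset_time``; pulse k occurs at ``onset_time + k/frequency``.
The somatic experiments of interest use 50 pulses at 20 Hz, the
frequency-tuning experiments 30 pulses at 2.5-20 Hz, and the spine
experiments 100 pulses at 20 Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["StimulusProtocol", "SOMA_50_AT_20HZ", "SPINE_100_AT_20HZ", "tuning_protocols"]


@dataclass(frozen=True)
class StimulusProtocol:
    """A regular pulse train.

    Parameters
    ----------
    n_pulses:
        Number of uncaging pulses, at least 1.
    frequency:
        Pulse repetition rate in Hz, strictly positive.
    onset_time:
        Time of the first pulse in seconds from recording start.
    label:
        Free-text tag carried through to outputs.
    """

    n_pulses: int
    frequency: float
    onset_time: float = 5.0
    label: str = ""

    def __post_init__(self):
        if int(self.n_pulses) != self.n_pulses or self.n_pulses < 1:
            raise InvalidArgumentError(f"n_pulses must be an integer >= 1, got {self.n_pulses}")
        if not (self.frequency > 0):
            raise InvalidArgumentError(f"frequency must be > 0 Hz, got {self.frequency}")
        if self.onset_time < 0:
            raise InvalidArgumentError(f"onset_time must be >= 0 s, got {self.onset_time}")

    @property
    def pulse_times(self) -> np.ndarray:
        """Times of every pulse in seconds."""
        return self.onset_time + np.arange(self.n_pulses) / self.frequency

    @property
    def end_time(self) -> float:
        """Time of the last pulse in seconds."""
        return float(self.onset_time + (self.n_pulses - 1) / self.frequency)

    @property
    def train_duration(self) -> float:
        """Duration from first to last pulse in seconds."""
        return float((self.n_pulses - 1) / self.frequency)

    def to_dict(self) -> dict:
        return {
            "n_pulses": int(self.n_pulses),
            "frequency": float(self.frequency),
            "onset_time": float(self.onset_time),
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            n_pulses=int(d["n_pulses"]),
            frequency=float(d["frequency"]),
            onset_time=float(d.get("onset_time", 5.0)),
            label=str(d.get("label", "")),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: Somatic kinetics protocol (peak / half-rise / half-decay comparisons).
SOMA_50_AT_20HZ = StimulusProtocol(n_pulses=50, frequency=20.0, onset_time=5.0, label="soma-50x20Hz")

#: Dendritic-spine protocol.
SPINE_100_AT_20HZ = StimulusProtocol(n_pulses=100, frequency=20.0, onset_time=5.0, label="spine-100x20Hz")


def tuning_protocols(frequencies=(2.5, 5.0, 10.0, 20.0), n_pulses: int = 30, onset_time: float = 5.0):
    """The 30-pulse frequency-tuning protocol family."""
    return [
        StimulusProtocol(n_pulses=n_pulses, frequency=f, onset_time=onset_time, label=f"tuning-{f:g}Hz")
        for f in frequencies
    ]
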