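"""Uncaging-evoked free-Ca2+ dynamics.

Each uncaging pulse adds a fixed Ca2+ increment that decays
mono-exponentially toward baseline; increments superpose across pulses and
the total is capped at a saturation ceiling at the instant a pulse lands
(buffer/indicator saturation).  Concentrations are in arbitrary units: the
imaging experiments never measure absolute Ca2+, only a linear indicator,
so only relative Ca2+ levels are meaningful and the kinase model's
half-activation constant is expressed in the same units.

The trajectory is evaluated analytically (superposed exponentials with
per-pulse applied increments), so sampling is exact at any time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidArgumentError, ValidationError
from ..protocol import StimulusProtocol

__all__ = ["CalciumParams", "calcium_evaluator", "simulate_ca_transient"]


@dataclass(frozen=True)
class CalciumParams:
    """Parameters of the pulse-train Ca2+ model (arbitrary concentration units)."""

    pulse_amplitude: float = 0.07
    decay_tau: float = 2.0
    baseline: float = 0.0
    saturation_ceiling: float = 1.6

    def __post_init__(self):
        if self.pulse_amplitude < 0 or self.baseline < 0 or self.saturation_ceiling < 0:
            raise ValidationError("calcium parameters must be non-negative")
        if not (self.decay_tau > 0):
            raise ValidationError(f"decay_tau must be > 0, got {self.decay_tau}")


def _applied_increments(protocol: StimulusProtocol, params: CalciumParams) -> np.ndarray:
    """Increment actually applied at each pulse after ceiling clipping."""
    times = protocol.pulse_times
    inc = np.empty(len(times))
    for k, tk in enumerate(times):
        # level just before pulse k: baseline + sum of earlier increments decayed to tk
        if k == 0:
            pre = params.baseline
        else:
            pre = params.baseline + np.sum(inc[:k] * np.exp(-(tk - times[:k]) / params.decay_tau))
        inc[k] = min(params.pulse_amplitude, max(params.saturation_ceiling - pre, 0.0))
    return inc


def calcium_evaluator(protocol: StimulusProtocol, params: CalciumParams):
    """Return ``f(t)`` evaluating the free-Ca2+ trajectory at arbitrary times."""
    times = protocol.pulse_times
    inc = _applied_increments(protocol, params)

    def ca(t):
        t = np.asarray(t, dtype=float)
        dt = t[..., None] - times
        contrib = np.where(dt >= 0, inc * np.exp(-np.clip(dt, 0, None) / params.decay_tau), 0.0)
        return params.baseline + contrib.sum(axis=-1)

    return ca


def simulate_ca_transient(
    protocol: StimulusProtocol,
    params: CalciumParams,
    duration: float,
    dt: float = 0.002,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the free-Ca2+ series on a regular grid.

    Parameters
    ----------
    protocol:
        Pulse train.  ``duration`` must extend past the last pulse.
    params:
        Ca2+ model parameters.
    duration:
        Length of the simulation in seconds.
    dt:
        Sampling interval of the returned grid in seconds.

    Returns
    -------
    (timestamps, ca):
        Regular time grid from 0 to ``duration`` and the Ca2+ series on it.
    """
    if not (duration > 0):
        raise InvalidArgumentError(f"duration must be > 0 s, got {duration}")
    if duration <= protocol.end_time:
        raise InvalidArgumentError(
            f"duration ({duration} s) must extend past the last pulse ({protocol.end_time} s)"
        )
    t = np.arange(0.0, duration + dt / 2, dt)
    return t, calcium_evaluator(protocol, params)(t)
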