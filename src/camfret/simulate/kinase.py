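"""Three-state CaMKII activation model.

Subunits are in one of three states: autoinhibited (fraction
``1 - B - P``), Ca2+/CaM-bound (``B``) or autonomous, i.e. T286-
phosphorylated and active after CaM dissociation (``P``):

    dB/dt = k_on * cam_active * (1 - B - P) - k_off * B - k_auto * B * (B + P)
    dP/dt = k_auto * B * (B + P) - k_dephos * P

with the Ca2+-dependent concentration of active CaM

    cam_active = cam_total * ca^h / (ca^h + K_cam^h).

The autophosphorylation term is proportional to ``B * (B + P)`` because
T286 phosphorylation is an inter-subunit reaction within the holoenzyme: a
bound (substrate) subunit must meet an active (bound or autonomous)
neighbour.  This quadratic term is what makes peak activation grow
supra-linearly with stimulus frequency.  Autophosphorylation converts
bound subunits into autonomous ones, so total activation ``A = B + P``
is conserved by the transfer and ``0 <= B + P <= 1`` holds for any input.

Activation is reported as ``A(t) = B(t) + P(t)``; the FRET sensor reads it
out through ``fret_gain`` (see :mod:`camfret.simulate.acquisition`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np

from ..errors import InvalidArgumentError, ValidationError

__all__ = ["GENOTYPES", "KinaseModelParams", "ActivationTrace", "simulate_kinase"]

#: Genotypes with a named preset: wild type plus the de novo mutations
#: reported in intellectual-disability cases.
GENOTYPES = ("WT", "F98S", "E109D", "A112V", "E183V", "P212L", "P212Q", "P235L", "H282R", "T286P")


@dataclass(frozen=True)
class KinaseModelParams:
    """Rate constants and readout parameters of one genotype.

    Units: ``K_cam`` is in the arbitrary Ca2+ units of
    :class:`~camfret.simulate.calcium.CalciumParams`; ``k_on`` in
    1/(uM*s) against active-CaM concentration; ``k_off``, ``k_auto``,
    ``k_dephos`` in 1/s.  ``fret_gain`` converts activation into
    fractional CFP rise / YFP drop; ``baseline_ratio`` is the resting
    CFP/YFP ratio.
    """

    genotype: str = "WT"
    K_cam: float = 1.5
    hill_h: float = 4.0
    k_on: float = 1.0
    k_off: float = 0.35
    k_auto: float = 0.8
    k_dephos: float = 0.05
    fret_gain: float = 0.25
    baseline_ratio: float = 0.55

    def __post_init__(self):
        for name in ("K_cam", "k_on", "k_off", "k_auto", "k_dephos"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0 < self.hill_h <= 4):
            raise ValidationError(f"hill_h must be in (0, 4], got {self.hill_h}")
        if not (self.fret_gain > 0):
            raise ValidationError(f"fret_gain must be > 0, got {self.fret_gain}")
        if not (self.baseline_ratio > 0):
            raise ValidationError(f"baseline_ratio must be > 0, got {self.baseline_ratio}")
        if self.genotype == "T286P" and self.k_auto != 0:
            raise ValidationError("T286P cannot autophosphorylate: k_auto must be 0")

    def replace(self, **kw) -> "KinaseModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KinaseModelParams":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class ActivationTrace:
    """Time courses of the kinase state fractions and their inputs."""

    timestamps: np.ndarray
    fraction_bound: np.ndarray
    fraction_autonomous: np.ndarray
    free_ca: np.ndarray
    cam_active: np.ndarray

    @property
    def activation(self) -> np.ndarray:
        """Total active fraction A(t) = B(t) + P(t)."""
        return self.fraction_bound + self.fraction_autonomous

    def sample_activation(self, t) -> np.ndarray:
        return np.interp(t, self.timestamps, self.activation)

    def sample_ca(self, t) -> np.ndarray:
        return np.interp(t, self.timestamps, self.free_ca)


def _hill(ca: np.ndarray, K: float, h: float) -> np.ndarray:
    ca = np.clip(ca, 0.0, None)
    if K == 0:
        return (ca > 0).astype(float)
    x = (ca / K) ** h
    return x / (1.0 + x)


def simulate_kinase(
    ca: np.ndarray,
    timestamps: np.ndarray,
    cam_total: float,
    params: KinaseModelParams,
) -> ActivationTrace:
    """Integrate the three-state model over a free-Ca2+ series.

    ``ca`` is given on ``timestamps`` (a regular fine grid; the
    recommended step is at most a tenth of the acquisition frame
    interval).  Integration is fixed-step classical Runge-Kutta on that
    grid, with midpoint Ca2+ taken as the average of adjacent samples.
    """
    ca = np.asarray(ca, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if ca.shape != timestamps.shape:
        raise InvalidArgumentError("ca and timestamps must have identical shapes")
    if not np.all(np.isfinite(ca)) or np.any(ca < 0):
        raise InvalidArgumentError("ca series must be finite and non-negative")
    if not isinstance(params, KinaseModelParams):
        params = KinaseModelParams.from_dict(dict(params))
    if cam_total < 0:
        raise InvalidArgumentError("cam_total must be >= 0")

    cam = cam_total * _hill(ca, params.K_cam, params.hill_h)
    cam_mid = 0.5 * (cam[:-1] + cam[1:]) if len(cam) > 1 else cam

    kon, koff, kauto, kdeph = params.k_on, params.k_off, params.k_auto, params.k_dephos

    n = len(timestamps)
    B = np.zeros(n)
    P = np.zeros(n)
    b = p = 0.0

    def deriv(b, p, c):
        a = b + p
        trans = kauto * b * a
        db = kon * c * (1.0 - a) - koff * b - trans
        dp = trans - kdeph * p
        return db, dp

    for i in range(n - 1):
        dt = timestamps[i + 1] - timestamps[i]
        c0, cm, c1 = cam[i], cam_mid[i], cam[i + 1]
        k1b, k1p = deriv(b, p, c0)
        k2b, k2p = deriv(b + 0.5 * dt * k1b, p + 0.5 * dt * k1p, cm)
        k3b, k3p = deriv(b + 0.5 * dt * k2b, p + 0.5 * dt * k2p, cm)
        k4b, k4p = deriv(b + dt * k3b, p + dt * k3p, c1)
        b += dt / 6.0 * (k1b + 2 * k2b + 2 * k3b + k4b)
        p += dt / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p)
        # numerical guard: the continuous system stays in the simplex
        b = min(max(b, 0.0), 1.0)
        p = min(max(p, 0.0), 1.0 - b)
        B[i + 1] = b
        P[i + 1] = p

    return ActivationTrace(
        timestamps=timestamps,
        fraction_bound=B,
        fraction_autonomous=P,
        free_ca=ca,
        cam_active=cam,
    )
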