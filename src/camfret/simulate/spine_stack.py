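"""Synthetic dendritic-spine image stacks.

Renders a Gaussian-blob spine head attached to a tube-like dendritic
shaft into a three-channel movie.  The red Ca2+-indicator channel scales
with local volume only, while the kinase-sensor channels (CFP/YFP) carry
an extra spine enrichment factor, so the measured
(sensor/volume) spine-to-shaft quotient recovers the ground-truth
enrichment.  Per-frame dynamics follow a supplied activation trace;
noise is Poisson shot noise plus Gaussian read noise, reproducible for a
given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidArgumentError
from .acquisition import RFP_GAIN, AcquisitionParams, SPINE_ACQUISITION
from .kinase import ActivationTrace, KinaseModelParams

__all__ = ["SpineGeometry", "SpineStack", "render_spine_stack"]


@dataclass(frozen=True)
class SpineGeometry:
    """Spine/shaft layout in pixels (image row = y, column = x)."""

    shape: tuple[int, int] = (48, 64)
    spine_center: tuple[float, float] = (16.0, 32.0)  # (y, x)
    spine_radius: float = 4.0
    shaft_y: float = 36.0
    shaft_halfwidth: float = 5.0

    def __post_init__(self):
        if self.spine_radius <= 0 or self.shaft_halfwidth <= 0:
            raise InvalidArgumentError("spine_radius and shaft_halfwidth must be > 0")
        gap = abs(self.spine_center[0] - self.shaft_y) - (self.spine_radius + self.shaft_halfwidth)
        if gap <= 0:
            raise InvalidArgumentError("spine and shaft regions must be disjoint")

    def volume_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """(spine, shaft) volume-density images, peak-normalized to 1."""
        h, w = self.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        sy, sx = self.spine_center
        spine = np.exp(-((yy - sy) ** 2 + (xx - sx) ** 2) / (2.0 * (self.spine_radius / 2.0) ** 2))
        shaft = np.exp(-((yy - self.shaft_y) ** 2) / (2.0 * (self.shaft_halfwidth / 2.0) ** 2))
        return spine, shaft

    def spine_mask(self) -> np.ndarray:
        h, w = self.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        sy, sx = self.spine_center
        return (yy - sy) ** 2 + (xx - sx) ** 2 <= self.spine_radius**2

    def shaft_mask(self) -> np.ndarray:
        h, w = self.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        return np.abs(yy - self.shaft_y) <= self.shaft_halfwidth


@dataclass
class SpineStack:
    """Three-channel rendered movie with its generating ground truth."""

    cfp: np.ndarray  # (T, H, W)
    yfp: np.ndarray
    rfp: np.ndarray
    frame_times: np.ndarray
    geometry: SpineGeometry
    background_level: float
    truth: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)


def render_spine_stack(
    geometry: SpineGeometry,
    enrichment: float,
    act: ActivationTrace,
    acq: AcquisitionParams = SPINE_ACQUISITION,
    params: KinaseModelParams = KinaseModelParams(),
    peak_counts: float = 400.0,
    read_noise_sd: float = 2.0,
    shot_noise: bool = True,
    rfp_gain: float = RFP_GAIN,
    shaft_activation_scale: float = 1.0,
    seed: int = 0,
) -> SpineStack:
    """Render the spine/shaft movie.

    ``enrichment`` multiplies the sensor (CFP/YFP) density in the spine
    blob relative to the volume marker; ``shaft_activation_scale``
    attenuates activation dynamics in the shaft (1 = same as spine, 0 =
    spine-restricted activation).  Set ``shot_noise=False`` and
    ``read_noise_sd=0`` for a noise-free stack.
    """
    if enrichment <= 0:
        raise InvalidArgumentError("enrichment must be > 0")
    rng = np.random.default_rng(seed)
    spine_v, shaft_v = geometry.volume_maps()

    t = acq.frame_times
    A = act.sample_activation(t)
    ca = act.sample_ca(t)
    ca0 = float(np.interp(0.0, act.timestamps, act.free_ca))

    g = params.fret_gain
    sensor_density = shaft_v + enrichment * spine_v
    volume_density = shaft_v + spine_v

    T = len(t)
    h, w = geometry.shape
    cfp = np.empty((T, h, w))
    yfp = np.empty((T, h, w))
    rfp = np.empty((T, h, w))
    for i in range(T):
        a_map = A[i] * (spine_v + shaft_activation_scale * shaft_v) / np.maximum(volume_density, 1e-12)
        cfp[i] = params.baseline_ratio * peak_counts * sensor_density * (1.0 + g * a_map)
        yfp[i] = peak_counts * sensor_density * (1.0 - g * a_map)
        rfp[i] = peak_counts * volume_density * (1.0 + rfp_gain * (ca[i] - ca0))

    for arr in (cfp, yfp, rfp):
        arr += acq.background_level
        if shot_noise:
            arr[:] = rng.poisson(np.clip(arr, 0, None)).astype(float)
        if read_noise_sd > 0:
            arr += rng.normal(0.0, read_noise_sd, size=arr.shape)

    return SpineStack(
        cfp=cfp,
        yfp=yfp,
        rfp=rfp,
        frame_times=t,
        geometry=geometry,
        background_level=acq.background_level,
        truth={
            "enrichment": float(enrichment),
            "fret_gain": g,
            "peak_activation": float(np.max(A)),
            "shaft_activation_scale": float(shaft_activation_scale),
        },
    )
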