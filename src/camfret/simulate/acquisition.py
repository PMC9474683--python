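"""Rendering of kinase/Ca2+ dynamics into noisy three-channel recordings.

The FRET sensor loses FRET on activation, so the donor (CFP) brightens and
the acceptor (YFP) dims: around their baselines,

    CFP(t) = cfp0 * (1 + fret_gain * A(t))
    YFP(t) = yfp0 * (1 - fret_gain * A(t))

which makes the CFP/YFP ratio rise with activation.  The red Ca2+
indicator responds linearly to free Ca2+:

    RFP(t) = rfp0 * (1 + rfp_gain * (ca(t) - ca_baseline)).

On top of the clean signals the renderer adds a constant background,
optional mono-exponential photobleaching, Gaussian read/shot noise, and a
positive artifact spike in every channel at frames whose exposure window
overlaps an uncaging pulse (stray 355-nm uncaging light reaches every
detector).  Output is bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidArgumentError, ValidationError
from ..protocol import StimulusProtocol
from ..records import TraceRecord
from .kinase import ActivationTrace, KinaseModelParams

__all__ = ["AcquisitionParams", "SOMA_ACQUISITION", "SPINE_ACQUISITION", "render_neuron_recording", "RFP_GAIN"]

#: RFP fractional change per unit free Ca2+ (a.u.); chosen so that the
#: saturating somatic Ca2+ transient gives a peak dF/F0 of about 2.
RFP_GAIN = 1.25

#: Baseline channel intensities in camera counts.
_YFP0 = 1000.0
_RFP0 = 1000.0


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera / acquisition settings.

    ``noise_sd_per_channel`` is the Gaussian noise SD in counts, applied
    per channel per frame (a single scalar; channel baselines are of
    comparable magnitude).  ``artifact_magnitude`` is the artifact spike
    height in counts added at frames overlapping uncaging pulses.
    """

    frame_rate: float = 25.0
    exposure: float = 0.010
    duration: float = 40.0
    noise_sd_per_channel: float = 4.0
    background_level: float = 100.0
    artifact_magnitude: float = 300.0
    photobleach_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.frame_rate > 0):
            raise ValidationError("frame_rate must be > 0")
        if not (self.duration > 0):
            raise ValidationError("duration must be > 0")
        if self.noise_sd_per_channel < 0:
            raise ValidationError("noise_sd_per_channel must be >= 0")
        if self.exposure < 0 or self.exposure > 1.0 / self.frame_rate:
            raise ValidationError("exposure must be within one frame interval")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration * self.frame_rate))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def replace(self, **kw) -> "AcquisitionParams":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


#: Somatic imaging: 25 Hz, 10 ms exposure.
SOMA_ACQUISITION = AcquisitionParams(frame_rate=25.0, exposure=0.010)

#: Spine imaging: 4 Hz, 100 ms exposure.
SPINE_ACQUISITION = AcquisitionParams(frame_rate=4.0, exposure=0.100)


def artifact_frames(acq: AcquisitionParams, protocol: StimulusProtocol) -> np.ndarray:
    """Boolean mask of frames whose exposure window overlaps a pulse."""
    t0 = acq.frame_times
    t1 = t0 + acq.exposure
    pulses = protocol.pulse_times
    hit = (pulses[None, :] >= t0[:, None]) & (pulses[None, :] <= t1[:, None])
    return hit.any(axis=1)


def render_neuron_recording(
    act: ActivationTrace,
    acq: AcquisitionParams,
    protocol: StimulusProtocol,
    params: KinaseModelParams,
    roi_id: str = "roi0",
    rfp_gain: float = RFP_GAIN,
    rng: np.random.Generator | None = None,
) -> TraceRecord:
    """Sample an activation trace into a noisy somatic recording.

    The record carries simulator ground truth (artifact frame mask and
    the noise-free activation metrics inputs) for recovery tests.
    """
    if act.timestamps[-1] < acq.duration - 1.0 / acq.frame_rate:
        raise InvalidArgumentError(
            f"activation trace ends at {act.timestamps[-1]:.3f} s but acquisition lasts {acq.duration} s"
        )
    if rng is None:
        rng = np.random.default_rng(acq.seed)

    t = acq.frame_times
    A = act.sample_activation(t)
    ca = act.sample_ca(t)
    ca0 = float(np.interp(0.0, act.timestamps, act.free_ca))

    g = params.fret_gain
    cfp0 = params.baseline_ratio * _YFP0
    cfp = cfp0 * (1.0 + g * A)
    yfp = _YFP0 * (1.0 - g * A)
    rfp = _RFP0 * (1.0 + rfp_gain * (ca - ca0))

    if acq.photobleach_rate > 0:
        bleach = np.exp(-acq.photobleach_rate * t)
        cfp, yfp, rfp = cfp * bleach, yfp * bleach, rfp * bleach

    art = artifact_frames(acq, protocol)
    spikes = acq.artifact_magnitude * art

    chans = []
    for clean in (cfp, yfp, rfp):
        noisy = clean + acq.background_level + spikes
        if acq.noise_sd_per_channel > 0:
            noisy = noisy + rng.normal(0.0, acq.noise_sd_per_channel, size=clean.shape)
        chans.append(noisy)

    return TraceRecord(
        roi_id=roi_id,
        genotype=params.genotype,
        protocol=protocol,
        frame_times=t,
        cfp=chans[0],
        yfp=chans[1],
        rfp=chans[2],
        background_cfp=acq.background_level,
        background_yfp=acq.background_level,
        background_rfp=acq.background_level,
        baseline_window=(0.0, protocol.onset_time),
        artifact_truth=art,
        ground_truth={
            "fret_gain": g,
            "baseline_ratio": params.baseline_ratio,
            "rfp_gain": rfp_gain,
            "peak_activation": float(np.max(A)),
        },
    )
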