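"""End-to-end single-recording and cohort simulation helpers.

``simulate_recording`` chains the Ca2+ model, the kinase model and the
acquisition renderer for one neuron.  ``simulate_cohort`` adds
between-neuron biological variability: lognormal (mean-one) scatter on
the FRET response gain, the Ca2+ indicator gain and the CaM off-rate,
emulating expression-level and cell-state differences between neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..protocol import StimulusProtocol
from ..records import TraceRecord
from .acquisition import RFP_GAIN, AcquisitionParams, SOMA_ACQUISITION, render_neuron_recording
from .calcium import CalciumParams, simulate_ca_transient
from .kinase import KinaseModelParams, simulate_kinase

__all__ = ["CohortVariability", "simulate_recording", "simulate_cohort", "DEFAULT_CAM_TOTAL"]

#: effective total CaM available to the kinase in neurons, in the model's
#: concentration units (absolute neuronal CaM is unknown; only the product
#: k_on * cam matters, so this is a scale convention)
DEFAULT_CAM_TOTAL = 1.0


@dataclass(frozen=True)
class CohortVariability:
    """Between-neuron lognormal coefficients of variation (mean-one factors)."""

    fret_gain_cv: float = 0.15
    rfp_gain_cv: float = 0.15
    k_off_cv: float = 0.08

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        out = {}
        for name, cv in (
            ("fret_gain", self.fret_gain_cv),
            ("rfp_gain", self.rfp_gain_cv),
            ("k_off", self.k_off_cv),
        ):
            if cv <= 0:
                out[name] = 1.0
            else:
                sigma = float(np.sqrt(np.log1p(cv**2)))
                out[name] = float(rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma))
        return out


def simulate_recording(
    params: KinaseModelParams,
    protocol: StimulusProtocol,
    acq: AcquisitionParams = SOMA_ACQUISITION,
    calcium: CalciumParams = CalciumParams(),
    cam_total: float = DEFAULT_CAM_TOTAL,
    ca_scale: float = 1.0,
    rfp_gain: float = RFP_GAIN,
    roi_id: str = "roi0",
    rng: np.random.Generator | None = None,
    ode_dt: float = 0.002,
) -> TraceRecord:
    """Simulate one neuron: Ca2+ pulses -> kinase activation -> noisy record.

    ``ca_scale`` multiplies the per-pulse Ca2+ increment (used for
    genotype-specific Ca2+ deficits and for pharmacological attenuation of
    the upstream Ca2+ influx).
    """
    cal = CalciumParams(
        pulse_amplitude=calcium.pulse_amplitude * ca_scale,
        decay_tau=calcium.decay_tau,
        baseline=calcium.baseline,
        saturation_ceiling=calcium.saturation_ceiling,
    )
    dt = min(ode_dt, 0.1 / acq.frame_rate)
    t, ca = simulate_ca_transient(protocol, cal, acq.duration, dt=dt)
    act = simulate_kinase(ca, t, cam_total, params)
    return render_neuron_recording(act, acq, protocol, params, roi_id=roi_id, rfp_gain=rfp_gain, rng=rng)


def simulate_cohort(
    params: KinaseModelParams,
    protocol: StimulusProtocol,
    n: int,
    base_seed: int = 0,
    acq: AcquisitionParams = SOMA_ACQUISITION,
    calcium: CalciumParams = CalciumParams(),
    variability: CohortVariability = CohortVariability(),
    cam_total: float = DEFAULT_CAM_TOTAL,
    ca_scale: float = 1.0,
) -> list[TraceRecord]:
    """Simulate ``n`` neurons with between-neuron variability.

    Neuron ``i`` uses the reproducible stream ``default_rng([base_seed, i])``
    so cohorts are bit-stable for a given base seed regardless of ``n``.
    """
    records = []
    for i in range(n):
        rng = np.random.default_rng([int(base_seed), i])
        jit = variability.draw(rng)
        p = params.replace(
            fret_gain=params.fret_gain * jit["fret_gain"],
            k_off=params.k_off * jit["k_off"],
        )
        rec = simulate_recording(
            p,
            protocol,
            acq=acq,
            calcium=calcium,
            cam_total=cam_total,
            ca_scale=ca_scale,
            rfp_gain=RFP_GAIN * jit["rfp_gain"],
            roi_id=f"{params.genotype}-{i:03d}",
            rng=rng,
        )
        records.append(rec)
    return records
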