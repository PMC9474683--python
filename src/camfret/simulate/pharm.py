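"""Pharmacological attenuation of the upstream Ca2+ influx.

Memantine blocks NMDA-receptor channels, acting upstream of the kinase:
it is modeled as a dose-dependent multiplicative reduction of the
per-pulse Ca2+ increment,

    factor(d) = 1 / (1 + d / ic50_sim).

``ic50_sim`` is a simulator constant calibrated once so that the
vehicle-normalized Ca2+-indicator response at 10 uM is about 0.6, the
attenuation observed at that dose in neurons.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from ..protocol import StimulusProtocol
from .calcium import CalciumParams, calcium_evaluator

__all__ = ["MEMANTINE_IC50_SIM", "memantine_ca_factor", "calibrate_memantine_ic50"]


def memantine_ca_factor(dose_um: float, ic50_sim: float | None = None) -> float:
    """Multiplicative Ca2+-amplitude factor at a memantine dose (uM)."""
    if dose_um < 0:
        raise ValueError("dose must be >= 0 uM")
    ic50 = MEMANTINE_IC50_SIM if ic50_sim is None else ic50_sim
    return 1.0 / (1.0 + dose_um / ic50)


def _peak_ca_ratio(scale: float, protocol: StimulusProtocol, calcium: CalciumParams) -> float:
    """Measured peak Ca2+ (ceiling-clipped) at a given amplitude scale, vs vehicle."""
    t = np.linspace(0.0, protocol.end_time + 5.0, 2000)

    def peak(s):
        cal = CalciumParams(
            pulse_amplitude=calcium.pulse_amplitude * s,
            decay_tau=calcium.decay_tau,
            baseline=calcium.baseline,
            saturation_ceiling=calcium.saturation_ceiling,
        )
        return float(np.max(calcium_evaluator(protocol, cal)(t)))

    return peak(scale) / peak(1.0)


def calibrate_memantine_ic50(
    target_fraction: float = 0.6,
    at_dose_um: float = 10.0,
    protocol: StimulusProtocol | None = None,
    calcium: CalciumParams = CalciumParams(),
) -> float:
    """Solve for ic50_sim giving the target indicator attenuation at one dose.

    The Ca2+ ceiling makes measured attenuation shallower than the
    underlying amplitude reduction, so this inverts through the Ca2+
    model rather than the Hill factor alone.
    """
    prot = protocol or StimulusProtocol(n_pulses=30, frequency=20.0, onset_time=5.0)

    def f(log_ic50):
        s = memantine_ca_factor(at_dose_um, float(np.exp(log_ic50)))
        return _peak_ca_ratio(s, prot, calcium) - target_fraction

    return float(np.exp(brentq(f, np.log(0.1), np.log(1000.0), xtol=1e-10)))


#: calibrated once for the 30-pulse 20 Hz protocol and default Ca2+ model
#: (see calibrate_memantine_ic50); regenerate with scripts/build_presets.py
MEMANTINE_IC50_SIM = 15.0
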