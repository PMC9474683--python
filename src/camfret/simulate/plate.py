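"""Synthetic plate-reader runs: Ca2+-addition / EGTA-addition step protocol.

Free Ca2+ steps from ~0 to a plateau when Ca2+ is added and collapses back
when EGTA chelates it; the kinase model is integrated across the steps at
the well's CaM concentration and rendered into noisy CFP / FRET channel
readings plus a matched empty-vector blank well.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidArgumentError
from ..plate_assay import PlateReaderRun
from .kinase import KinaseModelParams, simulate_kinase

__all__ = ["simulate_plate_run"]

#: plate free-Ca2+ plateau after Ca2+ addition, in the simulator's
#: arbitrary Ca2+ units (same scale as the neuronal saturation ceiling)
PLATE_CA_LEVEL = 1.6

_YFP0 = 2000.0


def simulate_plate_run(
    params: KinaseModelParams,
    cam_conc: float,
    ca_add_index: int,
    egta_add_index: int,
    n_frames: int,
    seed: int = 0,
    frame_interval: float = 10.0,
    ca_level: float = PLATE_CA_LEVEL,
    noise_sd: float = 3.0,
    background_level: float = 150.0,
    expression: float = 1.0,
    well_id: str = "well0",
    group: str = "high_expression",
) -> PlateReaderRun:
    """Simulate one well (and its blank) of the Ca2+/EGTA plate protocol.

    ``expression`` scales the probe amount in the well (emulating
    expression-level differences between mutants); the direct YFP probe
    read scales with it, so probe equalization can be exercised.
    """
    if not (0 < ca_add_index < egta_add_index < n_frames):
        raise InvalidArgumentError(
            f"schedule must satisfy 0 < ca_add ({ca_add_index}) < egta_add "
            f"({egta_add_index}) < n_frames ({n_frames})"
        )
    if cam_conc < 0:
        raise InvalidArgumentError("cam_conc must be >= 0")
    rng = np.random.default_rng(seed)

    frame_times = np.arange(n_frames) * frame_interval
    # integrate on a fine grid; rates are O(1)/s so 50 ms resolves the steps
    dt = 0.05
    t = np.arange(0.0, frame_times[-1] + dt, dt)
    ca = np.where((t >= ca_add_index * frame_interval) & (t < egta_add_index * frame_interval), ca_level, 0.0)
    # in the lysate the Ca2+ step fully saturates or releases CaM; cam_total
    # is the added CaM concentration in uM
    act = simulate_kinase(ca, t, cam_conc, params)
    A = act.sample_activation(frame_times)

    g = params.fret_gain
    cfp0 = params.baseline_ratio * _YFP0 * expression
    yfp0 = _YFP0 * expression
    cfp_clean = cfp0 * (1.0 + g * A) + background_level
    fret_clean = yfp0 * (1.0 - g * A) + background_level

    cfp = cfp_clean + rng.normal(0, noise_sd, n_frames)
    fret = fret_clean + rng.normal(0, noise_sd, n_frames)
    blank_cfp = background_level + rng.normal(0, noise_sd, n_frames)
    blank_fret = background_level + rng.normal(0, noise_sd, n_frames)

    probe_blank = 50.0
    probe = _YFP0 * expression + probe_blank + float(rng.normal(0, noise_sd))

    return PlateReaderRun(
        well_id=well_id,
        genotype=params.genotype,
        cam_conc=cam_conc,
        cfp_channel=cfp,
        fret_channel=fret,
        frame_times=frame_times,
        ca_add_index=ca_add_index,
        egta_add_index=egta_add_index,
        blank_cfp=blank_cfp,
        blank_fret=blank_fret,
        probe_yfp_direct=probe,
        blank_probe_yfp=probe_blank,
        group=group,
    )
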