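"""Preset calibration against noise-free pipeline metrics.

Given target metrics (peak dR/R0, half-decay, optionally half-rise) for a
stimulus protocol, the calibrator adjusts a chosen subset of kinase
parameters to minimize the squared relative error between the targets and
the metrics the full analysis pipeline recovers from a noise-free
simulated recording.  Calibrating through the pipeline (including
smoothing and normalization) rather than on the latent activation curve
means the targets are matched in exactly the units the assay reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

from ..errors import CalibrationError, InvalidArgumentError
from ..kinetics import KineticsOptions, analyze_recording
from ..protocol import SOMA_50_AT_20HZ, StimulusProtocol
from .acquisition import AcquisitionParams, SOMA_ACQUISITION
from .calcium import CalciumParams
from .cohort import DEFAULT_CAM_TOTAL, simulate_recording
from .kinase import KinaseModelParams

__all__ = ["CalibrationResult", "noise_free_metrics", "calibrate_preset", "DEFAULT_BOUNDS"]

#: metric name -> attribute of KineticsResult
_METRICS = {
    "peak_drr0": "peak_dRR0",
    "half_rise_s": "half_rise",
    "half_decay_s": "half_decay",
}

#: default parameter box for calibration
DEFAULT_BOUNDS = {
    "K_cam": (0.05, 5.0),
    "k_auto": (1e-3, 5.0),
    "k_off": (0.02, 2.0),
    "fret_gain": (0.01, 1.0),
}


@dataclass
class CalibrationResult:
    """Calibrated parameters with the per-metric relative residuals."""

    params: KinaseModelParams
    targets: dict
    achieved: dict
    residuals: dict = field(default_factory=dict)

    @property
    def max_abs_residual(self) -> float:
        return max(abs(v) for v in self.residuals.values())


def _simplex(x0, lo, hi, step=0.35):
    """Initial Nelder-Mead simplex spanning a meaningful log-space range."""
    pts = [np.clip(x0, lo, hi)]
    for i in range(len(x0)):
        p = pts[0].copy()
        p[i] = np.clip(p[i] - step if p[i] + step > hi[i] else p[i] + step, lo[i], hi[i])
        pts.append(p)
    return np.array(pts)


def _noise_free_acq(acq: AcquisitionParams, protocol: StimulusProtocol) -> AcquisitionParams:
    duration = max(acq.duration, protocol.end_time + 25.0)
    return acq.replace(noise_sd_per_channel=0.0, artifact_magnitude=0.0, photobleach_rate=0.0, duration=duration)


def noise_free_metrics(
    params: KinaseModelParams,
    protocol: StimulusProtocol = SOMA_50_AT_20HZ,
    acq: AcquisitionParams = SOMA_ACQUISITION,
    calcium: CalciumParams = CalciumParams(),
    cam_total: float = DEFAULT_CAM_TOTAL,
    ca_scale: float = 1.0,
    options: KineticsOptions = KineticsOptions(),
) -> dict[str, float]:
    """Run the full pipeline on a noise-free recording and return its metrics."""
    rec = simulate_recording(
        params,
        protocol,
        acq=_noise_free_acq(acq, protocol),
        calcium=calcium,
        cam_total=cam_total,
        ca_scale=ca_scale,
    )
    res = analyze_recording(rec, options)
    return {
        "peak_drr0": res.peak_dRR0,
        "half_rise_s": np.nan if res.half_rise is None else res.half_rise,
        "half_decay_s": np.nan if res.half_decay is None else res.half_decay,
    }


def calibrate_preset(
    targets: dict[str, float],
    base_params: KinaseModelParams,
    protocol: StimulusProtocol = SOMA_50_AT_20HZ,
    acq: AcquisitionParams = SOMA_ACQUISITION,
    calcium: CalciumParams = CalciumParams(),
    free: tuple[str, ...] = ("K_cam", "k_auto"),
    bounds: dict[str, tuple[float, float]] | None = None,
    cam_total: float = DEFAULT_CAM_TOTAL,
    max_residual: float = 0.10,
) -> CalibrationResult:
    """Fit ``free`` parameters of ``base_params`` to the target metrics.

    Parameters are optimized in log space inside the bounded box;
    residuals are relative errors per metric.  Raises
    :class:`CalibrationError` (with the residual report attached) when
    the optimizer cannot bring every metric within ``max_residual``.
    """
    if not targets:
        raise InvalidArgumentError("targets must be a non-empty mapping of metric -> value")
    unknown = set(targets) - set(_METRICS)
    if unknown:
        raise InvalidArgumentError(f"unknown target metrics: {sorted(unknown)} (known: {sorted(_METRICS)})")
    box = dict(DEFAULT_BOUNDS)
    box.update(bounds or {})
    missing = [f for f in free if f not in box]
    if missing:
        raise InvalidArgumentError(f"no bounds supplied for free parameters {missing}")
    names = list(targets)
    lo = np.log([box[f][0] for f in free])
    hi = np.log([box[f][1] for f in free])

    def with_params(x) -> KinaseModelParams:
        vals = np.exp(x)
        return base_params.replace(**{f: float(v) for f, v in zip(free, vals)})

    def resid(x):
        m = noise_free_metrics(
            with_params(x), protocol, acq=acq, calcium=calcium, cam_total=cam_total
        )
        out = []
        for name in names:
            got = m[name]
            if not np.isfinite(got):
                out.append(10.0)  # undetermined metric: large penalty
            else:
                out.append((got - targets[name]) / targets[name])
        return out

    x0 = np.log([np.clip(getattr(base_params, f), box[f][0], box[f][1]) for f in free])

    # the half-time metrics are frame-quantized, which corrupts small
    # finite-difference steps; a derivative-free stage first walks into the
    # basin, then a bounded least-squares polish refines
    def cost(x):
        return float(np.sum(np.square(resid(np.clip(x, lo, hi)))))

    nm = minimize(
        cost,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-8, "maxfev": 200, "initial_simplex": _simplex(x0, lo, hi)},
    )
    start = np.clip(nm.x, lo, hi)
    sol = least_squares(resid, x0=start, bounds=(lo, hi), diff_step=0.05, xtol=1e-10, ftol=1e-12)
    if np.sum(np.square(sol.fun)) > nm.fun:
        sol_x = start
    else:
        sol_x = sol.x

    fitted = with_params(sol_x)
    achieved = noise_free_metrics(fitted, protocol, acq=acq, calcium=calcium, cam_total=cam_total)
    residuals = {name: (achieved[name] - targets[name]) / targets[name] for name in names}
    result = CalibrationResult(params=fitted, targets=dict(targets), achieved=achieved, residuals=residuals)
    if not np.all(np.isfinite(list(residuals.values()))) or result.max_abs_residual > max_residual:
        raise CalibrationError(
            f"calibration residuals exceed {max_residual:.0%}: "
            + ", ".join(f"{k}={v:+.1%}" for k, v in residuals.items()),
            residuals=residuals,
        )
    return result
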