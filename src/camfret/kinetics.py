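"""Somatic trace pipeline: from raw three-channel ROI series to kinetics metrics.

Processing order follows the experimental description: background
subtraction, detection and linear-interpolation repair of uncaging-light
artifact frames, 5-point rolling average per raw channel, then ratioing
and baseline normalization.  Metrics are the peak of the normalized trace
within a fixed window after stimulus onset and midpoint-defined half-rise
and half-decay times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError, InvalidArgumentError
from .records import TraceRecord

__all__ = [
    "KineticsOptions",
    "NormalizedTraces",
    "KineticsResult",
    "subtract_background",
    "repair_artifacts",
    "rolling_average",
    "normalize",
    "detect_peak",
    "half_rise_time",
    "half_decay_time",
    "analyze_recording",
]


@dataclass(frozen=True)
class KineticsOptions:
    """Tunable constants of the trace pipeline (defaults follow the assay)."""

    peak_window_s: float = 20.0
    rolling_window: int = 5
    artifact_mad_k: float = 5.0
    artifact_local_window_s: float = 1.0
    #: gate artifact candidates to within this many frames of a scheduled pulse
    artifact_schedule_gate_frames: int = 1
    #: minimum usable baseline window length in seconds
    min_baseline_s: float = 1.0
    #: recordings whose Ca2+ peak dF/F0 falls below this are QC-flagged
    min_ca_peak_dff0: float = 0.2


@dataclass
class NormalizedTraces:
    """Baseline-normalized FRET-ratio and Ca2+ series."""

    times: np.ndarray
    dRR0: np.ndarray
    dFF0: np.ndarray
    R0: float
    F0: float
    repaired_frames: np.ndarray


@dataclass
class KineticsResult:
    """Per-recording kinetics metrics for the FRET and Ca2+ channels."""

    roi_id: str = ""
    genotype: str = ""
    peak_dRR0: float = np.nan
    peak_time: float = np.nan
    half_rise: float | None = None
    half_decay: float | None = None
    peak_dFF0: float = np.nan
    ca_peak_time: float = np.nan
    ca_half_rise: float | None = None
    ca_half_decay: float | None = None
    qc_flags: list = field(default_factory=list)
    #: intermediate series for audit (raw->corrected->smoothed->normalized)
    audit: dict = field(default_factory=dict)


def subtract_background(record: TraceRecord) -> TraceRecord:
    """Subtract the cell-free background from every channel.

    Frames driven to zero or below are left in place but flagged, so
    downstream steps (which require positive YFP) fail loudly rather than
    silently.
    """
    new = {}
    nonpos = False
    for name, series in record.channels().items():
        bg = getattr(record, f"background_{name}")
        bg = np.asarray(bg, dtype=float)
        if bg.ndim == 1 and len(bg) != len(series):
            raise DataError(f"background_{name} length {len(bg)} != series length {len(series)}")
        out = series - bg
        nonpos = nonpos or bool(np.any(out <= 0))
        new[name] = out
    rec = record.with_channels(**new, extra_flags=(["nonpositive_after_background"] if nonpos else []))
    rec = replace(rec, background_cfp=0.0, background_yfp=0.0, background_rfp=0.0)
    rec.flags = list(rec.flags)
    return rec


def _local_median_mad(x: np.ndarray, half_width: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame median and MAD over a centered window (edges reflected)."""
    w = 2 * half_width + 1
    if len(x) <= w:
        med = np.full_like(x, np.median(x))
        mad = np.full_like(x, np.median(np.abs(x - np.median(x))))
        return med, mad
    pad = np.pad(x, half_width, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(pad, w)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    return med, mad


def repair_artifacts(record: TraceRecord, options: KineticsOptions = KineticsOptions()) -> tuple[TraceRecord, np.ndarray]:
    """Detect and repair uncaging-light artifact frames.

    A frame is artifactual when any raw channel exceeds
    ``local median + k * local MAD`` (robust threshold over a +-1 s window)
    and, when a stimulus schedule is available, the frame lies within one
    frame of a scheduled pulse.  Flagged frames are replaced in all
    channels by linear interpolation between the nearest unflagged
    neighbours; flagged frames at the edges take the nearest unflagged
    value.
    """
    n = record.n_frames
    if n < 3:
        raise DataError("artifact repair needs at least 3 frames")
    dt = record.frame_interval
    half_width = max(1, int(round(options.artifact_local_window_s / dt)))

    over = np.zeros(n, dtype=bool)
    for series in record.channels().values():
        med, mad = _local_median_mad(series, half_width)
        over |= series > med + options.artifact_mad_k * mad

    if record.protocol is not None:
        gate_dist = (options.artifact_schedule_gate_frames + 0.5) * dt
        pulses = record.protocol.pulse_times
        idx = np.searchsorted(pulses, record.frame_times)
        dist = np.full(n, np.inf)
        left_ok = idx > 0
        dist[left_ok] = record.frame_times[left_ok] - pulses[idx[left_ok] - 1]
        right_ok = idx < len(pulses)
        dist[right_ok] = np.minimum(dist[right_ok], pulses[idx[right_ok]] - record.frame_times[right_ok])
        over &= dist <= gate_dist

    if over.all():
        raise DataError("every frame was flagged as artifactual")

    repaired = np.flatnonzero(over)
    if len(repaired) == 0:
        return record.with_channels(), repaired

    keep = ~over
    t = record.frame_times
    new = {}
    for name, series in record.channels().items():
        fixed = series.copy()
        fixed[over] = np.interp(t[over], t[keep], series[keep])
        new[name] = fixed
    rec = record.with_channels(**new, extra_flags=[f"repaired_{len(repaired)}_frames"])
    return rec, repaired


def rolling_average(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving mean; edge windows shrink symmetrically.

    ``window`` must be odd so the mean is centered; output length equals
    input length.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidArgumentError(f"window must be odd and >= 1, got {window}")
    series = np.asarray(series, dtype=float)
    kernel = np.ones(window)
    sums = np.convolve(series, kernel, mode="same")
    counts = np.convolve(np.ones_like(series), kernel, mode="same")
    return sums / counts


def normalize(record: TraceRecord) -> NormalizedTraces:
    """Compute dR/R0 (FRET ratio) and dF/F0 (Ca2+) against the pre-stimulus baseline."""
    if np.any(record.yfp <= 0):
        bad = int(np.flatnonzero(record.yfp <= 0)[0])
        raise DataError(f"YFP is non-positive at frame {bad}; cannot form CFP/YFP ratio")
    mask = record.baseline_mask()
    if not mask.any():
        raise DataError("baseline window contains no frames")
    R = record.cfp / record.yfp
    R0 = float(np.mean(R[mask]))
    if R0 <= 0:
        raise DataError("baseline FRET ratio R0 must be positive")
    F0 = float(np.mean(record.rfp[mask]))
    if F0 <= 0:
        raise DataError("baseline Ca2+ fluorescence F0 must be positive")
    return NormalizedTraces(
        times=record.frame_times,
        dRR0=(R - R0) / R0,
        dFF0=(record.rfp - F0) / F0,
        R0=R0,
        F0=F0,
        repaired_frames=np.array([], dtype=int),
    )


def detect_peak(series, times, onset: float, window: float = 20.0):
    """Maximum of ``series`` within ``[onset, onset + window]``.

    Ties resolve to the earliest frame.  Returns
    ``(value, time, truncated)`` where ``truncated`` reports that the
    recording ended before the window did.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    sel = (times >= onset) & (times <= onset + window)
    if not sel.any():
        raise DataError("no frames within the peak-search window")
    truncated = times[-1] < onset + window
    vals = series[sel]
    ts = times[sel]
    i = int(np.argmax(vals))
    return float(vals[i]), float(ts[i]), bool(truncated)


def half_rise_time(series, times, onset: float, peak_value: float, peak_time: float):
    """Midpoint-defined half-rise time from stimulus onset, or None.

    Restricted to ``[onset, peak_time]``: the midpoint between the first
    frame strictly above half-peak and the last frame strictly below
    half-peak, measured from onset.  Comparisons are strict; frames
    exactly at half-peak belong to neither set.
    """
    if not (peak_value > 0):
        return None
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    sel = (times >= onset) & (times <= peak_time)
    vals, ts = series[sel], times[sel]
    half = peak_value / 2.0
    above = ts[vals > half]
    below = ts[vals < half]
    if len(above) == 0:
        return None
    t_first = float(above[0])
    t_last = float(below[-1]) if len(below) else float(onset)
    return (t_first + t_last) / 2.0 - onset


def half_decay_time(series, times, peak_value: float, peak_time: float):
    """Midpoint-defined half-decay time from the peak, or None if undetermined.

    Restricted to ``[peak_time, end]``: the midpoint between the first
    frame strictly below half-peak and the last frame strictly above
    half-peak, measured from the peak.  Returns None when the trace never
    decays below half-peak before the recording ends.
    """
    if not (peak_value > 0):
        return None
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    sel = times >= peak_time
    vals, ts = series[sel], times[sel]
    half = peak_value / 2.0
    below = ts[vals < half]
    above = ts[vals > half]
    if len(below) == 0:
        return None
    t_first = float(below[0])
    t_last = float(above[-1]) if len(above) else float(peak_time)
    return (t_first + t_last) / 2.0 - peak_time


def analyze_recording(record: TraceRecord, options: KineticsOptions = KineticsOptions()) -> KineticsResult:
    """Run the full per-recording pipeline and extract kinetics metrics.

    Stages: background subtraction -> artifact repair -> per-channel
    rolling average -> ratio/baseline normalization -> peak and half-time
    metrics for both the FRET (dR/R0) and Ca2+ (dF/F0) channels.  All
    intermediate series are kept in ``result.audit``.
    """
    if record.protocol is None:
        raise DataError("analyze_recording requires a stimulus protocol on the record")
    onset = record.protocol.onset_time

    bg = subtract_background(record)
    repaired_rec, repaired = repair_artifacts(bg, options)
    smoothed = repaired_rec.with_channels(
        cfp=rolling_average(repaired_rec.cfp, options.rolling_window),
        yfp=rolling_average(repaired_rec.yfp, options.rolling_window),
        rfp=rolling_average(repaired_rec.rfp, options.rolling_window),
    )
    norm = normalize(smoothed)
    norm.repaired_frames = repaired

    qc = list(record.flags) + list(smoothed.flags)

    peak, peak_t, truncated = detect_peak(norm.dRR0, norm.times, onset, options.peak_window_s)
    if truncated:
        qc.append("peak_window_truncated")
    rise = half_rise_time(norm.dRR0, norm.times, onset, peak, peak_t)
    decay = half_decay_time(norm.dRR0, norm.times, peak, peak_t)
    if rise is None:
        qc.append("rise_undetermined")
    if decay is None:
        qc.append("decay_undetermined")

    ca_peak, ca_peak_t, _ = detect_peak(norm.dFF0, norm.times, onset, options.peak_window_s)
    ca_rise = half_rise_time(norm.dFF0, norm.times, onset, ca_peak, ca_peak_t)
    ca_decay = half_decay_time(norm.dFF0, norm.times, ca_peak, ca_peak_t)
    if ca_decay is None:
        qc.append("ca_decay_undetermined")
    if ca_peak < options.min_ca_peak_dff0:
        qc.append("little_ca_response")

    return KineticsResult(
        roi_id=record.roi_id,
        genotype=record.genotype,
        peak_dRR0=peak,
        peak_time=peak_t,
        half_rise=rise,
        half_decay=decay,
        peak_dFF0=ca_peak,
        ca_peak_time=ca_peak_t,
        ca_half_rise=ca_rise,
        ca_half_decay=ca_decay,
        qc_flags=qc,
        audit={
            "background_subtracted": bg.channels(),
            "repaired": repaired_rec.channels(),
            "repaired_frames": repaired,
            "smoothed": smoothed.channels(),
            "dRR0": norm.dRR0,
            "dFF0": norm.dFF0,
            "R0": norm.R0,
            "F0": norm.F0,
        },
    )
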