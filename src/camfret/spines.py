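"""Dendritic-spine quantification: enrichment index, QC filters, peaks, ratio images.

The enrichment index uses baseline YFP (sensor amount) and baseline RFP
(volume proxy) intensities in the spine and the adjacent shaft:

    enrichment = (YFP_spine / RFP_spine) / (YFP_shaft / RFP_shaft).

Spines are excluded when the FRET probe photo-damaged or darkened after
stimulation (CFP < 85% of baseline, or YFP < 85% and CFP < 90%) or when
the baseline Ca2+ indicator is too dim to serve as a volume proxy
(baseline mean < 2 x baseline SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .errors import DataError, StatsError

__all__ = [
    "SpineRecord",
    "ExclusionDecision",
    "RatioImage",
    "spine_enrichment_index",
    "apply_exclusion_filters",
    "spine_peak_amplitude",
    "render_ratio_image",
    "soma_ratio_image",
    "cumulative_distribution_compare",
    "measure_spine_stack",
]


@dataclass
class SpineRecord:
    """One spine's baseline intensities and response traces (background-subtracted)."""

    spine_id: str
    neuron_id: str
    hk2a_spine: float
    rcamp_spine: float
    hk2a_shaft: float
    rcamp_shaft: float
    cfp: np.ndarray
    yfp: np.ndarray
    rfp: np.ndarray
    frame_times: np.ndarray
    stim_end_frame: int
    baseline_frames: np.ndarray | None = None  # boolean mask; default: frames before stimulation

    def __post_init__(self):
        self.cfp = np.asarray(self.cfp, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        self.rfp = np.asarray(self.rfp, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        n = len(self.frame_times)
        if not (0 <= self.stim_end_frame < n):
            raise DataError(f"stim_end_frame {self.stim_end_frame} outside recording of {n} frames")
        if self.baseline_frames is None:
            self.baseline_frames = np.arange(n) < max(1, self.stim_end_frame // 2)
        self.baseline_frames = np.asarray(self.baseline_frames, dtype=bool)


@dataclass
class ExclusionDecision:
    excluded: bool
    reason: str  # "none" | "fret_decrease" | "dim_rcamp"
    metrics: dict = field(default_factory=dict)


@dataclass
class RatioImage:
    """Pixel map of dR/R0 (defined inside the mask, NaN outside)."""

    values: np.ndarray
    mask: np.ndarray
    epoch: str
    frames_averaged: int


def spine_enrichment_index(rec: SpineRecord) -> float:
    """Sensor-over-volume quotient of spine vs adjacent shaft."""
    vals = (rec.hk2a_spine, rec.rcamp_spine, rec.hk2a_shaft, rec.rcamp_shaft)
    if any(not np.isfinite(v) or v <= 0 for v in vals):
        raise DataError(f"spine {rec.spine_id}: enrichment needs four positive baseline intensities, got {vals}")
    return (rec.hk2a_spine / rec.rcamp_spine) / (rec.hk2a_shaft / rec.rcamp_shaft)


def apply_exclusion_filters(
    rec: SpineRecord,
    post_window: int = 5,
    cfp_hard: float = 0.85,
    yfp_soft: float = 0.85,
    cfp_soft: float = 0.90,
    rcamp_sd_mult: float = 2.0,
) -> ExclusionDecision:
    """QC decision for one spine.

    The probe-darkening filter compares mean CFP/YFP over the
    ``post_window`` frames starting at the end of stimulation (the same
    window used for peak measurement) against the baseline means; it is
    evaluated before the dim-indicator filter, so each spine lands in
    exactly one category.
    """
    base = rec.baseline_frames
    if not base.any():
        raise DataError(f"spine {rec.spine_id}: empty baseline window")
    post = slice(rec.stim_end_frame, rec.stim_end_frame + post_window)

    cfp_ratio = float(np.mean(rec.cfp[post]) / np.mean(rec.cfp[base]))
    yfp_ratio = float(np.mean(rec.yfp[post]) / np.mean(rec.yfp[base]))
    metrics = {"cfp_post_over_base": cfp_ratio, "yfp_post_over_base": yfp_ratio}

    if cfp_ratio < cfp_hard or (yfp_ratio < yfp_soft and cfp_ratio < cfp_soft):
        return ExclusionDecision(True, "fret_decrease", metrics)

    base_rfp = rec.rfp[base]
    mean_rfp = float(np.mean(base_rfp))
    sd_rfp = float(np.std(base_rfp, ddof=1)) if base_rfp.size > 1 else 0.0
    metrics.update({"rfp_base_mean": mean_rfp, "rfp_base_sd": sd_rfp})
    if mean_rfp < rcamp_sd_mult * sd_rfp:
        return ExclusionDecision(True, "dim_rcamp", metrics)

    return ExclusionDecision(False, "none", metrics)


def spine_peak_amplitude(series, stim_end_frame: int, n_frames: int = 5):
    """Maximum of a normalized series over ``n_frames`` frames from stimulation end.

    Returns ``(value, qc_flags)``; the window is truncated (and flagged)
    when fewer frames remain.
    """
    series = np.asarray(series, dtype=float)
    if not (0 <= stim_end_frame < len(series)):
        raise DataError(f"stim_end_frame {stim_end_frame} outside series of {len(series)} frames")
    window = series[stim_end_frame : stim_end_frame + n_frames]
    flags = []
    if len(window) < n_frames:
        flags.append("peak_window_truncated")
    return float(np.max(window)), flags


def _ratio_frames(cfp_frames: np.ndarray, yfp_frames: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-filter each channel frame, then ratio (per frame)."""
    out = np.empty_like(cfp_frames, dtype=float)
    for i in range(len(cfp_frames)):
        c = ndimage.gaussian_filter(cfp_frames[i].astype(float), sigma=sigma, truncate=4.0)
        y = ndimage.gaussian_filter(yfp_frames[i].astype(float), sigma=sigma, truncate=4.0)
        out[i] = c / np.where(y == 0, np.nan, y)
    return out


def _default_mask_threshold(baseline_yfp_mean: np.ndarray) -> float:
    """Cellular-mask threshold: median + 5*MAD of the image border (background)."""
    border = np.concatenate(
        [
            baseline_yfp_mean[:3].ravel(),
            baseline_yfp_mean[-3:].ravel(),
            baseline_yfp_mean[:, :3].ravel(),
            baseline_yfp_mean[:, -3:].ravel(),
        ]
    )
    med = float(np.median(border))
    mad = float(np.median(np.abs(border - med)))
    return med + 5.0 * mad


def render_ratio_image(
    cfp_stack: np.ndarray,
    yfp_stack: np.ndarray,
    baseline_frames,
    epoch_frames,
    epoch: str = "post_immediate",
    sigma: float = 1.0,
    mask_threshold: float | None = None,
    frames: int = 3,
) -> RatioImage:
    """dR/R0 pixel image for one epoch.

    Per frame: Gaussian-filter (sigma in px, truncated at 4 sigma) each
    channel, ratio, divide by the pre-stimulus mean-ratio image; the
    first ``frames`` epoch frames are averaged, 1 is subtracted to give
    dR/R0, and pixels whose baseline YFP falls below the cellular-mask
    threshold (default: border median + 5 MAD) are removed.
    """
    epoch_frames = np.asarray(epoch_frames)
    if len(epoch_frames) < frames:
        raise DataError(f"epoch has {len(epoch_frames)} frames; needs >= {frames}")
    baseline_frames = np.asarray(baseline_frames)

    # pixels with zero YFP (outside any signal) become NaN and are dropped
    # by the mask; silence the expected all-NaN / 0-division warnings
    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        r0 = np.nanmean(_ratio_frames(cfp_stack[baseline_frames], yfp_stack[baseline_frames], sigma), axis=0)
        r = np.nanmean(
            _ratio_frames(cfp_stack[epoch_frames[:frames]], yfp_stack[epoch_frames[:frames]], sigma), axis=0
        )
        drr0 = r / r0 - 1.0

    baseline_yfp = yfp_stack[baseline_frames].mean(axis=0)
    thr = _default_mask_threshold(baseline_yfp) if mask_threshold is None else float(mask_threshold)
    mask = baseline_yfp > thr
    if not mask.any():
        raise DataError("cellular mask is empty at the given threshold")
    values = np.where(mask, drr0, np.nan)
    return RatioImage(values=values, mask=mask, epoch=epoch, frames_averaged=frames)


def soma_ratio_image(
    cfp_stack: np.ndarray,
    yfp_stack: np.ndarray,
    artifact_frames: np.ndarray,
    baseline_frames,
    epoch_frames,
    epoch: str = "post_immediate",
    sigma: float = 1.0,
    mask_threshold: float | None = None,
    frames: int = 10,
) -> RatioImage:
    """Somatic dR/R0 image: averages ``frames`` artifact-free frames per epoch."""
    artifact_frames = np.asarray(artifact_frames, dtype=bool)
    base = np.asarray(baseline_frames)
    base = base[~artifact_frames[base]]
    ep = np.asarray(epoch_frames)
    ep = ep[~artifact_frames[ep]]
    if len(ep) < frames:
        raise DataError(f"epoch has only {len(ep)} artifact-free frames; needs >= {frames}")
    return render_ratio_image(
        cfp_stack, yfp_stack, base, ep, epoch=epoch, sigma=sigma, mask_threshold=mask_threshold, frames=frames
    )


def cumulative_distribution_compare(wt_values, mut_values) -> dict:
    """Two-sample Kolmogorov-Smirnov plus unpaired t on spine peak amplitudes."""
    wt = np.asarray(wt_values, dtype=float)
    mut = np.asarray(mut_values, dtype=float)
    if len(wt) < 5 or len(mut) < 5:
        raise StatsError("need at least 5 spines per group")
    ks = sps.ks_2samp(wt, mut, method="auto")
    tt = sps.ttest_ind(wt, mut, equal_var=True)
    return {
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "t_stat": float(tt.statistic),
        "t_p": float(tt.pvalue),
        "n_wt": len(wt),
        "n_mut": len(mut),
    }


def measure_spine_stack(stack, n_baseline_frames: int, stim_end_frame: int, spine_id="spine0", neuron_id="n0") -> SpineRecord:
    """Extract a :class:`SpineRecord` from a rendered spine stack.

    ROI means per frame for the spine disc and the shaft band; background
    taken as the mean of a cell-free corner and subtracted from both the
    traces and the baseline intensities.
    """
    geom = stack.geometry
    spine = geom.spine_mask()
    shaft = geom.shaft_mask()
    corner = np.zeros(geom.shape, dtype=bool)
    corner[:6, -6:] = True

    def roi_trace(channel, mask):
        return channel[:, mask].mean(axis=1)

    bg = {name: roi_trace(stack.channel(name), corner) for name in ("cfp", "yfp", "rfp")}
    spine_tr = {name: roi_trace(stack.channel(name), spine) - bg[name] for name in ("cfp", "yfp", "rfp")}
    shaft_tr = {name: roi_trace(stack.channel(name), shaft) - bg[name] for name in ("cfp", "yfp", "rfp")}

    base = np.arange(len(stack.frame_times)) < n_baseline_frames
    return SpineRecord(
        spine_id=spine_id,
        neuron_id=neuron_id,
        hk2a_spine=float(spine_tr["yfp"][base].mean()),
        rcamp_spine=float(spine_tr["rfp"][base].mean()),
        hk2a_shaft=float(shaft_tr["yfp"][base].mean()),
        rcamp_shaft=float(shaft_tr["rfp"][base].mean()),
        cfp=spine_tr["cfp"],
        yfp=spine_tr["yfp"],
        rfp=spine_tr["rfp"],
        frame_times=stack.frame_times,
        stim_end_frame=stim_end_frame,
        baseline_frames=base,
    )
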