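"""Reference benchmark: calibrated-simulation reproduction of the printed metrics.

Stage A calibrates the WT and P212L presets against the printed somatic
anchors (peak dR/R0 and half-decay under 50 pulses at 20 Hz), then
measures what noisy simulated cohorts recover through the full trace
pipeline.  Stage B re-uses the same presets on protocols they were never
calibrated on (half-rise; 30-pulse trains at 5 and 20 Hz), making those
quantities genuine model predictions.  Shared by the acceptance script
and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from .io import kinetics_results_frame
from .kinetics import analyze_recording
from .protocol import SOMA_50_AT_20HZ, StimulusProtocol
from .simulate import CALIBRATION_TARGETS, KinaseModelParams, calibrate_preset, simulate_cohort

__all__ = ["calibrate_wt_p212l", "cohort_metrics", "benchmark_targets"]


def calibrate_wt_p212l() -> dict[str, KinaseModelParams]:
    """Stage A: calibrate both presets from the printed anchors."""
    out = {}
    for geno in ("WT", "P212L"):
        res = calibrate_preset(CALIBRATION_TARGETS[geno], KinaseModelParams(genotype=geno))
        out[geno] = res.params
    return out


def cohort_metrics(params: KinaseModelParams, protocol: StimulusProtocol, n: int, base_seed: int):
    """Simulate a noisy cohort, run the pipeline, return group-mean metrics."""
    records = simulate_cohort(params, protocol, n, base_seed=base_seed)
    df = kinetics_results_frame([analyze_recording(r) for r in records])
    return {
        "peak_drr0": float(df["peak_drr0"].mean()),
        "half_rise_s": float(df["half_rise_s"].mean()),
        "half_decay_s": float(df["half_decay_s"].mean()),
        "peak_dff0": float(df["peak_dff0"].mean()),
        "n": int(len(df)),
    }


def benchmark_targets(seed: int = 1) -> dict[str, dict]:
    """Recompute every benchmark quantity from scratch.

    Returns ``{target_id: {"value": ..., "n": ...}}`` with the group-mean
    metrics on the scale the assay reports (dR/R0 fractions, seconds).
    """
    seed = int(seed)
    presets = calibrate_wt_p212l()

    wt_cohort = cohort_metrics(presets["WT"], SOMA_50_AT_20HZ, 19, base_seed=seed)
    pl_cohort = cohort_metrics(presets["P212L"], SOMA_50_AT_20HZ, 19, base_seed=seed + 100)
    pl_5hz = cohort_metrics(
        presets["P212L"], StimulusProtocol(n_pulses=30, frequency=5.0, onset_time=5.0), 16, base_seed=seed + 200
    )
    wt_20hz = cohort_metrics(
        presets["WT"], StimulusProtocol(n_pulses=30, frequency=20.0, onset_time=5.0), 16, base_seed=seed + 300
    )

    return {
        "t1": {"value": wt_cohort["peak_drr0"], "n": wt_cohort["n"]},
        "t2": {"value": pl_cohort["peak_drr0"], "n": pl_cohort["n"]},
        "t3": {"value": wt_cohort["half_rise_s"], "n": wt_cohort["n"]},
        "t4": {"value": pl_cohort["half_decay_s"], "n": pl_cohort["n"]},
        "t7": {"value": wt_cohort["half_decay_s"], "n": wt_cohort["n"]},
        "t5": {"value": pl_5hz["peak_drr0"], "n": pl_5hz["n"]},
        "t6": {"value": wt_20hz["peak_drr0"], "n": wt_20hz["n"]},
    }
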