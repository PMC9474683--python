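"""Trace pipeline unit tests: each stage against closed forms and brute-force oracles."""

import numpy as np
import pytest

from camfret.errors import DataError, InvalidArgumentError
from camfret.kinetics import (
    KineticsOptions,
    analyze_recording,
    detect_peak,
    half_decay_time,
    half_rise_time,
    normalize,
    repair_artifacts,
    rolling_average,
    subtract_background,
)
from camfret.protocol import StimulusProtocol
from camfret.simulate import SOMA_ACQUISITION, simulate_recording

from conftest import make_record


# ---------------------------------------------------------------- background
def test_background_zero_is_identity():
    rec = make_record([1.0, 2.0, 3.0])
    out = subtract_background(rec)
    assert np.array_equal(out.cfp, rec.cfp)


def test_constant_background_shifts_every_frame():
    rec = make_record([10.0, 20.0, 30.0], background_cfp=5.0)
    assert np.array_equal(subtract_background(rec).cfp, [5.0, 15.0, 25.0])


def test_series_background_elementwise_oracle():
    rng = np.random.default_rng(0)
    x = rng.uniform(50, 100, 64)
    bg = rng.uniform(0, 10, 64)
    rec = make_record(x, background_cfp=bg)
    out = subtract_background(rec)
    assert np.array_equal(out.cfp, x - bg)  # independent element-wise oracle


def test_background_driving_nonpositive_is_flagged():
    rec = make_record([1.0, 2.0, 3.0], background_cfp=2.0)
    assert "nonpositive_after_background" in subtract_background(rec).flags


# ------------------------------------------------------------ artifact repair
def test_clean_record_repair_is_identity():
    rng = np.random.default_rng(1)
    rec = make_record(100 + rng.normal(0, 1, 200), times=np.arange(200) / 25.0)
    out, repaired = repair_artifacts(rec)
    assert len(repaired) == 0
    assert np.array_equal(out.cfp, rec.cfp)


def test_single_spike_replaced_by_linear_midpoint():
    prot = StimulusProtocol(n_pulses=1, frequency=1.0, onset_time=5.0)
    times = np.arange(0, 10, 0.04)
    cfp = np.full(len(times), 10.0)
    i = np.argmin(np.abs(times - 5.0))
    cfp[i - 1] = 10.0
    cfp[i + 1] = 20.0
    cfp[i] = 1000.0  # spike at the pulse frame
    base = np.where(np.arange(len(times)) > i, 20.0, 10.0)
    base[i] = 1000.0
    rec = make_record(base, protocol=prot, times=times, baseline_window=(0.0, 4.0))
    out, repaired = repair_artifacts(rec)
    assert i in repaired
    assert out.cfp[i] == pytest.approx(15.0)


def test_repair_recall_and_false_positive_rate_against_truth():
    # weak-response protocol, artifact = 10x noise SD
    prot = StimulusProtocol(n_pulses=30, frequency=2.5, onset_time=5.0)
    acq = SOMA_ACQUISITION.replace(
        noise_sd_per_channel=10.0, artifact_magnitude=100.0, duration=30.0
    )
    from camfret.simulate import get_preset

    recalls, fps, total_neg = [], 0, 0
    for seed in range(5):
        rec = simulate_recording(get_preset("WT"), prot, acq=acq, rng=np.random.default_rng(seed))
        rec = subtract_background(rec)
        _, repaired = repair_artifacts(rec)
        truth = np.flatnonzero(rec.artifact_truth)
        hit = np.isin(truth, repaired).sum()
        recalls.append(hit / len(truth))
        fps += np.isin(repaired, truth, invert=True).sum()
        total_neg += rec.n_frames - len(truth)
    assert np.mean(recalls) >= 0.95
    assert fps / total_neg <= 0.01


def test_too_few_frames_for_repair_is_error():
    with pytest.raises(DataError):
        repair_artifacts(make_record([1.0, 2.0]))


def test_repair_idempotent_on_repaired_output(wt_params, soma_protocol):
    rec = simulate_recording(
        wt_params, soma_protocol, rng=np.random.default_rng(3),
        acq=SOMA_ACQUISITION.replace(duration=30.0),
    )
    rec = subtract_background(rec)
    once, rep1 = repair_artifacts(rec)
    twice, rep2 = repair_artifacts(once)
    assert len(rep2) == 0
    for ch in ("cfp", "yfp", "rfp"):
        assert np.array_equal(getattr(once, ch), getattr(twice, ch))


# ------------------------------------------------------------ rolling average
def test_rolling_average_constant_unchanged():
    x = np.full(20, 3.7)
    assert np.allclose(rolling_average(x, 5), 3.7)


def test_rolling_average_impulse_spreads_fifth():
    x = np.zeros(11)
    x[5] = 1.0
    out = rolling_average(x, 5)
    assert np.allclose(out[3:8], 0.2)
    assert np.allclose(out[[0, 1, 2, 8, 9, 10]], 0.0)


def test_rolling_average_interior_matches_bruteforce():
    rng = np.random.default_rng(2)
    x = rng.normal(size=100)
    out = rolling_average(x, 5)
    for i in range(2, 98):
        assert out[i] == pytest.approx(np.mean(x[i - 2 : i + 3]), rel=1e-12)
    # shrunken edges
    assert out[0] == pytest.approx(np.mean(x[:3]))
    assert out[-1] == pytest.approx(np.mean(x[-3:]))


def test_rolling_average_even_window_rejected():
    with pytest.raises(InvalidArgumentError):
        rolling_average(np.zeros(10), 4)


# ------------------------------------------------------------------ normalize
def test_constant_ratio_normalizes_to_zero():
    prot = StimulusProtocol(n_pulses=1, frequency=1.0, onset_time=5.0)
    rec = make_record(np.full(100, 50.0), yfp=np.full(100, 100.0), times=np.arange(100) / 10.0, protocol=prot)
    norm = normalize(rec)
    assert np.allclose(norm.dRR0, 0.0)
    assert norm.R0 == pytest.approx(0.5)


def test_ratio_doubling_gives_drr0_of_one():
    prot = StimulusProtocol(n_pulses=1, frequency=1.0, onset_time=5.0)
    cfp = np.full(100, 50.0)
    cfp[60:] = 100.0
    rec = make_record(cfp, yfp=np.full(100, 100.0), times=np.arange(100) / 10.0, protocol=prot)
    assert np.allclose(normalize(rec).dRR0[60:], 1.0)


def test_nonpositive_yfp_is_data_error_naming_frame():
    prot = StimulusProtocol(n_pulses=1, frequency=1.0, onset_time=5.0)
    yfp = np.full(100, 100.0)
    yfp[42] = 0.0
    rec = make_record(np.full(100, 50.0), yfp=yfp, times=np.arange(100) / 10.0, protocol=prot)
    with pytest.raises(DataError, match="42"):
        normalize(rec)


def test_normalized_fret_matches_closed_form_of_rendered_gain(wt_params, soma_protocol, noise_free_acq):
    # dR/R0 of a noise-free rendering must equal (1+gA)/(1-gA)-1 for the
    # smoothed activation (channel smoothing is linear in A)
    from camfret.simulate import CalciumParams, simulate_ca_transient, simulate_kinase

    rec = simulate_recording(wt_params, soma_protocol, acq=noise_free_acq)
    res = analyze_recording(rec)
    t, ca = simulate_ca_transient(soma_protocol, CalciumParams(), noise_free_acq.duration, dt=0.002)
    A = simulate_kinase(ca, t, 1.0, wt_params).sample_activation(rec.frame_times)
    A = rolling_average(A, 5)
    g = wt_params.fret_gain
    expected = (1 + g * A) / (1 - g * A)
    expected = expected / expected[rec.baseline_mask()].mean() - 1
    assert np.allclose(res.audit["dRR0"], expected, atol=5e-3 * max(expected.max(), 1e-9))


# ---------------------------------------------------------------- peak finder
def test_triangle_peak_apex():
    times = np.arange(0, 10, 0.1)
    series = np.minimum(times, 6.0 - times * 0.5)  # rises then falls
    v, t, trunc = detect_peak(series, times, onset=0.0, window=20.0)
    assert trunc
    i = np.argmax(series)
    assert (v, t) == (series[i], times[i])


def test_equal_maxima_earlier_wins():
    times = np.arange(10.0)
    series = np.array([0, 1, 5, 2, 5, 1, 0, 0, 0, 0], dtype=float)
    v, t, _ = detect_peak(series, times, onset=0.0, window=20.0)
    assert v == 5.0 and t == 2.0


def test_peak_equals_bruteforce_slice_max():
    rng = np.random.default_rng(5)
    times = np.arange(0, 40, 0.04)
    series = rng.normal(size=len(times))
    onset = 5.0
    v, t, _ = detect_peak(series, times, onset, window=20.0)
    sel = (times >= onset) & (times <= onset + 20.0)
    assert v == series[sel].max()


# ------------------------------------------------------------- half-rise/decay
def crossing_scan_rise(series, times, onset, peak_value, peak_time):
    """Exhaustive scan oracle for the midpoint half-rise definition."""
    half = peak_value / 2.0
    first_above = None
    last_below = None
    for v, t in zip(series, times):
        if t < onset or t > peak_time:
            continue
        if v > half and first_above is None:
            first_above = t
        if v < half:
            last_below = t
    if first_above is None:
        return None
    if last_below is None:
        last_below = onset
    return (first_above + last_below) / 2.0 - onset


def crossing_scan_decay(series, times, peak_value, peak_time):
    half = peak_value / 2.0
    first_below = None
    last_above = None
    for v, t in zip(series, times):
        if t < peak_time:
            continue
        if v < half and first_below is None:
            first_below = t
        if v > half:
            last_above = t
    if first_below is None:
        return None
    if last_above is None:
        last_above = peak_time
    return (first_below + last_above) / 2.0 - peak_time


def test_linear_ramp_half_rise():
    times = np.arange(0, 2.001, 0.001)
    series = times / 2.0
    hr = half_rise_time(series, times, onset=0.0, peak_value=1.0, peak_time=2.0)
    assert hr == pytest.approx(1.0, abs=0.002)


def test_step_to_peak_half_rise_is_half_frame():
    times = np.arange(0, 1.0, 0.1)
    series = np.zeros(10)
    series[1:] = 1.0
    hr = half_rise_time(series, times, onset=0.0, peak_value=1.0, peak_time=0.1)
    assert hr == pytest.approx(0.05)


def test_noisy_half_times_match_exhaustive_scan():
    rng = np.random.default_rng(7)
    for _ in range(200):
        times = np.arange(0, 30, 0.04)
        base = np.interp(times, [0, 5, 8, 30], [0, 0, 1, 0.0])
        series = base + rng.normal(0, 0.15, len(times))
        pv, pt, _ = detect_peak(series, times, onset=5.0, window=20.0)
        assert half_rise_time(series, times, 5.0, pv, pt) == pytest.approx(
            crossing_scan_rise(series, times, 5.0, pv, pt)
        )
        got = half_decay_time(series, times, pv, pt)
        want = crossing_scan_decay(series, times, pv, pt)
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want)


def test_exponential_half_decay_is_tau_ln2():
    tau = 10.0
    times = np.arange(0, 120, 0.001)
    series = np.exp(-times / tau)
    hd = half_decay_time(series, times, peak_value=1.0, peak_time=0.0)
    assert hd == pytest.approx(tau * np.log(2), abs=0.01)


@pytest.mark.parametrize("rate", [4.0, 25.0, 250.0])
def test_half_decay_converges_with_frame_rate(rate):
    tau = 10.0
    times = np.arange(0, 120, 1.0 / rate)
    series = np.exp(-times / tau)
    hd = half_decay_time(series, times, 1.0, 0.0)
    assert hd == pytest.approx(tau * np.log(2), abs=1.0 / rate + 1e-9)


def test_trace_ending_above_half_peak_is_undetermined():
    times = np.arange(0, 10, 0.1)
    series = np.exp(-times / 100.0)
    assert half_decay_time(series, times, 1.0, 0.0) is None


# ----------------------------------------------------------- full pipeline
def test_noise_free_simulation_recovers_ground_truth_metrics(wt_params, soma_protocol, noise_free_acq):
    from camfret.simulate import noise_free_metrics

    rec = simulate_recording(wt_params, soma_protocol, acq=noise_free_acq)
    res = analyze_recording(rec)
    # calibration stores what the pipeline recovers; agree to 2 %
    ref = noise_free_metrics(wt_params, soma_protocol)
    assert res.peak_dRR0 == pytest.approx(ref["peak_drr0"], rel=0.02)
    assert res.half_decay == pytest.approx(ref["half_decay_s"], rel=0.02)


def test_undetermined_decay_sets_qc_flag(wt_params, soma_protocol):
    # truncate the recording right after the peak so decay cannot complete
    acq = SOMA_ACQUISITION.replace(noise_sd_per_channel=0.0, artifact_magnitude=0.0, duration=9.0)
    rec = simulate_recording(wt_params, soma_protocol, acq=acq)
    res = analyze_recording(rec)
    assert res.half_decay is None
    assert "decay_undetermined" in res.qc_flags


def test_smoothing_order_changes_peak_below_one_percent(wt_params, soma_protocol, noise_free_acq):
    rec = simulate_recording(wt_params, soma_protocol, acq=noise_free_acq)
    res = analyze_recording(rec)
    # alternative order: ratio first, then smooth the ratio
    bg = subtract_background(rec)
    rep, _ = repair_artifacts(bg)
    ratio = rolling_average(rep.cfp / rep.yfp, 5)
    r0 = ratio[rec.baseline_mask()].mean()
    drr0 = ratio / r0 - 1
    alt_peak, _, _ = detect_peak(drr0, rec.frame_times, soma_protocol.onset_time, 20.0)
    assert alt_peak == pytest.approx(res.peak_dRR0, rel=0.01)


def test_scale_invariance_of_drr0(wt_params, soma_protocol, noise_free_acq):
    rec = simulate_recording(wt_params, soma_protocol, acq=noise_free_acq)
    scaled = type(rec)(
        roi_id=rec.roi_id, genotype=rec.genotype, protocol=rec.protocol,
        frame_times=rec.frame_times, cfp=rec.cfp * 3.0, yfp=rec.yfp * 3.0, rfp=rec.rfp,
        background_cfp=rec.background_cfp * 3.0, background_yfp=rec.background_yfp * 3.0,
        background_rfp=rec.background_rfp, baseline_window=rec.baseline_window,
    )
    a = analyze_recording(rec)
    b = analyze_recording(scaled)
    assert b.peak_dRR0 == pytest.approx(a.peak_dRR0, rel=1e-9)


def test_half_rise_bounded_by_time_to_peak(wt_params, soma_protocol):
    rec = simulate_recording(wt_params, soma_protocol, rng=np.random.default_rng(13))
    res = analyze_recording(rec)
    assert 0 <= res.half_rise <= res.peak_time - soma_protocol.onset_time
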