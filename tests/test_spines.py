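"""Spine quantification: enrichment, exclusion truth table, peaks, ratio images."""

import numpy as np
import pytest

from camfret.errors import DataError, InvalidArgumentError
from camfret.protocol import SPINE_100_AT_20HZ
from camfret.simulate import (
    CalciumParams,
    SPINE_ACQUISITION,
    SpineGeometry,
    get_preset,
    render_spine_stack,
    simulate_ca_transient,
    simulate_kinase,
)
from camfret.spines import (
    ExclusionDecision,
    SpineRecord,
    apply_exclusion_filters,
    cumulative_distribution_compare,
    measure_spine_stack,
    render_ratio_image,
    soma_ratio_image,
    spine_enrichment_index,
    spine_peak_amplitude,
)


def make_spine(
    hk2a_spine=1.0,
    rcamp_spine=1.0,
    hk2a_shaft=1.0,
    rcamp_shaft=1.0,
    cfp=None,
    yfp=None,
    rfp=None,
    n=40,
    stim_end=20,
):
    ones = np.full(n, 100.0)
    return SpineRecord(
        spine_id="s0",
        neuron_id="n0",
        hk2a_spine=hk2a_spine,
        rcamp_spine=rcamp_spine,
        hk2a_shaft=hk2a_shaft,
        rcamp_shaft=rcamp_shaft,
        cfp=ones if cfp is None else np.asarray(cfp, dtype=float),
        yfp=ones if yfp is None else np.asarray(yfp, dtype=float),
        rfp=ones if rfp is None else np.asarray(rfp, dtype=float),
        frame_times=np.arange(n) / 4.0,
        stim_end_frame=stim_end,
        baseline_frames=np.arange(n) < 10,
    )


# ------------------------------------------------------------- enrichment
def test_enrichment_identity():
    assert spine_enrichment_index(make_spine()) == pytest.approx(1.0)


def test_enrichment_simple_ratio():
    assert spine_enrichment_index(make_spine(hk2a_spine=2.0)) == pytest.approx(2.0)


def test_enrichment_scale_invariant_and_swap_inverts():
    rng = np.random.default_rng(0)
    a, b, c, d = rng.uniform(0.5, 3.0, 4)
    base = spine_enrichment_index(make_spine(a, b, c, d))
    scaled = spine_enrichment_index(make_spine(7 * a, 7 * b, 7 * c, 7 * d))
    assert scaled == pytest.approx(base, rel=1e-12)
    swapped = spine_enrichment_index(make_spine(b, a, d, c))
    assert swapped == pytest.approx(1.0 / base, rel=1e-12)


def test_enrichment_nonpositive_intensity_is_error():
    with pytest.raises(DataError):
        spine_enrichment_index(make_spine(rcamp_shaft=0.0))


# ---------------------------------------------------------- exclusion rules
def drop_trace(base, post_ratio, n=40, stim_end=20, post=5):
    x = np.full(n, base)
    x[stim_end : stim_end + post] = base * post_ratio
    return x


@pytest.mark.parametrize(
    "cfp_ratio,yfp_ratio,expected",
    [
        (0.84, 1.00, "fret_decrease"),  # CFP < 85 % alone excludes
        (0.92, 0.80, "none"),  # YFP < 85 % but CFP >= 90 % keeps
        (0.89, 0.84, "fret_decrease"),  # both soft thresholds crossed
        (0.86, 0.86, "none"),  # neither rule fires
        (0.849, 1.00, "fret_decrease"),  # hard boundary just below
        (0.851, 0.851, "none"),  # just above both boundaries
    ],
)
def test_fret_decrease_truth_table(cfp_ratio, yfp_ratio, expected):
    rec = make_spine(cfp=drop_trace(100.0, cfp_ratio), yfp=drop_trace(100.0, yfp_ratio))
    # keep the Ca2+ indicator clearly bright so only the FRET rule can fire
    rec.rfp = np.full(40, 100.0) + np.tile([0.5, -0.5], 20)
    d = apply_exclusion_filters(rec)
    assert d.reason == expected
    assert d.excluded == (expected != "none")


def test_dim_rcamp_boundary():
    rng = np.random.default_rng(1)
    rec = make_spine()
    noise = rng.normal(0, 1.0, 40)
    noise = (noise - noise[:10].mean()) / noise[:10].std(ddof=1)  # baseline sd exactly 1
    rec.rfp = 1.9 + noise  # baseline mean 1.9 < 2 x SD 1.0
    d = apply_exclusion_filters(rec)
    assert d.reason == "dim_rcamp"
    rec.rfp = 2.1 + noise
    assert apply_exclusion_filters(rec).reason == "none"


def test_fret_decrease_takes_precedence_over_dim_rcamp():
    rec = make_spine(cfp=drop_trace(100.0, 0.5))
    rec.rfp = np.full(40, 0.01)  # would also be dim
    assert apply_exclusion_filters(rec).reason == "fret_decrease"


def test_exclusion_monotone_in_cfp_drop():
    # decreasing post-stimulus CFP can never convert excluded -> kept
    prev_excluded = False
    for ratio in np.linspace(1.0, 0.5, 26):
        rec = make_spine(cfp=drop_trace(100.0, ratio))
        rec.rfp = np.full(40, 100.0) + np.tile([0.5, -0.5], 20)
        excluded = apply_exclusion_filters(rec).excluded
        assert excluded or not prev_excluded
        prev_excluded = excluded


def test_counts_bookkeeping_partitions_spines():
    rng = np.random.default_rng(2)
    reasons = []
    for i in range(60):
        cfp_ratio = rng.uniform(0.7, 1.1)
        rec = make_spine(cfp=drop_trace(100.0, cfp_ratio))
        rec.rfp = rng.uniform(0, 4) + rng.normal(0, 1, 40)
        try:
            reasons.append(apply_exclusion_filters(rec).reason)
        except DataError:
            continue
    counts = {r: reasons.count(r) for r in ("none", "fret_decrease", "dim_rcamp")}
    assert sum(counts.values()) == len(reasons)


# ------------------------------------------------------------- spine peak
def test_spine_peak_examples():
    series = np.array([0.0, 0.0, 0.1, 0.3, 0.2, 0.15, 0.1])
    v, flags = spine_peak_amplitude(series, 2)
    assert v == 0.3 and flags == []
    v, flags = spine_peak_amplitude(np.zeros(10), 3)
    assert v == 0.0


def test_spine_peak_truncated_window_flagged():
    v, flags = spine_peak_amplitude(np.arange(4.0), 2)
    assert v == 3.0
    assert "peak_window_truncated" in flags


def test_spine_peak_matches_bruteforce_slice():
    rng = np.random.default_rng(3)
    x = rng.normal(size=50)
    v, _ = spine_peak_amplitude(x, 17)
    assert v == max(x[17], x[18], x[19], x[20], x[21])


# ------------------------------------------------------------ ratio images
def _stack_pair(ratio_rise=0.0, n=8, shape=(24, 24)):
    # background-subtracted frames: zero outside the cell
    yfp_base = np.zeros(shape)
    yfp_base[6:18, 6:18] = 300.0  # cell
    cfp = np.empty((n, *shape))
    yfp = np.empty((n, *shape))
    for i in range(n):
        rise = ratio_rise if i >= n // 2 else 0.0
        cfp[i] = (yfp_base * 0.5) * (1 + rise)
        yfp[i] = yfp_base.copy()
    return cfp, yfp


def test_ratio_image_zero_activation_is_zero_inside_mask():
    cfp, yfp = _stack_pair(0.0)
    img = render_ratio_image(cfp, yfp, np.arange(4), np.arange(4, 8), frames=3)
    assert np.nanmax(np.abs(img.values)) == pytest.approx(0.0, abs=1e-9)
    assert img.mask.sum() > 0


def test_ratio_image_uniform_fifty_percent_rise():
    cfp, yfp = _stack_pair(0.5)
    img = render_ratio_image(cfp, yfp, np.arange(4), np.arange(4, 8), frames=3)
    inside = img.values[img.mask]
    # Gaussian blur mixes cell and border pixels at the edge; the interior is exact
    assert np.nanmedian(inside) == pytest.approx(0.5, abs=0.01)


def test_ratio_image_empty_mask_is_error():
    cfp, yfp = _stack_pair(0.0)
    with pytest.raises(DataError):
        render_ratio_image(cfp, yfp, np.arange(4), np.arange(4, 8), mask_threshold=1e9)


def test_spine_restricted_activation_lights_spine_over_shaft(wt_params):
    t, ca = simulate_ca_transient(SPINE_100_AT_20HZ, CalciumParams(), 40.0, dt=0.005)
    act = simulate_kinase(ca, t, 1.0, wt_params)
    acq = SPINE_ACQUISITION.replace(duration=40.0)
    stack = render_spine_stack(
        SpineGeometry(), 1.3, act, acq=acq, params=wt_params,
        shot_noise=False, read_noise_sd=0.0, shaft_activation_scale=0.0,
    )
    geom = stack.geometry
    n_base = int(4 * 4.9)
    peak_frames = np.arange(int(4 * 7.0), int(4 * 7.0) + 3)
    img = render_ratio_image(
        stack.cfp - stack.background_level,
        stack.yfp - stack.background_level,
        np.arange(n_base),
        peak_frames,
    )
    spine_mean = np.nanmean(img.values[geom.spine_mask() & img.mask])
    shaft_mean = np.nanmean(img.values[geom.shaft_mask() & img.mask])
    assert spine_mean > 3 * abs(shaft_mean)


def test_soma_ratio_image_excludes_artifact_frames():
    cfp, yfp = _stack_pair(0.5, n=30)
    artifacts = np.zeros(30, dtype=bool)
    artifacts[15:20] = True
    cfp[15:20] += 500.0  # contaminated frames
    img = soma_ratio_image(
        cfp, yfp, artifacts, np.arange(12), np.arange(15, 30), frames=10
    )
    inside = img.values[img.mask]
    assert np.nanmedian(inside) == pytest.approx(0.5, abs=0.01)
    cfp2, yfp2 = _stack_pair(0.5, n=30)
    with pytest.raises(DataError):
        soma_ratio_image(cfp2, yfp2, np.ones(30, dtype=bool), np.arange(12), np.arange(15, 30))


# ---------------------------------------------------- rendered-stack recovery
def test_rendered_enrichment_identity_noise_free(wt_activation, wt_params):
    acq = SPINE_ACQUISITION.replace(duration=20.0)
    stack = render_spine_stack(
        SpineGeometry(), 1.0, wt_activation, acq=acq, params=wt_params,
        shot_noise=False, read_noise_sd=0.0,
    )
    rec = measure_spine_stack(stack, n_baseline_frames=16, stim_end_frame=40)
    assert spine_enrichment_index(rec) == pytest.approx(1.0, rel=1e-6)


def test_rendered_enrichment_recovers_1p36(wt_activation, wt_params):
    acq = SPINE_ACQUISITION.replace(duration=20.0)
    stack = render_spine_stack(
        SpineGeometry(), 1.36, wt_activation, acq=acq, params=wt_params,
        shot_noise=False, read_noise_sd=0.0,
    )
    rec = measure_spine_stack(stack, n_baseline_frames=16, stim_end_frame=40)
    assert spine_enrichment_index(rec) == pytest.approx(1.36, rel=0.02)


def test_injected_cfp_drop_is_flagged_by_filter(wt_activation, wt_params):
    acq = SPINE_ACQUISITION.replace(duration=30.0)
    stack = render_spine_stack(
        SpineGeometry(), 1.36, wt_activation, acq=acq, params=wt_params, seed=5
    )
    stack.cfp[60:] *= 0.75  # 25 % CFP drop after stimulation
    rec = measure_spine_stack(stack, n_baseline_frames=16, stim_end_frame=60)
    d = apply_exclusion_filters(rec)
    assert d.excluded and d.reason == "fret_decrease"


def test_overlapping_geometry_rejected():
    with pytest.raises(InvalidArgumentError):
        SpineGeometry(spine_center=(30.0, 32.0), shaft_y=36.0)


# --------------------------------------------------------------- KS compare
def test_ks_identical_samples_statistic_zero():
    x = np.arange(10.0)
    res = cumulative_distribution_compare(x, x)
    assert res["ks_stat"] == 0.0


def test_ks_disjoint_supports_statistic_one():
    res = cumulative_distribution_compare(np.arange(10.0), np.arange(100.0, 110.0))
    assert res["ks_stat"] == 1.0


def test_ks_power_on_shifted_normals():
    # a 1-SD shift at n = 40/50 is detected essentially always at the
    # simulation-scaled alpha, and in the large majority of runs even at
    # the stringent 0.001 level the assay reports
    rng = np.random.default_rng(6)
    n_sim = 300
    hits_05 = hits_001 = 0
    for _ in range(n_sim):
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 1, 50)
        p = cumulative_distribution_compare(a, b)["ks_p"]
        hits_05 += p < 0.05
        hits_001 += p < 0.001
    assert hits_05 / n_sim > 0.95
    assert hits_001 / n_sim > 0.6
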