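import numpy as np
import pandas as pd
import pytest

import calcilux as cx
from calcilux.coupling import (coupling_calibration, coupling_slope,
                               pair_events, spatial_correlation,
                               temporal_correlation)
from calcilux.roi import ROISet
from calcilux.simulate import MEARecording, PhotocurrentTrace


SINGLE_PULSE = cx.StimulationSchedule(onsets_s=np.array([0.05]),
                                      pulse_width_ms=100)


def analytic_trace(tau_on=0.032, tau_off=0.068, i_max=440.0,
                   onset=0.05, width=0.1, dt=5e-4, post=0.5):
    t = np.arange(0.0, onset + width + post, dt)
    tp = t - onset
    i_end = i_max * (1 - np.exp(-width / tau_on))
    i = np.where(tp < 0, 0.0,
                 np.where(tp <= width, i_max * (1 - np.exp(-np.maximum(tp, 0)
                                                           / tau_on)),
                          i_end * np.exp(-(tp - width) / tau_off)))
    return PhotocurrentTrace(time_s=t, current_pa=i, tau_on_ms=tau_on * 1e3,
                             tau_off_ms=tau_off * 1e3, i_max_pa=i_max)


def make_roiset(centroids_px, pixel_scale_um=2.0, field=64):
    centroids_px = np.asarray(centroids_px, float)
    label = np.zeros((field, field), dtype=int)
    for k, (cy, cxx) in enumerate(centroids_px, start=1):
        label[int(cy), int(cxx)] = k
    return ROISet(label_image=label,
                  ids=np.arange(1, len(centroids_px) + 1),
                  centroids_px=centroids_px, pixel_scale_um=pixel_scale_um)


def make_events(rows):
    return pd.DataFrame(rows, columns=["roi_id", "stim_idx", "t_onset_s",
                                       "latency_s", "class",
                                       "peak_dI_over_I0"])


def test_photocurrent_closed_form_peak_matches_tau_on():
    tr = analytic_trace()
    # peak reached at pulse end: i_max (1 - e^{-w/tau_on})
    assert tr.current_pa.max() == pytest.approx(
        440.0 * (1 - np.exp(-0.1 / 0.032)), rel=1e-6)


def test_fit_photocurrent_noiseless_exact_recovery():
    fit = cx.fit_photocurrent(analytic_trace(), SINGLE_PULSE)
    assert fit.ok
    assert fit.tau_on_ms == pytest.approx(32.0, abs=0.5)
    assert fit.tau_off_ms == pytest.approx(68.0, abs=0.5)


def test_fit_photocurrent_simulated_recovery():
    tr = cx.simulate_photocurrent(SINGLE_PULSE, noise_frac=0.01, seed=0)
    fit = cx.fit_photocurrent(tr, SINGLE_PULSE)
    assert fit.ok
    assert fit.tau_on_ms == pytest.approx(32.0, abs=6.0)
    assert fit.tau_off_ms == pytest.approx(68.0, abs=8.0)


def test_fit_photocurrent_requires_single_pulse():
    multi = cx.StimulationSchedule.periodic(2, 1.0, pulse_width_ms=100)
    fit = cx.fit_photocurrent(analytic_trace(), multi)
    assert not fit.ok and "single" in fit.message


def test_fit_photocurrent_rejects_flat_trace():
    tr = analytic_trace()
    flat = PhotocurrentTrace(time_s=tr.time_s,
                             current_pa=np.zeros_like(tr.current_pa),
                             tau_on_ms=0, tau_off_ms=0, i_max_pa=0)
    assert not cx.fit_photocurrent(flat, SINGLE_PULSE).ok


def test_pair_events_simple_match():
    rois = make_roiset([[10, 10], [40, 40]])  # um: (20,20), (80,80)
    mea = MEARecording(
        positions_um=np.array([[20.0, 20.0]]),
        spikes=pd.DataFrame({"electrode": [0, 0],
                             "t_s": [2.105, 14.110],
                             "amplitude_uv": [50.0, 60.0],
                             "event_idx": [0, 1]}))
    ev = make_events([
        (1, 0, 2.1, 0.1, "primary", 3.0),
        (1, 1, 14.1, 0.1, "primary", 3.5),
        (2, 0, 2.1, 0.1, "primary", 9.9),   # ROI 2 far from electrode
    ])
    pairs = pair_events(ev, mea, rois, radius_um=30.0)
    assert len(pairs) == 2
    assert set(pairs["roi_id"]) == {1}
    assert np.allclose(sorted(pairs["optical_pct"]), [300.0, 350.0])
    assert np.allclose(sorted(pairs["lag_ms"]), [5.0, 10.0], atol=1e-6)


def test_pair_events_one_to_one_greedy():
    # two spikes compete for one event: only the smaller |lag| wins
    rois = make_roiset([[10, 10]])
    mea = MEARecording(
        positions_um=np.array([[20.0, 20.0]]),
        spikes=pd.DataFrame({"electrode": [0, 0], "t_s": [2.12, 2.103],
                             "amplitude_uv": [40.0, 55.0],
                             "event_idx": [0, 0]}))
    ev = make_events([(1, 0, 2.1, 0.1, "primary", 3.0)])
    pairs = pair_events(ev, mea, rois, radius_um=30.0)
    assert len(pairs) == 1
    assert pairs["amplitude_uv"].iloc[0] == 55.0


def test_pair_events_unit_mismatch_raises():
    rois = make_roiset([[10, 10]], pixel_scale_um=2.0)  # centroids ~20 um
    mea = MEARecording(
        positions_um=np.array([[20000.0, 20000.0]]),    # mm-scale mistake
        spikes=pd.DataFrame({"electrode": [0], "t_s": [2.1],
                             "amplitude_uv": [50.0], "event_idx": [0]}))
    with pytest.raises(ValueError, match="unit"):
        pair_events(make_events([(1, 0, 2.1, 0.1, "primary", 3.0)]), mea, rois)


def test_temporal_correlation_perfectly_linear():
    pairs = pd.DataFrame({
        "amplitude_uv": [10.0, 20.0, 30.0, 40.0],
        "optical_pct": [100.0, 200.0, 300.0, 400.0],
        "distance_um": [5.0] * 4,
    })
    res = temporal_correlation(pairs)
    assert res.ok
    assert res.r2 == pytest.approx(1.0)
    assert res.slope == pytest.approx(0.1)


def test_temporal_correlation_degenerate_cases():
    none = temporal_correlation(pd.DataFrame(columns=["amplitude_uv",
                                                      "optical_pct",
                                                      "distance_um"]))
    assert not none.ok and "no pairs" in none.message
    const = temporal_correlation(pd.DataFrame({
        "amplitude_uv": [1.0, 2.0, 3.0],
        "optical_pct": [5.0, 5.0, 5.0],
        "distance_um": [1.0, 1.0, 1.0]}))
    assert not const.ok and "variance" in const.message


def test_end_to_end_temporal_r2_tracks_noise_ratio():
    cfg = cx.invivo_preset(seed=11, duration_h=1.0)
    sched = cx.StimulationSchedule.hourly_blocks(1, 10)
    stack, cm = cx.simulate_session(cfg, sched)
    rois = cx.assign_rois(stack, sched)
    traces = cx.extract_traces(stack, rois, sched)
    events = cx.detect_events(traces, sched)
    electrodes = rois.centroids_um()
    mea = cx.simulate_mea(cm, electrodes, noise_ratio=0.1, radius_um=15.0,
                          seed=11)
    pairs = pair_events(events, mea, rois, radius_um=15.0)
    res = temporal_correlation(pairs)
    assert res.ok and res.n >= 30
    assert res.r2 == pytest.approx(0.9, abs=0.08)


def test_spatial_correlation_linear_construction():
    # activity discs of graded area around a 3x3 electrode grid; spike
    # counts proportional to area -> R^2 ~ 1
    scale = 2.0
    field = 200
    act = np.zeros((field, field), bool)
    grid = cx.mea_grid(3, 3, pitch_um=120.0, origin_um=(40.0, 40.0))
    rows, rr, cc = [], *np.mgrid[0:field, 0:field].astype(float)
    for e, (ey, ex) in enumerate(grid):
        r_um = 10.0 + 4.0 * e
        act |= ((rr * scale - ey) ** 2 + (cc * scale - ex) ** 2) <= r_um ** 2
        rows += [(e, 0.1 * k, 50.0, -1) for k in range(3 + e)]
    mea = MEARecording(positions_um=grid,
                       spikes=pd.DataFrame(rows, columns=["electrode", "t_s",
                                                          "amplitude_uv",
                                                          "event_idx"]))
    res = spatial_correlation(act, scale, mea)
    assert res.ok
    assert res.r2 > 0.95
    assert res.slope > 0


def test_spatial_correlation_end_to_end():
    r2s = []
    for seed in (0, 1, 2):
        cfg = cx.invivo_preset(seed=seed, duration_h=1.0)
        sched = cx.StimulationSchedule.hourly_blocks(1, 10)
        stack, cm = cx.simulate_session(cfg, sched)
        rois = cx.assign_rois(stack, sched)
        amap = rois.label_image > 0
        grid = cx.mea_grid(4, 4, pitch_um=56.0, origin_um=(28.0, 28.0))
        mea = cx.simulate_mea(cm, grid, noise_ratio=0.12, seed=seed)
        res = spatial_correlation(amap, cfg.pixel_scale_um, mea)
        assert res.ok
        r2s.append(res.r2)
    assert np.mean(r2s) == pytest.approx(0.88, abs=0.1)


def test_coupling_slope_increases_with_intensity():
    ser = cx.simulate_intensity_series(seed=0)
    tab = coupling_slope(ser)
    slopes = tab.set_index("intensity_uw_mm2")["slope_uv_per_pct"]
    assert slopes.is_monotonic_increasing
    assert (tab["n"] >= 3).all()


def test_coupling_calibration_two_pa_per_percent():
    df = cx.simulate_concomitant(n_pulses=60, seed=0)
    cal = coupling_calibration(df)
    assert cal["n"] == 60
    assert cal["pa_per_pct"] == pytest.approx(2.0, rel=0.1)
    assert cal["pct_per_pa"] == pytest.approx(0.5, rel=0.1)
    assert cal["r2"] > 0.9
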