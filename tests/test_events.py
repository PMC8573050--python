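import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import calcilux as cx
from calcilux.events import classify_latency, fit_decay, roi_noise_sd
from calcilux.traces import TraceMatrix, compute_dff


def make_traces(t, dff_row, onsets, masked=None):
    sched = (cx.StimulationSchedule(onsets_s=np.asarray(onsets, float),
                                    pulse_width_ms=10)
             if len(onsets) else cx.empty_schedule())
    masked = np.zeros(t.size, bool) if masked is None else masked
    dff = np.asarray(dff_row, float)[None, :]
    return TraceMatrix(
        roi_ids=np.array([1]), times_s=t, intensity=dff + 1.0, dff=dff,
        masked=masked,
        baselines=np.ones((1, max(len(onsets), 1))),
        baseline_ok=np.ones((1, max(len(onsets), 1)), bool),
        stim_of_frame=np.zeros(t.size, int), schedule=sched), sched


def test_latency_classification_examples():
    assert classify_latency(0.3) == "primary"
    assert classify_latency(0.7) == "discarded"
    assert classify_latency(1.5) == "secondary"
    assert classify_latency(0.5) == "primary"      # boundary inclusive
    assert classify_latency(1.0) == "secondary"    # boundary inclusive
    assert classify_latency(None) == "spontaneous"
    assert classify_latency(7.0) == "spontaneous"  # beyond horizon


@settings(deadline=None, derandomize=True)
@given(lat=st.one_of(st.none(),
                     st.floats(min_value=0.0, max_value=10.0)))
def test_classification_partition(lat):
    cls = classify_latency(lat)
    assert cls in {"primary", "secondary", "spontaneous", "discarded"}


def test_detect_events_classes_and_peaks():
    t = np.arange(0.0, 12.0, 0.1)
    d = np.zeros(t.size)
    d[(t >= 2.3) & (t < 2.5)] = 3.0       # latency 0.3 -> primary
    d[(t >= 3.5) & (t < 3.7)] = 1.0       # latency 1.5 -> secondary
    d[(t >= 9.0) & (t < 9.2)] = 0.5       # no stimulus within 5 s -> spontaneous
    traces, sched = make_traces(t, d, onsets=[2.0])
    ev = cx.detect_events(traces, sched)
    assert list(ev["class"]) == ["primary", "secondary", "spontaneous"]
    assert np.allclose(ev["peak_dI_over_I0"], [3.0, 1.0, 0.5])
    assert ev.loc[ev["class"] == "primary", "latency_s"].iloc[0] == \
        pytest.approx(0.3)


def test_detect_events_flat_trace_has_none():
    t = np.arange(0.0, 5.0, 0.1)
    traces, sched = make_traces(t, np.zeros(t.size), onsets=[2.0])
    assert len(cx.detect_events(traces, sched)) == 0


def test_decay_tail_not_redetected_as_secondary():
    # exponential tail crossing threshold after 1 s must stay one event
    t = np.arange(0.0, 8.0, 0.1)
    d = np.zeros(t.size)
    ev_t = 2.1
    after = t >= ev_t
    d[after] = 3.0 * 0.5 ** ((t[after] - ev_t) / 0.216)
    traces, sched = make_traces(t, d, onsets=[2.0])
    ev = cx.detect_events(traces, sched)
    assert list(ev["class"]) == ["primary"]


def test_delayed_event_on_decay_tail_is_split():
    t = np.arange(0.0, 8.0, 0.1)
    d = np.zeros(t.size)
    after = t >= 2.1
    d[after] = 3.0 * 0.5 ** ((t[after] - 2.1) / 0.216)
    d[(t >= 3.5) & (t < 3.7)] += 1.0
    traces, sched = make_traces(t, d, onsets=[2.0])
    ev = cx.detect_events(traces, sched)
    assert list(ev["class"]) == ["primary", "secondary"]


def test_event_detection_recall_and_false_positives(invivo_hour):
    from tests.conftest import match_rois_to_neurons
    p = invivo_hour
    mapping = match_rois_to_neurons(p.rois, p.cellmap)
    prim = p.events[p.events["class"] == "primary"].copy()
    prim["neuron"] = prim["roi_id"].map(mapping)
    gt = p.cellmap.events[p.cellmap.events["class"] == "primary"]
    gt_keys = set(zip(gt["neuron"], gt["stim_idx"]))
    det_keys = set(zip(prim["neuron"], prim["stim_idx"]))
    recall = len(gt_keys & det_keys) / len(gt_keys)
    assert recall >= 0.9
    false_pos = len(det_keys - gt_keys)
    assert false_pos <= 0.05 * p.rois.n_rois * p.schedule.n_stimuli


def test_fidelity_example_seven_of_ten():
    ev = pd.DataFrame({
        "roi_id": [1] * 7, "stim_idx": list(range(7)),
        "t_onset_s": np.arange(7) * 12.0 + 2.1,
        "latency_s": [0.1] * 7, "class": ["primary"] * 7,
        "peak_dI_over_I0": [3.0] * 7,
    })
    sched = cx.StimulationSchedule.periodic(10, 12.0, start_s=2.0)
    fid = cx.fidelity(ev, np.array([1]), sched)
    assert fid["fidelity"].iloc[0] == pytest.approx(0.7)
    assert fid["n_stimuli"].iloc[0] == 10


def test_fidelity_monotone_in_responses():
    sched = cx.StimulationSchedule.periodic(10, 12.0, start_s=2.0)
    rows = []
    for k in range(1, 11):
        ev = pd.DataFrame({
            "roi_id": [1] * k, "stim_idx": list(range(k)),
            "t_onset_s": np.arange(k) * 12.0 + 2.1,
            "latency_s": [0.1] * k, "class": ["primary"] * k,
            "peak_dI_over_I0": [3.0] * k,
        })
        rows.append(cx.fidelity(ev, np.array([1]), sched)["fidelity"].iloc[0])
    assert all(b >= a for a, b in zip(rows, rows[1:]))
    assert all(0.0 <= f <= 1.0 for f in rows)


def test_fidelity_empty_window_flagged():
    sched = cx.StimulationSchedule.periodic(5, 12.0, start_s=2.0)
    ev = pd.DataFrame(columns=["roi_id", "stim_idx", "t_onset_s", "latency_s",
                               "class", "peak_dI_over_I0"])
    fid = cx.fidelity(ev, np.array([1]), sched, windows_h=[(10.0, 11.0)])
    assert not fid["usable"].iloc[0]
    assert np.isnan(fid["fidelity"].iloc[0])


def test_fit_decay_noiseless_exact():
    t = np.arange(0.0, 1.5, 0.02)
    y = 3.0 * 0.5 ** (t / 0.216)
    fit = fit_decay(t, y)
    assert fit.t_half_ms == pytest.approx(216.0, abs=0.5)


def test_fit_decay_fixed_point():
    t = np.arange(0.0, 1.0, 0.02)
    fit1 = fit_decay(t, 2.0 * 0.5 ** (t / 0.1))
    y2 = 2.0 * 0.5 ** (t / (fit1.t_half_ms / 1000.0))
    fit2 = fit_decay(t, y2)
    assert fit2.t_half_ms == pytest.approx(fit1.t_half_ms, rel=1e-3)


def test_fit_decay_rejects_non_decay():
    t = np.arange(0.0, 1.0, 0.02)
    fit = fit_decay(t, t.copy())
    assert not fit.ok


def test_fit_decay_too_few_points():
    fit = fit_decay(np.array([0.0, 0.1]), np.array([1.0, 0.5]))
    assert not fit.ok


def test_hek_decay_half_life_216(hek_trace):
    tm, cm, sched = hek_trace
    fits = [f for f in cx.decay_fits_per_stimulus(tm, 1) if f.t_half_ms]
    assert len(fits) == 10
    ths = [f.t_half_ms for f in fits]
    assert np.mean(ths) == pytest.approx(216.0, abs=1.0)


def test_hourly_summary_schema(invivo_day):
    p = invivo_day
    windows = [(float(h), float(h + 1)) for h in range(14)]
    summ = cx.hourly_summary(p.events, p.rois.ids, p.schedule, windows)
    assert len(summ) == 14
    assert summ["mean_fidelity"].between(0, 1).all()
    assert (summ["n_active_neurons"] <= p.rois.n_rois).all()
    # circadian amplitude peak visible in hours 7-8
    peak = summ.loc[summ["window_start_h"].isin([7.0, 8.0]),
                    "mean_primary_dff"].mean()
    off = summ.loc[summ["window_start_h"].isin([5.0, 9.0]),
                   "mean_primary_dff"].mean()
    assert peak > 1.5 * off


def test_compare_windows_detects_amplitude_gain(invivo_day):
    tstat, p_val = cx.compare_windows(invivo_day.events, (7.0, 9.0),
                                      (5.0, 7.0), alternative="greater")
    assert tstat > 0 and p_val < 0.01


def test_roi_noise_sd_positive_on_noisy_traces(invivo_hour):
    sd = roi_noise_sd(invivo_hour.traces, 1)
    assert 0 < sd < 0.2
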