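"""Transient detection, latency classification, fidelity and kinetics.

Detected transients are classified by their onset latency relative to the
nearest preceding stimulus:

* primary    — onset within 500 ms of the stimulus (direct activation),
* secondary  — onset at least 1 s after the stimulus (delayed
  astrocyte-mediated pathway), up to ``secondary_horizon``,
* spontaneous — no stimulus within the horizon,
* discarded  — onset in the (0.5, 1.0) s gap, unclassifiable by the latency
  rule (the quiet window in which little or no activity occurs).

Fidelity is the fraction of stimulations that elicit at least one primary
response at a given ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schedule import StimulationSchedule
from .traces import TraceMatrix

_EPS = 1e-9

EVENT_TABLE_COLUMNS = ["roi_id", "stim_idx", "t_onset_s", "latency_s",
                       "class", "peak_dI_over_I0"]


@dataclass
class KineticsFit:
    """Exponential kinetics fit result (times in milliseconds)."""

    t_half_ms: float | None = None
    tau_on_ms: float | None = None
    tau_off_ms: float | None = None
    residual_rms: float = np.nan
    n_points: int = 0
    ok: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "t_half_ms": self.t_half_ms,
            "tau_on_ms": self.tau_on_ms,
            "tau_off_ms": self.tau_off_ms,
            "residual_rms": None if np.isnan(self.residual_rms) else self.residual_rms,
            "n_points": self.n_points,
            "ok": self.ok,
            "message": self.message,
        }


def classify_latency(latency_s: float | None,
                     secondary_horizon_s: float = 5.0) -> str:
    """Latency class of one event (see module docstring)."""
    if latency_s is None or not np.isfinite(latency_s) or latency_s > secondary_horizon_s + _EPS:
        return "spontaneous"
    if latency_s <= 0.5 + _EPS:
        return "primary"
    if latency_s >= 1.0 - _EPS:
        return "secondary"
    return "discarded"


def roi_noise_sd(traces: TraceMatrix, roi_id: int,
                 baseline_window_s: float = 1.0) -> float:
    """Robust per-ROI noise SD of dI/I0: 1.4826 x MAD over pre-stimulus frames."""
    k = traces.roi_index(roi_id)
    t = traces.times_s
    ok = ~traces.masked & np.isfinite(traces.dff[k])
    sched = traces.schedule
    if sched.n_stimuli:
        sel = np.zeros_like(ok)
        for onset in sched.onsets_s:
            sel |= (t >= onset - baseline_window_s) & (t < onset)
        sel &= ok
        if not sel.any():
            sel = ok
    else:
        sel = ok
    x = traces.dff[k, sel]
    if x.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _runs(flags: np.ndarray, times: np.ndarray, max_gap_s: float) -> list[tuple[int, int]]:
    """Index runs of consecutive True flags, split at time gaps > max_gap_s."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    runs = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1 and times[i] - times[prev] <= max_gap_s:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def detect_events(traces: TraceMatrix, schedule: StimulationSchedule,
                  event_sigma: float = 5.0,
                  low_sigma: float = 2.0,
                  secondary_horizon_s: float = 5.0,
                  abs_threshold_floor: float = 0.1) -> pd.DataFrame:
    """Detect dI/I0 transients and classify them by post-stimulus latency.

    Detection uses hysteresis thresholding: a transient is a run of frames
    with dI/I0 above ``low_sigma`` times the per-ROI baseline noise SD that
    reaches ``event_sigma`` times the noise SD at least once. The absolute
    threshold ``abs_threshold_floor`` bounds the high threshold from below
    (with 40% of it bounding the low threshold), which both covers
    noiseless traces (SD = 0) and keeps quantization-level noise on
    near-noiseless movies from producing ghost events. The low
    threshold keeps a transient's decay tail attached to its event, so
    noise crossings on the tail are not re-detected as later events; a run
    is split into a new event wherever the frame-to-frame rise exceeds the
    high threshold, so a delayed transient riding on a decay tail is still
    resolved. The onset is the first frame above the high threshold (or the
    rise frame for a split event); the peak is the run maximum;
    classification follows :func:`classify_latency` with the latency
    measured from onset to the nearest preceding stimulus.
    """
    rows = []
    t = traces.times_s
    onsets = schedule.onsets_s
    dt_med = float(np.median(np.diff(t))) if t.size > 1 else 0.1
    for roi_id in traces.roi_ids:
        k = traces.roi_index(roi_id)
        sd = roi_noise_sd(traces, roi_id)
        thr_hi = max(event_sigma * sd, abs_threshold_floor)
        thr_lo = max(low_sigma * sd, 0.4 * abs_threshold_floor)
        dff = traces.dff[k]
        supra = np.isfinite(dff) & (dff > thr_lo)
        segments: list[tuple[int, int]] = []
        for a0, b in _runs(supra, t, max_gap_s=2.5 * dt_med):
            rises = np.flatnonzero(np.diff(dff[a0:b + 1]) > thr_hi) + 1 + a0
            bounds = [a0] + [int(r) for r in rises] + [b + 1]
            segments.extend((bounds[i], bounds[i + 1] - 1)
                            for i in range(len(bounds) - 1))
        for a0, b in segments:
            seg = dff[a0:b + 1]
            hi = np.flatnonzero(seg > thr_hi)
            if hi.size == 0:
                continue
            a = a0 + int(hi[0])
            onset_t = t[a]
            peak = float(np.nanmax(seg))
            if onsets.size:
                s = int(np.searchsorted(onsets, onset_t + _EPS) - 1)
            else:
                s = -1
            if s < 0:
                latency = np.nan
            else:
                latency = onset_t - onsets[s]
            cls = classify_latency(latency, secondary_horizon_s)
            if cls == "spontaneous":
                s = -1
                latency = np.nan
            rows.append((int(roi_id), s, onset_t, latency, cls, peak))
    return pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS)


def fidelity(events: pd.DataFrame, roi_ids: np.ndarray,
             schedule: StimulationSchedule,
             windows_h: list[tuple[float, float]] | None = None) -> pd.DataFrame:
    """Per-ROI, per-window fraction of stimuli with >= 1 primary response.

    ``windows_h`` are (start, end) session hours; by default one window
    spanning the whole schedule. Windows containing no stimulus get NaN
    fidelity and are flagged unusable.
    """
    onsets = schedule.onsets_s
    if windows_h is None:
        end_h = (onsets[-1] / 3600.0 + 1e-6) if onsets.size else 0.0
        windows_h = [(0.0, max(end_h, 1e-6))]
    prim = events[events["class"] == "primary"]
    rows = []
    for (h0, h1) in windows_h:
        in_win = (onsets >= h0 * 3600.0) & (onsets < h1 * 3600.0)
        stim_idx = set(np.flatnonzero(in_win).tolist())
        n_stim = len(stim_idx)
        for roi_id in roi_ids:
            sub = prim[(prim["roi_id"] == roi_id)
                       & (prim["stim_idx"].isin(stim_idx))]
            n_resp = sub["stim_idx"].nunique()
            fid = n_resp / n_stim if n_stim else np.nan
            rows.append((int(roi_id), h0, h1, n_stim, n_resp, fid, n_stim > 0))
    return pd.DataFrame(rows, columns=["roi_id", "window_start_h",
                                       "window_end_h", "n_stimuli",
                                       "n_responses", "fidelity", "usable"])


def fit_decay(times_s: np.ndarray, dff: np.ndarray,
              noise_floor_frac: float = 0.05,
              min_points: int = 4) -> KineticsFit:
    """Exponential decay fit A * 2^(-t/t_half) to the post-peak segment.

    The peak sample itself is excluded (camera integration makes it follow
    the flat top of the transient, not the decay); fitting stops at the
    first sample below ``noise_floor_frac`` of the peak.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(dff, dtype=float)
    fin = np.isfinite(t) & np.isfinite(y)
    t, y = t[fin], y[fin]
    if y.size < min_points + 1:
        return KineticsFit(ok=False, message="too few samples")
    ip = int(np.argmax(y))
    peak = y[ip]
    if peak <= 0:
        return KineticsFit(ok=False, message="non-positive peak")
    t_seg = t[ip + 1:]
    y_seg = y[ip + 1:]
    below = np.flatnonzero(y_seg < noise_floor_frac * peak)
    if below.size:
        t_seg, y_seg = t_seg[:below[0]], y_seg[:below[0]]
    if y_seg.size < min_points:
        return KineticsFit(ok=False, n_points=int(y_seg.size),
                           message="fewer than 4 usable post-peak points")
    t0 = t_seg[0]
    # refuse clearly non-decaying segments
    slope = np.polyfit(t_seg - t0, y_seg, 1)[0]
    if slope >= 0:
        return KineticsFit(ok=False, n_points=int(y_seg.size),
                           message="segment is not decaying")

    def model(tt, a, t_half):
        return a * 0.5 ** (tt / t_half)

    a0 = max(y_seg[0], 1e-6)
    th0 = max((t_seg[-1] - t0) / 3.0, 1e-3)
    try:
        popt, _ = optimize.curve_fit(model, t_seg - t0, y_seg, p0=[a0, th0],
                                     bounds=([0, 1e-6], [np.inf, np.inf]),
                                     maxfev=5000)
    except RuntimeError:
        return KineticsFit(ok=False, n_points=int(y_seg.size),
                           message="decay fit did not converge")
    resid = y_seg - model(t_seg - t0, *popt)
    return KineticsFit(
        t_half_ms=float(popt[1] * 1000.0),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        n_points=int(y_seg.size),
    )


def decay_fits_per_stimulus(traces: TraceMatrix, roi_id: int,
                            segment_s: float = 1.0) -> list[KineticsFit]:
    """Fit the decay of each stimulated transient of one ROI."""
    k = traces.roi_index(roi_id)
    t = traces.times_s
    fits = []
    for onset in traces.schedule.onsets_s:
        sel = (t >= onset) & (t < onset + segment_s) & ~traces.masked
        if sel.sum() < 5:
            continue
        fits.append(fit_decay(t[sel], traces.dff[k, sel]))
    return fits


def hourly_summary(events: pd.DataFrame, roi_ids: np.ndarray,
                   schedule: StimulationSchedule,
                   windows_h: list[tuple[float, float]]) -> pd.DataFrame:
    """Per-window aggregates of the classified events.

    For each (start, end) hour window: mean primary peak dI/I0, mean
    fidelity across ROIs, number of secondary responses, number of active
    neurons (ROIs with >= 1 primary event in the window), and the count and
    mean amplitude of spontaneous events.
    """
    fid = fidelity(events, roi_ids, schedule, windows_h)
    rows = []
    for (h0, h1) in windows_h:
        t0, t1 = h0 * 3600.0, h1 * 3600.0
        in_win = events[(events["t_onset_s"] >= t0) & (events["t_onset_s"] < t1)]
        prim = in_win[in_win["class"] == "primary"]
        sec = in_win[in_win["class"] == "secondary"]
        spon = in_win[in_win["class"] == "spontaneous"]
        fsub = fid[(fid["window_start_h"] == h0) & (fid["usable"])]
        rows.append({
            "window_start_h": h0,
            "window_end_h": h1,
            "mean_primary_dff": prim["peak_dI_over_I0"].mean(),
            "mean_fidelity": fsub["fidelity"].mean() if len(fsub) else np.nan,
            "n_secondary": int(len(sec)),
            "n_active_neurons": int(prim["roi_id"].nunique()),
            "n_spontaneous": int(len(spon)),
            "mean_spontaneous_dff": spon["peak_dI_over_I0"].mean(),
        })
    return pd.DataFrame(rows)


def compare_windows(events: pd.DataFrame, window_a: tuple[float, float],
                    window_b: tuple[float, float],
                    alternative: str = "two-sided") -> tuple[float, float]:
    """Student's t-test on primary peak dI/I0 between two hour windows.

    Returns (t statistic, p value); ``alternative='greater'`` tests whether
    window_a exceeds window_b.
    """
    def amps(win):
        t0, t1 = win[0] * 3600.0, win[1] * 3600.0
        sub = events[(events["class"] == "primary")
                     & (events["t_onset_s"] >= t0)
                     & (events["t_onset_s"] < t1)]
        return sub["peak_dI_over_I0"].to_numpy()

    res = stats.ttest_ind(amps(window_a), amps(window_b),
                          alternative=alternative)
    return float(res.statistic), float(res.pvalue)
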