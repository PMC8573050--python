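"""Forward simulator for Ca2+ bioluminescence recordings.

Generates, with seed-reproducible ground truth:

* single-cell transient traces (threefold peak/baseline, 216 ms decay
  half-life at the default preset),
* movie stacks of a cortical field with stimulus-locked primary events,
  delayed astrocyte-mediated secondary events (>= 1 s post-stimulus, absent
  when astrocyte coupling is switched off, emulating norepinephrine block),
  spontaneous transients near 50% dI/I0, substrate decay with periodic
  replenishment, circadian per-hour gains, and camera-deadtime frame masks,
* opsin photocurrent traces (saturating rise, exponential decay),
* multi-electrode recordings whose spike amplitudes couple linearly to
  optical peak amplitudes for neurons within 50 um of an electrode.

Long sessions are rendered sparsely: full frames only around each stimulus
plus one background epoch per hour; ground-truth events are generated only
inside rendered intervals so that every generated event is observable.

The transient model is an instantaneous rise held for one frame interval
followed by exponential decay with the configured half-life; movie frames
record the exposure-averaged photon flux, so the peak frame reads exactly
the event amplitude and the summed photons match the model's closed-form
integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SessionConfig
from .schedule import StimulationSchedule
from .stack import MovieStack, deadtime_mask
from .traces import TraceMatrix, compute_dff

EVENT_COLUMNS = ["neuron", "stim_idx", "t_onset_s", "latency_s", "class", "amplitude"]


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class CellMap:
    """Simulated cell geometry plus the ground-truth event table.

    ``events`` columns: neuron (index), stim_idx (-1 for spontaneous),
    t_onset_s, latency_s (NaN for spontaneous), class (primary / secondary /
    spontaneous), amplitude (true dI/I0).
    """

    positions_px: np.ndarray          # (N, 2) as (row, col)
    radii_px: np.ndarray
    responsive: np.ndarray            # (N,) bool
    partners: dict[int, list[int]]    # astrocyte partners per responsive neuron
    events: pd.DataFrame
    pixel_scale_um: float

    def __post_init__(self) -> None:
        if self.events is not None and len(self.events):
            sec = self.events["class"] == "secondary"
            # container invariant; generation enforces it too
            assert not (sec.any() and self.partners is None)

    @property
    def n_neurons(self) -> int:
        return int(self.positions_px.shape[0])

    def positions_um(self) -> np.ndarray:
        return self.positions_px * self.pixel_scale_um

    def responsive_ids(self) -> np.ndarray:
        return np.flatnonzero(self.responsive)

    def save_events_csv(self, path: str | Path) -> None:
        out = self.events.rename(columns={"amplitude": "true_dI_over_I0",
                                          "neuron": "neuron_id"})
        out.to_csv(path, index=False)


@dataclass
class PhotocurrentTrace:
    """Opsin photocurrent (inward; stored as magnitude in pA)."""

    time_s: np.ndarray
    current_pa: np.ndarray
    tau_on_ms: float
    tau_off_ms: float
    i_max_pa: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.time_s, "pA": self.current_pa})

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class MEARecording:
    """Extracellular spikes on a multi-electrode array.

    ``spikes`` columns: electrode, t_s, amplitude_uv and (simulation
    provenance, for recovery tests only) event_idx into the ground-truth
    event table, -1 for noise-added spikes.
    """

    positions_um: np.ndarray          # (E, 2)
    spikes: pd.DataFrame
    sampling_rate_hz: float = 20000.0

    @property
    def n_electrodes(self) -> int:
        return int(self.positions_um.shape[0])

    def save_csv(self, path: str | Path) -> None:
        df = self.spikes.copy()
        df["x_um"] = self.positions_um[df["electrode"].to_numpy(), 1]
        df["y_um"] = self.positions_um[df["electrode"].to_numpy(), 0]
        df.to_csv(path, index=False)


def mea_grid(n_rows: int, n_cols: int, pitch_um: float,
             origin_um: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Regular electrode grid; positions as (row_um, col_um)."""
    rr, cc = np.mgrid[0:n_rows, 0:n_cols].astype(float)
    pos = np.column_stack([rr.ravel() * pitch_um + origin_um[0],
                           cc.ravel() * pitch_um + origin_um[1]])
    return pos


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _place_cells(rng: np.random.Generator, n: int, field: int,
                 margin: float, min_sep: float) -> np.ndarray:
    """Cell centers on a jittered lattice with guaranteed minimum separation.

    A square lattice dense enough to hold ``n`` cells is jittered uniformly
    by less than half the slack between lattice pitch and ``min_sep``; a
    random subset of lattice sites is kept. This keeps placement random in
    appearance while making crowding failures impossible up to the lattice
    capacity.
    """
    lo, hi = margin, field - margin
    span = hi - lo
    if span <= 0:
        raise ValueError("field too small for the requested margin")
    k = int(np.ceil(np.sqrt(n)))
    while True:
        pitch = span / k
        jitter = (pitch - min_sep) / 2.0
        if jitter >= 0 or k * k < n:
            break
        k -= 1
    if k * k < n or pitch < min_sep:
        raise ValueError(
            f"cannot place {n} cells with separation {min_sep} px in a "
            f"{field} px field")
    gy, gx = np.mgrid[0:k, 0:k].astype(float)
    sites = np.column_stack([gy.ravel(), gx.ravel()]) * pitch + lo + pitch / 2.0
    chosen = rng.choice(sites.shape[0], size=n, replace=False)
    pts = sites[chosen] + rng.uniform(-jitter, jitter, size=(n, 2))
    return np.clip(pts, lo, hi)


def _gaussian_blob(radius_px: float) -> tuple[np.ndarray, int]:
    """Unit-peak Gaussian footprint (sigma = radius/2), truncated at 3 sigma."""
    sigma = radius_px / 2.0
    half = max(int(np.ceil(3 * sigma)), 2)
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    blob = np.exp(-(y ** 2 + x ** 2) / (2 * sigma ** 2))
    return blob, half


# ---------------------------------------------------------------------------
# render-window / frame-grid construction
# ---------------------------------------------------------------------------

def render_windows(config: SessionConfig,
                   schedule: StimulationSchedule) -> list[tuple[float, float]]:
    """Intervals (seconds) rendered to frames: stimulus margins + hourly epochs."""
    windows: list[tuple[float, float]] = []
    m = config.render_margin_s
    for onset in schedule.onsets_s:
        windows.append((max(0.0, onset - m), min(config.duration_s, onset + m)))
    epoch = config.background_epoch_s
    for h in range(int(np.ceil(config.duration_h))):
        t0 = h * 3600.0 + 1800.0
        if t0 + epoch > min((h + 1) * 3600.0, config.duration_s):
            t0 = h * 3600.0
        t1 = min(t0 + epoch, config.duration_s)
        if t1 > t0:
            windows.append((t0, t1))
    windows.sort()
    merged: list[tuple[float, float]] = []
    for w in windows:
        if merged and w[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w[1]))
        else:
            merged.append(w)
    return merged


def frame_grid(config: SessionConfig, windows: list[tuple[float, float]]
               ) -> np.ndarray:
    """Frame start times: the global ``k * frame_interval`` grid restricted
    to the rendered windows."""
    dt = config.frame_interval_s
    chunks = []
    for t0, t1 in windows:
        k0 = int(np.ceil(t0 / dt - 1e-9))
        k1 = int(np.floor((t1 - dt) / dt + 1e-9))
        if k1 >= k0:
            chunks.append(np.arange(k0, k1 + 1, dtype=np.int64))
    if not chunks:
        return np.empty(0)
    ks = np.unique(np.concatenate(chunks))
    return ks * dt


def _snap(t: float, dt: float) -> float:
    return round(t / dt) * dt


# ---------------------------------------------------------------------------
# ground-truth event generation
# ---------------------------------------------------------------------------

def _generate_events(config: SessionConfig, schedule: StimulationSchedule,
                     rng: np.random.Generator,
                     windows: list[tuple[float, float]]) -> pd.DataFrame:
    """Draw the ground-truth event table for one session.

    Evoked events anchor on the first frame starting at/after pulse end
    (the stimulus frame itself is camera deadtime). A responding neuron
    joins the staggered latency cascade (1..stagger_frames-1 frames past the
    anchor, all within the 500 ms primary window) with the
    circadian-modulated participation probability, else it fires in the
    anchor frame itself. No event is ever placed in the (0.5, 1.0] s
    post-stimulus window. Secondary events appear on astrocyte partners of
    primary responders, >= 1 s post-stimulus, only with coupling on.
    """
    dt = config.frame_interval_s
    resp = np.flatnonzero(_responsive_flags(config, rng))
    partners = _draw_partners(config, rng, resp)
    rows: list[tuple] = []

    def jitter_amp(base: float, gain: float) -> float:
        j = 1.0 + config.amplitude_jitter * rng.standard_normal()
        return base * gain * max(j, 0.1)

    for s, onset in enumerate(schedule.onsets_s):
        hour = config.hour_of(onset)
        g_amp, g_resp, g_conn = config.circadian.gains(hour)
        p_resp = min(1.0, config.response_prob * g_resp)
        p_casc = min(1.0, config.participation * g_conn)
        anchor = dt * np.ceil((onset + schedule.pulse_width_s) / dt - 1e-9)
        fired: list[int] = []
        for i in resp:
            if rng.random() >= p_resp:
                continue
            if config.stagger_frames > 1 and rng.random() < p_casc:
                j = int(rng.integers(1, config.stagger_frames))
            else:
                j = 0
            t_ev = anchor + j * dt
            rows.append((i, s, t_ev, t_ev - onset, "primary",
                         jitter_amp(config.primary_amplitude, g_amp)))
            fired.append(i)
        if config.astrocyte_coupling_on and config.secondary_prob > 0:
            seen: set[int] = set()
            for i in fired:
                for q in partners.get(int(i), []):
                    if q in seen or rng.random() >= config.secondary_prob:
                        continue
                    lat = (config.secondary_latency_mean_s
                           + rng.uniform(0.0, 0.4))
                    t_ev = anchor + _snap(lat - dt, dt)
                    if t_ev - onset < 1.0:
                        t_ev = onset + dt * np.ceil(1.0 / dt)
                    rows.append((q, s, t_ev, t_ev - onset, "secondary",
                                 jitter_amp(config.secondary_amplitude, g_amp)))
                    seen.add(q)

    # spontaneous transients inside stimulus-free rendered epochs
    if config.spontaneous_rate_per_h > 0:
        stim_windows = [(o - config.render_margin_s, o + config.render_margin_s)
                        for o in schedule.onsets_s]
        for t0, t1 in windows:
            if any(t0 < b and a < t1 for a, b in stim_windows):
                continue
            span_h = (t1 - t0) / 3600.0
            g_amp = config.circadian.gains(config.hour_of(t0))[0]
            for i in resp:
                n = rng.poisson(config.spontaneous_rate_per_h * span_h)
                times = np.sort(rng.uniform(t0 + 1.0, t1 - 1.0, size=n))
                last = -np.inf
                for t_ev in times:
                    t_ev = _snap(t_ev, dt)
                    if t_ev - last < 2.0:
                        continue  # keep transients separable
                    rows.append((i, -1, t_ev, np.nan, "spontaneous",
                                 jitter_amp(config.spontaneous_amplitude, g_amp)))
                    last = t_ev

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events = events.sort_values("t_onset_s", kind="stable").reset_index(drop=True)
    return events, resp, partners


def _responsive_flags(config: SessionConfig, rng: np.random.Generator
                      ) -> np.ndarray:
    flags = np.zeros(config.n_neurons, dtype=bool)
    chosen = rng.choice(config.n_neurons, size=config.n_responsive, replace=False)
    flags[chosen] = True
    return flags


def _draw_partners(config: SessionConfig, rng: np.random.Generator,
                   resp: np.ndarray) -> dict[int, list[int]]:
    partners: dict[int, list[int]] = {}
    if not config.astrocyte_coupling_on or resp.size < 2:
        return partners
    for i in resp:
        others = resp[resp != i]
        k = min(config.n_partners, others.size)
        partners[int(i)] = [int(q) for q in
                            rng.choice(others, size=k, replace=False)]
    return partners


# ---------------------------------------------------------------------------
# transient shape and frame rendering
# ---------------------------------------------------------------------------

def transient_exposure_average(times_s: np.ndarray, t_onset: float,
                               amplitude: float, t_half_s: float,
                               dt: float) -> np.ndarray:
    """Exposure-averaged activation of one transient at the given frame times.

    Model: activation = A on [t_onset, t_onset + dt), then
    A * 2^(-(t - t_onset - dt)/t_half). The frame spanning [t, t + dt)
    records the time average, so the onset frame reads exactly A and the
    total (sum * dt) equals the closed-form integral A*(dt + t_half/ln 2).
    """
    t = np.asarray(times_s, dtype=float)
    out = np.zeros_like(t)
    rel = t - t_onset
    tau = t_half_s / np.log(2.0)
    # frames fully in the decay phase
    dec = rel >= dt - 1e-9
    x = rel[dec] - dt
    out[dec] = amplitude * tau / dt * (np.exp(-x / tau)
                                       - np.exp(-(x + dt) / tau))
    # the onset frame (flat top)
    on = (rel > -1e-9) & (rel < dt - 1e-9)
    out[on] = amplitude
    return out


def transient_integral(amplitude: float, t_half_s: float, dt: float) -> float:
    """Closed-form time integral of the flat-top + exponential transient."""
    return amplitude * (dt + t_half_s / np.log(2.0))


def _activation_series(times_s: np.ndarray, events: pd.DataFrame, neuron: int,
                       config: SessionConfig) -> np.ndarray:
    act = np.zeros_like(times_s)
    sub = events[events["neuron"] == neuron]
    dt = config.frame_interval_s
    horizon = config.t_half_decay_s * 12 + dt
    for t_ev, amp in zip(sub["t_onset_s"].to_numpy(), sub["amplitude"].to_numpy()):
        i0 = np.searchsorted(times_s, t_ev - 1e-9)
        i1 = np.searchsorted(times_s, t_ev + horizon)
        act[i0:i1] += transient_exposure_average(
            times_s[i0:i1], t_ev, amp, config.t_half_decay_s, dt)
    return act


def _render_stack(config: SessionConfig, schedule: StimulationSchedule,
                  times_s: np.ndarray, positions: np.ndarray,
                  events: pd.DataFrame, rng: np.random.Generator) -> MovieStack:
    n_frames = times_s.size
    h = w = config.field_size
    gain = np.asarray(config.substrate_gain(times_s), dtype=np.float32)
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    frames[:] = gain[:, None, None] * np.float32(config.background_level)

    blob, half = _gaussian_blob(config.cell_radius_px)
    blob = blob.astype(np.float32)
    for i, (cy, cx) in enumerate(positions):
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = iy - half, iy + half + 1
        x0, x1 = ix - half, ix + half + 1
        act = _activation_series(times_s, events, i, config).astype(np.float32)
        amp_t = gain * np.float32(config.cell_brightness) * (1.0 + act)
        frames[:, y0:y1, x0:x1] += amp_t[:, None, None] * blob

    if config.noise_sd > 0:
        chunk = 2000
        for a in range(0, n_frames, chunk):
            b = min(a + chunk, n_frames)
            frames[a:b] += rng.normal(
                0.0, config.noise_sd, size=frames[a:b].shape).astype(np.float32)
        np.clip(frames, 0.0, None, out=frames)

    masked = deadtime_mask(times_s, config.exposure_ms, schedule)
    return MovieStack(frames=frames, times_s=times_s,
                      exposure_ms=config.exposure_ms,
                      pixel_scale_um=config.pixel_scale_um, masked=masked)


# ---------------------------------------------------------------------------
# public simulator operations
# ---------------------------------------------------------------------------

def simulate_session(config: SessionConfig, schedule: StimulationSchedule
                     ) -> tuple[MovieStack, CellMap]:
    """Simulate a full recording session (sparse-rendered movie + ground truth)."""
    if schedule.n_stimuli and schedule.onsets_s[-1] >= config.duration_s:
        raise ValueError("schedule extends past the session duration")
    rng = np.random.default_rng(config.seed)
    margin = 3 * config.cell_radius_px + 2
    min_sep = max(10.0, 3.0 * config.cell_radius_px)
    positions = _place_cells(rng, config.n_neurons, config.field_size,
                             margin, min_sep)
    windows = render_windows(config, schedule)
    times = frame_grid(config, windows)
    events, resp, partners = _generate_events(config, schedule, rng, windows)
    responsive = np.zeros(config.n_neurons, dtype=bool)
    responsive[resp] = True
    stack = _render_stack(config, schedule, times, positions, events, rng)
    cellmap = CellMap(
        positions_px=positions,
        radii_px=np.full(config.n_neurons, config.cell_radius_px),
        responsive=responsive,
        partners=partners,
        events=events,
        pixel_scale_um=config.pixel_scale_um,
    )
    return stack, cellmap


def simulate_hek_trace(config: SessionConfig, schedule: StimulationSchedule
                       ) -> tuple[TraceMatrix, CellMap]:
    """Single-cell transient trace under direct pulse stimulation.

    Each pulse evokes a transient peaking at ``fold_change`` times baseline
    in the first unmasked frame after pulse end, then decaying exponentially
    with the configured half-life. Intensity is point-sampled at the frame
    grid; Gaussian noise of ``noise_sd`` counts is added per frame.
    """
    if config.frame_interval_s > config.t_half_decay_s:
        raise ValueError(
            f"frame interval {config.frame_interval_s * 1e3:.0f} ms is too "
            f"coarse to resolve a {config.t_half_decay_ms:.0f} ms half-life "
            "decay; use a finer frame interval")
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_s
    times = np.arange(0.0, config.duration_s, dt)
    masked = deadtime_mask(times, config.exposure_ms, schedule)
    amp = config.fold_change - 1.0
    act = np.zeros_like(times)
    rows = []
    for s, offset in enumerate(schedule.offsets_s()):
        candidates = np.flatnonzero((times >= offset - 1e-9) & ~masked)
        if candidates.size == 0:
            continue
        i0 = candidates[0]
        t_ev = times[i0]
        decay = 0.5 ** ((times[i0:] - t_ev) / config.t_half_decay_s)
        act[i0:] += amp * decay
        rows.append((0, s, t_ev, t_ev - schedule.onsets_s[s], "primary", amp))
    gain = np.asarray(config.substrate_gain(times))
    intensity = gain * config.cell_brightness * (1.0 + act)
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=times.size)
    dff, baselines, baseline_ok, stim_of_frame = compute_dff(
        intensity[None, :], times, masked, schedule)
    tm = TraceMatrix(
        roi_ids=np.array([1]), times_s=times, intensity=intensity[None, :],
        dff=dff, masked=masked, baselines=baselines, baseline_ok=baseline_ok,
        stim_of_frame=stim_of_frame, schedule=schedule)
    cellmap = CellMap(
        positions_px=np.array([[config.field_size / 2, config.field_size / 2]]),
        radii_px=np.array([config.cell_radius_px]),
        responsive=np.array([True]),
        partners={},
        events=pd.DataFrame(rows, columns=EVENT_COLUMNS),
        pixel_scale_um=config.pixel_scale_um,
    )
    return tm, cellmap


def simulate_photocurrent(pulse: StimulationSchedule,
                          tau_on_ms: float = 32.0, tau_off_ms: float = 68.0,
                          i_max_pa: float = 440.0,
                          sampling_hz: float = 2000.0,
                          post_s: float = 0.5,
                          noise_frac: float = 0.0,
                          seed: int | None = None) -> PhotocurrentTrace:
    """Opsin photocurrent for a single pulse.

    Rise i_max*(1 - exp(-t/tau_on)) during the pulse; exponential decay with
    tau_off after pulse end. ``noise_frac`` adds Gaussian noise with SD
    ``noise_frac * i_max``. Current is reported as magnitude (the physical
    current is inward).
    """
    if pulse.n_stimuli != 1:
        raise ValueError("simulate_photocurrent expects a single-pulse schedule")
    if sampling_hz < 1000.0:
        raise ValueError("sampling rate must be >= 1 kHz")
    width = pulse.pulse_width_s
    if width < tau_on_ms / 1000.0 / 10.0:
        warnings.warn("pulse shorter than tau_on/10: on-time will be "
                      "unidentifiable from this trace", stacklevel=2)
    dt = 1.0 / sampling_hz
    onset = float(pulse.onsets_s[0])
    t = np.arange(0.0, onset + width + post_s, dt)
    tp = t - onset  # time since pulse onset; negative before the pulse
    tau_on = tau_on_ms / 1000.0
    tau_off = tau_off_ms / 1000.0
    i = np.where(
        tp < 0.0,
        0.0,
        np.where(
            tp <= width,
            i_max_pa * (1.0 - np.exp(-np.maximum(tp, 0.0) / tau_on)),
            i_max_pa * (1.0 - np.exp(-width / tau_on))
            * np.exp(-(np.maximum(tp - width, 0.0)) / tau_off),
        ),
    )
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_frac * i_max_pa, size=t.size)
    return PhotocurrentTrace(time_s=t, current_pa=i, tau_on_ms=tau_on_ms,
                             tau_off_ms=tau_off_ms, i_max_pa=i_max_pa)


def simulate_mea(cellmap: CellMap, electrodes_um: np.ndarray,
                 coupling_uv_per_pct: float = 0.17,
                 noise_ratio: float = 0.1,
                 radius_um: float = 50.0,
                 seed: int | None = None) -> MEARecording:
    """Extracellular spikes coupled to the optical primary events.

    Every ground-truth primary event of a neuron within ``radius_um`` of an
    electrode yields one spike on that electrode with clean amplitude
    ``coupling * (dI/I0 in %)``; Gaussian amplitude noise with variance
    ``noise_ratio/(1-noise_ratio)`` times the clean-amplitude variance is
    added, so the population R^2 of amplitude vs optical % has expectation
    ``1 - noise_ratio``.
    """
    if not 0.0 <= noise_ratio < 1.0:
        raise ValueError("noise_ratio must be in [0, 1)")
    electrodes_um = np.asarray(electrodes_um, dtype=float)
    rng = np.random.default_rng(seed)
    pos_um = cellmap.positions_um()
    prim = cellmap.events[cellmap.events["class"] == "primary"]
    rows = []
    for e, epos in enumerate(electrodes_um):
        d = np.hypot(*(pos_um - epos).T)
        near = np.flatnonzero(d <= radius_um)
        if near.size == 0:
            continue
        sub = prim[prim["neuron"].isin(near)]
        for idx, ev in sub.iterrows():
            t_spk = ev["t_onset_s"] - 0.02 + rng.uniform(-0.01, 0.01)
            clean = coupling_uv_per_pct * ev["amplitude"] * 100.0
            rows.append((e, t_spk, clean, idx))
    if not rows:
        warnings.warn("no neuron lies within the coupling radius of any "
                      "electrode: empty recording", stacklevel=2)
        spikes = pd.DataFrame(columns=["electrode", "t_s", "amplitude_uv",
                                       "event_idx"])
        return MEARecording(positions_um=electrodes_um, spikes=spikes)
    spikes = pd.DataFrame(rows, columns=["electrode", "t_s", "amplitude_uv",
                                         "event_idx"])
    clean = spikes["amplitude_uv"].to_numpy()
    if noise_ratio > 0 and clean.size > 1:
        sd = np.sqrt(noise_ratio / (1.0 - noise_ratio) * clean.var(ddof=0))
        spikes["amplitude_uv"] = np.maximum(
            clean + rng.normal(0.0, sd, size=clean.size), 0.1)
    spikes = spikes.sort_values("t_s").reset_index(drop=True)
    return MEARecording(positions_um=electrodes_um, spikes=spikes)


def simulate_spatial_scene(n_rows: int = 5, n_cols: int = 6,
                           pitch_um: float = 150.0,
                           spatial_noise: float = 0.12,
                           events_per_neuron: int = 10,
                           neurons_per_disc: float = 6.0,
                           pixel_scale_um: float = 2.0,
                           radius_um: float = 50.0,
                           seed: int | None = None
                           ) -> tuple[np.ndarray, float, MEARecording]:
    """Benchmark scene for the electrode-neighborhood spatial correlation.

    Cells (binary discs in the activity map) are scattered with a uniform
    density, each emitting ``events_per_neuron`` events; every electrode's
    clean spike count is proportional to the number of cells within
    ``radius_um``. Cell centers are kept clear of the electrode-disc
    boundary band so the active-area fraction inside each disc is exactly
    proportional to the enclosed-cell count, and Gaussian count noise with
    variance ``spatial_noise/(1-spatial_noise)`` times the clean-count
    variance makes the expected area-vs-count R^2 equal 1 - spatial_noise.

    Returns (activity_map, pixel_scale_um, MEARecording).
    """
    rng = np.random.default_rng(seed)
    margin = radius_um + 30.0
    electrodes = mea_grid(n_rows, n_cols, pitch_um, (margin, margin))
    extent = electrodes.max(axis=0) + margin
    h, w = int(extent[0] / pixel_scale_um), int(extent[1] / pixel_scale_um)
    disc_area = np.pi * radius_um ** 2
    density = neurons_per_disc / disc_area
    n_cells = rng.poisson(density * extent[0] * extent[1])

    cell_r_um = 4.0
    band = (radius_um - cell_r_um - 2.0, radius_um + cell_r_um + 2.0)
    cells = []
    tries = 0
    while len(cells) < n_cells and tries < 100000:
        tries += 1
        cand = rng.uniform([0, 0], extent)
        d = np.hypot(*(electrodes - cand).T)
        if np.any((d > band[0]) & (d < band[1])):
            continue  # boundary band: would make area vs count ambiguous
        if cells and np.min(np.hypot(*(np.asarray(cells) - cand).T)) < 2.5 * cell_r_um:
            continue
        cells.append(cand)
    cells = np.asarray(cells) if cells else np.empty((0, 2))

    activity = np.zeros((h, w), dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w].astype(float) * pixel_scale_um
    stamp_r_px = cell_r_um / pixel_scale_um
    for cy, cx in cells:
        iy, ix = int(round(cy / pixel_scale_um)), int(round(cx / pixel_scale_um))
        half = int(np.ceil(stamp_r_px)) + 1
        ys, ye = max(iy - half, 0), min(iy + half + 1, h)
        xs, xe = max(ix - half, 0), min(ix + half + 1, w)
        yy, xx = np.mgrid[ys:ye, xs:xe]
        activity[ys:ye, xs:xe] |= ((yy - iy) ** 2 + (xx - ix) ** 2
                                   <= stamp_r_px ** 2)

    counts = np.array([
        np.count_nonzero(np.hypot(*(cells - e).T) <= radius_um) if len(cells) else 0
        for e in electrodes], dtype=float) * events_per_neuron
    if spatial_noise > 0 and counts.size > 1:
        sd = np.sqrt(spatial_noise / (1.0 - spatial_noise) * counts.var(ddof=0))
        counts = np.maximum(np.rint(counts + rng.normal(0, sd, counts.size)), 0)
    rows = []
    for e, n in enumerate(counts.astype(int)):
        for k in range(n):
            rows.append((e, 0.1 * k, 50.0, -1))
    spikes = pd.DataFrame(rows, columns=["electrode", "t_s", "amplitude_uv",
                                         "event_idx"])
    return activity, pixel_scale_um, MEARecording(positions_um=electrodes,
                                                  spikes=spikes)


def simulate_concomitant(n_pulses: int = 40,
                         pct_per_pa: float = 0.5,
                         i_max_pa: float = 440.0,
                         noise_frac: float = 0.02,
                         seed: int | None = None) -> pd.DataFrame:
    """Concomitant photocurrent / optical-response peak pairs.

    Each pulse drives a fractional activation; the photocurrent peak scales
    linearly with drive and the optical peak (in %) is ``pct_per_pa`` times
    the current, both with small measurement noise. At the default preset a
    2 pA change in current corresponds to a 1% change in optical signal.
    """
    rng = np.random.default_rng(seed)
    drive = rng.uniform(0.3, 1.0, size=n_pulses)
    current = i_max_pa * drive * (1 + noise_frac * rng.standard_normal(n_pulses))
    optical = (pct_per_pa * i_max_pa * drive
               * (1 + noise_frac * rng.standard_normal(n_pulses)))
    return pd.DataFrame({"current_pa": current, "optical_pct": optical})


def simulate_intensity_series(intensities_uw_mm2=(5.0, 10.0, 15.0, 20.0),
                              n_events: int = 40,
                              saturating: bool = True,
                              i_sat_uw_mm2: float = 8.0,
                              optical_max_pct: float = 350.0,
                              uv_per_intensity: float = 2.5,
                              jitter: float = 0.15,
                              noise_frac: float = 0.03,
                              seed: int | None = None) -> pd.DataFrame:
    """Paired optical/electrical observations across stimulation intensities.

    With ``saturating`` the optical peak follows
    ``optical_max * (1 - exp(-I/I_sat))`` while the electrical amplitude
    stays linear in intensity, so the electrical-vs-optical slope rises
    with intensity; without it both are linear and the slope is constant.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for inten in intensities_uw_mm2:
        if saturating:
            o_level = optical_max_pct * (1 - np.exp(-inten / i_sat_uw_mm2))
        else:
            o_level = optical_max_pct / 20.0 * inten
        for _ in range(n_events):
            s = max(1 + jitter * rng.standard_normal(), 0.1)
            optical = o_level * s * (1 + noise_frac * rng.standard_normal())
            amp = (uv_per_intensity * inten * s
                   * (1 + noise_frac * rng.standard_normal()))
            rows.append((inten, optical, amp))
    return pd.DataFrame(rows, columns=["intensity_uw_mm2", "optical_pct",
                                       "amplitude_uv"])
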