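"""Per-ROI intensity and dI/I0 traces.

The core activity statistic is the fractional change

    dI/I0 = (I - I0) / I0,

where I is the background-subtracted ROI intensity and I0 the ambient
(pre-stimulus) intensity: the mean over a baseline window immediately
preceding each stimulation. I0 is recomputed per stimulus, which is what
cancels the slow decay of the luciferase substrate — any multiplicative gain
common to baseline and transient divides out.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .roi import ROISet, _robust_sd
from .schedule import StimulationSchedule
from .stack import MovieStack


@dataclass
class TraceMatrix:
    """Per-ROI intensity and dI/I0 time series.

    ``intensity`` and ``dff`` are (n_rois, n_frames); masked frames carry
    NaN in ``dff``. ``baselines`` is (n_rois, n_stimuli) with the I0 used
    for each stimulus segment (a single column for unstimulated sessions);
    ``baseline_ok`` flags stimuli whose baseline window was usable.
    ``stim_of_frame`` maps each frame to the stimulus governing its baseline
    (-1 for frames before the first stimulus in an unstimulated prefix).
    """

    roi_ids: np.ndarray
    times_s: np.ndarray
    intensity: np.ndarray
    dff: np.ndarray
    masked: np.ndarray
    baselines: np.ndarray
    baseline_ok: np.ndarray
    stim_of_frame: np.ndarray
    schedule: StimulationSchedule

    @property
    def n_rois(self) -> int:
        return int(self.roi_ids.size)

    def roi_index(self, roi_id: int) -> int:
        return int(np.flatnonzero(self.roi_ids == roi_id)[0])

    def trace(self, roi_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(times, dff) for one ROI."""
        return self.times_s, self.dff[self.roi_index(roi_id)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: roi_id, t_s, intensity, dI_over_I0."""
        n_r, n_t = self.intensity.shape
        return pd.DataFrame({
            "roi_id": np.repeat(self.roi_ids, n_t),
            "t_s": np.tile(self.times_s, n_r),
            "intensity": self.intensity.ravel(),
            "dI_over_I0": self.dff.ravel(),
        })

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_dff(intensity: np.ndarray, times_s: np.ndarray, masked: np.ndarray,
                schedule: StimulationSchedule,
                baseline_window_s: float = 1.0,
                min_baseline_frames: int = 2,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-stimulus re-baselined dI/I0.

    Returns (dff, baselines, baseline_ok, stim_of_frame). For each stimulus
    the baseline is the mean intensity over the unmasked frames in
    ``[onset - baseline_window_s, onset)``; the stimulus segment runs from
    its onset to the next onset. Frames before the first stimulus use the
    first stimulus' baseline. With no stimuli at all, the per-ROI median
    over unmasked frames serves as I0. A stimulus whose baseline window has
    fewer than ``min_baseline_frames`` unmasked frames is flagged unusable
    and its segment left NaN.
    """
    intensity = np.atleast_2d(np.asarray(intensity, dtype=float))
    n_rois, n_frames = intensity.shape
    t = np.asarray(times_s, dtype=float)
    ok = ~np.asarray(masked, dtype=bool)
    dff = np.full_like(intensity, np.nan)

    if schedule.n_stimuli == 0:
        i0 = np.median(intensity[:, ok], axis=1, keepdims=True)
        stim_of_frame = np.full(n_frames, -1, dtype=int)
        with np.errstate(divide="ignore", invalid="ignore"):
            dff[:, ok] = (intensity[:, ok] - i0) / i0
        return dff, i0, np.ones((n_rois, 1), dtype=bool), stim_of_frame

    onsets = schedule.onsets_s
    n_stim = onsets.size
    baselines = np.full((n_rois, n_stim), np.nan)
    baseline_ok = np.zeros((n_rois, n_stim), dtype=bool)
    # segment s: [onset_s, onset_{s+1}); prefix frames mapped to stimulus 0
    stim_of_frame = np.searchsorted(onsets, t, side="right") - 1

    for s, onset in enumerate(onsets):
        win = ok & (t >= onset - baseline_window_s) & (t < onset)
        if win.sum() < min_baseline_frames:
            continue
        i0 = intensity[:, win].mean(axis=1)
        baselines[:, s] = i0
        baseline_ok[:, s] = i0 != 0
        seg = ok & (stim_of_frame == s if s > 0 else stim_of_frame <= 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            dff[:, seg] = (intensity[:, seg] - i0[:, None]) / i0[:, None]
        bad = np.flatnonzero(~baseline_ok[:, s])
        if bad.size:
            dff[np.ix_(bad, np.flatnonzero(seg))] = np.nan
    return dff, baselines, baseline_ok, stim_of_frame


def extract_traces(stack: MovieStack, rois: ROISet,
                   schedule: StimulationSchedule,
                   baseline_window_s: float = 1.0,
                   annulus_radii: tuple[float, float] = (2.0, 4.0),
                   ) -> TraceMatrix:
    """Per-ROI traces with local-annulus background subtraction.

    ROI intensity per frame is the mean over the ROI mask minus the median
    over a surrounding annulus (``annulus_radii`` in units of the ROI's
    equivalent radius), realizing intensity measured relative to the
    surrounding background. Annulus pixels belonging to any glowing source
    are excluded: sources are all pixels above the session mean image's
    median plus 5 robust SDs, which removes both assigned ROIs and cells
    that glow at baseline without responding (their light would otherwise
    bias the background estimate upward and inflate dI/I0). dI/I0 then
    follows per-stimulus re-baselining (:func:`compute_dff`).
    """
    h, w = stack.shape
    rows, cols = np.mgrid[0:h, 0:w]
    n_frames = stack.n_frames
    intensity = np.empty((rois.n_rois, n_frames))
    radii = rois.radii_px()
    flat = stack.frames.reshape(n_frames, -1)

    mean_img = stack.frames.mean(axis=0, dtype=np.float64)
    source = (mean_img > np.median(mean_img) + 5.0 * _robust_sd(mean_img))
    source |= rois.label_image > 0

    for k, roi_id in enumerate(rois.ids):
        mask = rois.label_image == roi_id
        cy, cx = rois.centroids_px[k]
        dist = np.hypot(rows - cy, cols - cx)
        r = max(radii[k], 1.0)
        ring = (dist >= annulus_radii[0] * r) & (dist <= annulus_radii[1] * r)
        ann = ring & ~source
        if ann.sum() < 10:  # crowded neighborhood: fall back to the raw ring
            ann = ring & ~(rois.label_image > 0)
        roi_mean = flat[:, mask.ravel()].mean(axis=1)
        if ann.any():
            bg = np.median(flat[:, ann.ravel()], axis=1)
        else:
            bg = np.zeros(n_frames)
        intensity[k] = roi_mean - bg

    dff, baselines, baseline_ok, stim_of_frame = compute_dff(
        intensity, stack.times_s, stack.masked, schedule, baseline_window_s)
    return TraceMatrix(
        roi_ids=rois.ids.copy(),
        times_s=stack.times_s.copy(),
        intensity=intensity,
        dff=dff,
        masked=stack.masked.copy(),
        baselines=baselines,
        baseline_ok=baseline_ok,
        stim_of_frame=stim_of_frame,
        schedule=schedule,
    )
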