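"""Active-neuron detection and ROI assignment.

ROIs are assigned once, from the response to the first stimulation of a
session (the reference image), and held fixed for the rest of the recording.
Detection works on a stimulus-evoked change image — the first unmasked
post-stimulus frame minus the mean pre-stimulus baseline frame — so that
cells which glow at baseline but never respond are not picked up. A median
filter removes residual smooth background before robust thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.registration import phase_cross_correlation

from .schedule import StimulationSchedule
from .stack import MovieStack


@dataclass
class ROISet:
    """Labeled pixel masks for the assigned neurons.

    ``label_image`` holds the ROI id at each member pixel (0 = background);
    ids are 1..R, ordered by descending peak response intensity. Centroids
    are intensity-weighted, in (row, col) pixel coordinates.
    """

    label_image: np.ndarray
    ids: np.ndarray
    centroids_px: np.ndarray
    pixel_scale_um: float
    assignment_frame: int = 0

    @property
    def n_rois(self) -> int:
        return int(self.ids.size)

    def mask(self, roi_id: int) -> np.ndarray:
        return self.label_image == roi_id

    def centroids_um(self) -> np.ndarray:
        return self.centroids_px * self.pixel_scale_um

    def areas_px(self) -> np.ndarray:
        return np.array([(self.label_image == i).sum() for i in self.ids])

    def radii_px(self) -> np.ndarray:
        """Equivalent-circle radius per ROI."""
        return np.sqrt(self.areas_px() / np.pi)


def _robust_sd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def response_image(stack: MovieStack, schedule: StimulationSchedule,
                   baseline_window_s: float = 1.0,
                   response_window_s: float = 0.6,
                   n_ref_stimuli: int = 10) -> tuple[np.ndarray, int]:
    """Stimulus-evoked change image for ROI assignment.

    For each of the first ``n_ref_stimuli`` stimuli with usable frames, the
    per-stimulus change image is the pixelwise maximum of the unmasked
    frames within ``response_window_s`` after pulse offset, minus the mean
    pre-stimulus baseline frame; the returned image is the pixelwise
    maximum over those stimuli, so that responders with variable latency or
    occasional failures are still represented. Also returns the index of
    the first post-pulse response frame used. For an empty schedule, falls
    back to the spontaneous activity image: max projection minus median
    projection.
    """
    t = stack.times_s
    ok = ~stack.masked
    if schedule.n_stimuli == 0:
        frames = stack.frames[ok]
        if frames.shape[0] == 0:
            raise ValueError("no unmasked frames")
        img = frames.max(axis=0).astype(float) - np.median(frames, axis=0)
        return img, int(np.flatnonzero(ok)[0])
    img: np.ndarray | None = None
    resp_idx: int | None = None
    n_used = 0
    for onset, offset in zip(schedule.onsets_s, schedule.offsets_s()):
        pre = ok & (t >= onset - baseline_window_s) & (t < onset)
        post = ok & (t >= offset) & (t < offset + response_window_s)
        if not pre.any() or not post.any():
            continue
        if resp_idx is None:
            resp_idx = int(np.flatnonzero(post)[0])
        base = stack.frames[pre].mean(axis=0, dtype=np.float64)
        change = stack.frames[post].max(axis=0).astype(np.float64) - base
        img = change if img is None else np.maximum(img, change)
        n_used += 1
        if n_used >= n_ref_stimuli:
            break
    if img is None or resp_idx is None:
        raise ValueError("no stimulus has both an unmasked baseline window "
                         "and an unmasked post-stimulus frame")
    return img, resp_idx


def assign_rois(stack: MovieStack, schedule: StimulationSchedule,
                detect_sigma: float = 5.0, min_area_px: int = 4,
                median_size: int = 15,
                baseline_window_s: float = 1.0) -> ROISet:
    """Detect responding neurons and assign stable ROI identities.

    Pixels of the (median-filter background-subtracted) response image above
    ``detect_sigma`` times the robust noise SD are labeled into connected
    components; components smaller than ``min_area_px`` are discarded as hot
    pixels. ROIs are numbered by descending peak response intensity.
    """
    img, resp_idx = response_image(stack, schedule, baseline_window_s)
    background = ndimage.median_filter(img, size=median_size)
    det = img - background
    sd = _robust_sd(det)
    if sd == 0:
        sd = np.finfo(float).tiny  # flat image -> nothing passes
    labeled = measure.label(det > detect_sigma * sd)
    props = measure.regionprops(labeled, intensity_image=det)
    props = [p for p in props if p.area >= min_area_px]
    if not props:
        warnings.warn("no component passed the detection threshold; "
                      "empty ROI set", stacklevel=2)
        return ROISet(
            label_image=np.zeros(stack.shape, dtype=np.int32),
            ids=np.empty(0, dtype=int),
            centroids_px=np.empty((0, 2)),
            pixel_scale_um=stack.pixel_scale_um,
            assignment_frame=resp_idx,
        )
    props.sort(key=lambda p: -float(p.intensity_max))
    label_image = np.zeros(stack.shape, dtype=np.int32)
    centroids = np.empty((len(props), 2))
    for rank, p in enumerate(props, start=1):
        label_image[labeled == p.label] = rank
        centroids[rank - 1] = p.centroid_weighted
    return ROISet(
        label_image=label_image,
        ids=np.arange(1, len(props) + 1),
        centroids_px=centroids,
        pixel_scale_um=stack.pixel_scale_um,
        assignment_frame=resp_idx,
    )


def check_registration(stack: MovieStack, rois: ROISet,
                       max_shift_px: float = 2.0) -> float:
    """Rigid-shift check between the assignment frame and the last frame.

    Returns the estimated shift magnitude in pixels; warns if it exceeds
    ``max_shift_px`` (ROIs are held fixed, so larger drift would corrupt
    trace extraction).
    """
    ok = np.flatnonzero(~stack.masked)
    ref = stack.frames[rois.assignment_frame].astype(float)
    late = stack.frames[ok[-1]].astype(float)
    shift, _, _ = phase_cross_correlation(ref, late, upsample_factor=10)
    mag = float(np.hypot(*shift))
    if mag > max_shift_px:
        warnings.warn(f"field shift {mag:.2f} px exceeds {max_shift_px} px; "
                      "fixed ROI masks may no longer be valid", stacklevel=2)
    return mag
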