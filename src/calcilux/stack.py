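"""Movie stacks: time-ordered photon-count frames with timing metadata.

Frames whose exposure interval overlaps a stimulation pulse are flagged as
masked (camera deadtime) and carry no analyzable values downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .schedule import StimulationSchedule


@dataclass
class MovieStack:
    """T x H x W photon-count frames with a (possibly non-uniform) timebase.

    ``times_s`` are frame start times; a frame spans
    ``[t, t + exposure_ms/1000)``. ``masked`` flags deadtime frames.
    """

    frames: np.ndarray
    times_s: np.ndarray
    exposure_ms: float
    pixel_scale_um: float
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if self.times_s.shape[0] != self.frames.shape[0]:
            raise ValueError("times_s length must match frame count")
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.frames < 0):
            raise ValueError("photon counts must be >= 0")
        if self.masked is None:
            self.masked = np.zeros(self.frames.shape[0], dtype=bool)
        else:
            self.masked = np.asarray(self.masked, dtype=bool)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def save(self, path: str | Path, schedule: StimulationSchedule | None = None,
             extra: dict | None = None) -> None:
        """Write a multi-page 16-bit TIFF plus a JSON sidecar.

        The sidecar carries frame times, masked-frame indices, the schedule
        and any extra metadata; 16-bit pages clip counts at 65535.
        """
        path = Path(path)
        data = np.clip(np.rint(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack")
        meta = {
            "times_s": self.times_s.tolist(),
            "exposure_ms": self.exposure_ms,
            "pixel_scale_um": self.pixel_scale_um,
            "masked_frames": np.flatnonzero(self.masked).tolist(),
            "schedule": schedule.to_dict() if schedule is not None else None,
        }
        if extra:
            meta.update(extra)
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> tuple["MovieStack", StimulationSchedule | None, dict]:
        """Read a TIFF + sidecar pair written by :meth:`save`."""
        path = Path(path)
        frames = tifffile.imread(path).astype(np.float64)
        if frames.ndim == 2:
            frames = frames[None]
        meta = json.loads(path.with_suffix(".json").read_text())
        masked = np.zeros(frames.shape[0], dtype=bool)
        masked[np.asarray(meta.get("masked_frames", []), dtype=int)] = True
        stack = cls(
            frames=frames,
            times_s=np.asarray(meta["times_s"], dtype=float),
            exposure_ms=float(meta["exposure_ms"]),
            pixel_scale_um=float(meta["pixel_scale_um"]),
            masked=masked,
        )
        sched = None
        if meta.get("schedule"):
            sched = StimulationSchedule.from_dict(meta["schedule"])
        return stack, sched, meta


def deadtime_mask(times_s: np.ndarray, exposure_ms: float,
                  schedule: StimulationSchedule) -> np.ndarray:
    """Flag frames whose exposure interval overlaps any stimulation pulse."""
    masked = np.zeros(times_s.shape[0], dtype=bool)
    exp_s = exposure_ms / 1000.0
    for onset, offset in zip(schedule.onsets_s, schedule.offsets_s()):
        masked |= (times_s < offset) & (times_s + exp_s > onset)
    return masked
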