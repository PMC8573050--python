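"""Stimulation schedules: pulse onsets, widths and intensities.

A schedule drives both the forward simulator (when transients are evoked,
which camera frames are masked as deadtime) and the analysis (baseline
windows, response latencies are all measured relative to pulse onsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class StimulationSchedule:
    """A sequence of light stimulation pulses.

    Parameters
    ----------
    onsets_s
        Pulse onset times in seconds from session start, strictly increasing.
    pulse_width_ms
        Pulse duration in milliseconds (> 0).
    intensity_uw_mm2
        Stimulation intensity in uW/mm^2.
    repetition_rate_hz
        Nominal repetition rate; informational only.
    """

    onsets_s: np.ndarray
    pulse_width_ms: float = 100.0
    intensity_uw_mm2: float = 15.0
    repetition_rate_hz: float | None = None

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        object.__setattr__(self, "onsets_s", onsets)
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be > 0")
        if onsets.ndim != 1:
            raise ValueError("onsets_s must be one-dimensional")
        if onsets.size > 1:
            gaps = np.diff(onsets)
            if np.any(gaps <= 0):
                raise ValueError("onsets_s must be strictly increasing")
            if np.any(gaps < self.pulse_width_ms / 1000.0):
                raise ValueError("inter-pulse intervals must be >= pulse width")

    @property
    def n_stimuli(self) -> int:
        return int(self.onsets_s.size)

    @property
    def pulse_width_s(self) -> float:
        return self.pulse_width_ms / 1000.0

    def offsets_s(self) -> np.ndarray:
        """Pulse end times in seconds."""
        return self.onsets_s + self.pulse_width_s

    @classmethod
    def periodic(
        cls,
        n_stimuli: int,
        interval_s: float,
        start_s: float = 0.0,
        pulse_width_ms: float = 100.0,
        intensity_uw_mm2: float = 15.0,
    ) -> "StimulationSchedule":
        """Evenly spaced pulse train: ``n_stimuli`` pulses every ``interval_s``."""
        onsets = start_s + interval_s * np.arange(n_stimuli, dtype=float)
        return cls(
            onsets_s=onsets,
            pulse_width_ms=pulse_width_ms,
            intensity_uw_mm2=intensity_uw_mm2,
            repetition_rate_hz=1.0 / interval_s if interval_s > 0 else None,
        )

    @classmethod
    def hourly_blocks(
        cls,
        hours: int,
        per_hour: int,
        interval_s: float = 12.0,
        start_hour: float = 0.0,
        pulse_width_ms: float = 10.0,
        intensity_uw_mm2: float = 13.0,
        start_offset_s: float = 2.0,
    ) -> "StimulationSchedule":
        """Block of ``per_hour`` pulses at the start of each recording hour.

        Mirrors a long session in which a short train of visual stimuli is
        delivered at every time point of a multi-hour recording. Each block
        starts ``start_offset_s`` into its hour so the first pulse still has
        a pre-stimulus baseline window.
        """
        onsets = []
        for h in range(hours):
            t0 = (start_hour + h) * 3600.0 + start_offset_s
            onsets.extend(t0 + interval_s * np.arange(per_hour))
        return cls(
            onsets_s=np.asarray(onsets, dtype=float),
            pulse_width_ms=pulse_width_ms,
            intensity_uw_mm2=intensity_uw_mm2,
        )

    def to_dict(self) -> dict:
        return {
            "onsets_s": self.onsets_s.tolist(),
            "pulse_width_ms": self.pulse_width_ms,
            "intensity_uw_mm2": self.intensity_uw_mm2,
            "repetition_rate_hz": self.repetition_rate_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationSchedule":
        return cls(
            onsets_s=np.asarray(d["onsets_s"], dtype=float),
            pulse_width_ms=float(d["pulse_width_ms"]),
            intensity_uw_mm2=float(d["intensity_uw_mm2"]),
            repetition_rate_hz=d.get("repetition_rate_hz"),
        )


def empty_schedule() -> StimulationSchedule:
    """Schedule with no pulses (spontaneous-activity recordings)."""
    return StimulationSchedule(onsets_s=np.empty(0), pulse_width_ms=1.0)
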