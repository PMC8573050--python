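"""Session configuration for the forward simulator, plus shipped presets.

The configuration collects every generative parameter of the simulator:
geometry (field size, cell positions are drawn at random within it), optics
(frame interval, exposure, camera noise), sensor kinetics (decay half-life),
response statistics (amplitudes, response probability, secondary latency),
slow modulations (substrate decay/replenishment, per-hour circadian gains)
and the seed.

Three presets are shipped:

``hek``
    A single transfected cell under direct pulse stimulation: threefold
    peak/baseline transients decaying with a 216 ms half-life.
``slice``
    A cortical-slice field on a multi-electrode array: many responsive
    cells, used for optical-electrical correlation work.
``invivo``
    A cortical field imaged through a cranial window for 14 h: 8 responsive
    neurons among ~50 glowing cells, 300% primary transients, delayed
    astrocyte-mediated secondary events, substrate decay with 3-hourly
    replenishment, and circadian gains peaking at recording hours 7-8.
``baseline``
    No stimulation: sparse spontaneous transients near 50% dI/I0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

# Hours (recording time) over which circadian gains exceed unity in the
# in-vivo preset: activity peaks at the 7th-8th recording hour.
PEAK_HOURS = (7, 8)


@dataclass(frozen=True)
class CircadianProfile:
    """Per-hour multiplicative gains applied by the simulator.

    ``amplitude`` scales transient dI/I0, ``response`` scales the per-stimulus
    response probability, ``connectivity`` scales the cascade-participation
    probability that controls how densely the evoked activity is linked in
    time (and hence the inferred network's connection density). Hours absent
    from a mapping have gain 1.0.
    """

    amplitude: dict[int, float] = field(default_factory=dict)
    response: dict[int, float] = field(default_factory=dict)
    connectivity: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.amplitude, self.response, self.connectivity):
            if any(g <= 0 for g in m.values()):
                raise ValueError("circadian gains must be > 0")

    def gains(self, hour: int) -> tuple[float, float, float]:
        """(amplitude, response-probability, connectivity) gains at ``hour``."""
        return (
            self.amplitude.get(hour, 1.0),
            self.response.get(hour, 1.0),
            self.connectivity.get(hour, 1.0),
        )

    @classmethod
    def flat(cls) -> "CircadianProfile":
        return cls()

    def to_dict(self) -> dict:
        return {
            "amplitude": {str(k): v for k, v in self.amplitude.items()},
            "response": {str(k): v for k, v in self.response.items()},
            "connectivity": {str(k): v for k, v in self.connectivity.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircadianProfile":
        return cls(
            amplitude={int(k): float(v) for k, v in d.get("amplitude", {}).items()},
            response={int(k): float(v) for k, v in d.get("response", {}).items()},
            connectivity={int(k): float(v) for k, v in d.get("connectivity", {}).items()},
        )


@dataclass(frozen=True)
class SessionConfig:
    """All generative parameters of a simulated recording session."""

    # session geometry / timing
    duration_h: float = 1.0
    start_hour: float = 0.0              # recording hour at t = 0 (circadian index)
    n_neurons: int = 50
    n_responsive: int = 8
    field_size: int = 96                 # pixels (square field)
    pixel_scale_um: float = 2.0          # um per pixel
    frame_interval_s: float = 0.1
    exposure_ms: float = 100.0

    # response statistics (dI/I0 is dimensionless fractional change)
    primary_amplitude: float = 3.0
    secondary_amplitude: float = 1.0
    spontaneous_amplitude: float = 0.5
    amplitude_jitter: float = 0.0        # relative SD of per-event amplitude
    response_prob: float = 0.7
    fold_change: float = 3.0             # peak/baseline for the single-cell preset
    t_half_decay_ms: float = 216.0
    secondary_latency_mean_s: float = 1.5
    secondary_prob: float = 0.4          # per stimulus per responsive neuron
    astrocyte_coupling_on: bool = True
    n_partners: int = 2                  # astrocyte partners per responsive neuron
    spontaneous_rate_per_h: float = 20.0  # per responsive neuron, in rendered epochs

    # cascade structure (controls evoked-latency staggering -> connectivity)
    stagger_frames: int = 5              # latency cascade depth, frames after stimulus
    participation: float = 1.0           # base probability of joining the cascade

    # slow modulations
    circadian: CircadianProfile = field(default_factory=CircadianProfile.flat)
    substrate_half_decay_h: float = 2.5
    substrate_replenish_h: float = 3.0

    # rendering / camera
    background_level: float = 100.0      # substrate glow floor, counts/pixel
    cell_brightness: float = 150.0       # baseline cell peak brightness, counts
    cell_radius_px: float = 3.0
    noise_sd: float = 0.0                # Gaussian counts per pixel per frame
    background_epoch_s: float = 60.0     # rendered unstimulated epoch per hour
    render_margin_s: float = 5.0         # rendered margin around each stimulus

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.response_prob <= 1.0:
            raise ValueError("response_prob must be in [0, 1]")
        if self.n_responsive > self.n_neurons:
            raise ValueError("n_responsive cannot exceed n_neurons")
        if self.secondary_latency_mean_s < 1.0:
            raise ValueError("secondary_latency_mean_s must be >= 1 s")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if not 0.0 < self.participation <= 1.0:
            raise ValueError("participation must be in (0, 1]")

    @property
    def duration_s(self) -> float:
        return self.duration_h * 3600.0

    @property
    def t_half_decay_s(self) -> float:
        return self.t_half_decay_ms / 1000.0

    def substrate_gain(self, t_s: np.ndarray | float) -> np.ndarray | float:
        """Global substrate gain at time ``t_s``.

        The luciferase substrate decays with half-life ``substrate_half_decay_h``
        and is replenished (gain reset to 1) every ``substrate_replenish_h``.
        """
        t = np.asarray(t_s, dtype=float)
        phase = np.mod(t, self.substrate_replenish_h * 3600.0)
        gain = 0.5 ** (phase / (self.substrate_half_decay_h * 3600.0))
        return gain if gain.shape else float(gain)

    def hour_of(self, t_s: float) -> int:
        """Recording-hour index (circadian index) of session time ``t_s``."""
        return int(np.floor(self.start_hour + t_s / 3600.0))

    def replace(self, **kw) -> "SessionConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["circadian"] = self.circadian.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if "circadian" in d and not isinstance(d["circadian"], CircadianProfile):
            d["circadian"] = CircadianProfile.from_dict(d["circadian"])
        return cls(**d)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Calibrated split of the fourfold peak NAP gain at hours 7-8 into an
# amplitude factor and a connectivity factor (see docs/methods.md).  The
# connectivity side raises the cascade participation from its off-peak base
# of 0.2 to 1.0 at the peak hours, which multiplies the NAP by ~1.55
# (measured through the full pipeline); the amplitude gain 2.5 supplies the
# rest (2.5 x 1.55 ~ 4; measured fold 3.85 +- 0.24 over 10 seeds).
_INVIVO_PARTICIPATION = 0.2
_PEAK_AMPLITUDE_GAIN = 2.5


def _invivo_circadian() -> CircadianProfile:
    conn_gain = 1.0 / _INVIVO_PARTICIPATION
    return CircadianProfile(
        amplitude={h: _PEAK_AMPLITUDE_GAIN for h in PEAK_HOURS},
        response={},
        connectivity={h: conn_gain for h in PEAK_HOURS},
    )


def hek_preset(seed: int = 0, **overrides) -> SessionConfig:
    """Single transfected cell, direct pulse stimulation, fast imaging."""
    base = SessionConfig(
        duration_h=140.0 / 3600.0,
        n_neurons=1,
        n_responsive=1,
        field_size=32,
        pixel_scale_um=1.0,
        frame_interval_s=0.02,
        exposure_ms=20.0,
        fold_change=3.0,
        primary_amplitude=2.0,       # fold 3 <=> dI/I0 of 2
        amplitude_jitter=0.0,
        response_prob=1.0,
        t_half_decay_ms=216.0,
        astrocyte_coupling_on=False,
        secondary_prob=0.0,
        spontaneous_rate_per_h=0.0,
        noise_sd=0.0,
        seed=seed,
    )
    return base.replace(**overrides)


def slice_preset(seed: int = 0, **overrides) -> SessionConfig:
    """Cortical slice on a multi-electrode array (optical-electrical work)."""
    base = SessionConfig(
        duration_h=600.0 / 3600.0,
        n_neurons=60,
        n_responsive=40,
        field_size=128,
        pixel_scale_um=4.0,
        frame_interval_s=0.1,
        exposure_ms=100.0,
        primary_amplitude=3.0,
        amplitude_jitter=0.15,
        response_prob=0.9,
        secondary_prob=0.2,
        spontaneous_rate_per_h=0.0,
        noise_sd=2.0,
        seed=seed,
    )
    return base.replace(**overrides)


def invivo_preset(seed: int = 0, **overrides) -> SessionConfig:
    """14-hour cranial-window session with circadian modulation."""
    base = SessionConfig(
        duration_h=14.0,
        n_neurons=50,
        n_responsive=8,
        field_size=112,
        pixel_scale_um=2.0,
        frame_interval_s=0.1,
        exposure_ms=100.0,
        primary_amplitude=3.0,
        secondary_amplitude=1.0,
        spontaneous_amplitude=0.5,
        amplitude_jitter=0.15,
        response_prob=0.7,
        secondary_prob=0.4,
        spontaneous_rate_per_h=10.0,
        participation=_INVIVO_PARTICIPATION,
        circadian=_invivo_circadian(),
        substrate_half_decay_h=2.5,
        substrate_replenish_h=3.0,
        noise_sd=4.0,
        seed=seed,
    )
    return base.replace(**overrides)


def baseline_preset(seed: int = 0, **overrides) -> SessionConfig:
    """Unstimulated recording: sparse spontaneous transients near 50% dI/I0."""
    base = SessionConfig(
        duration_h=0.2,
        n_neurons=30,
        n_responsive=8,
        field_size=96,
        pixel_scale_um=2.0,
        frame_interval_s=0.1,
        exposure_ms=100.0,
        spontaneous_amplitude=0.5,
        amplitude_jitter=0.1,
        spontaneous_rate_per_h=60.0,
        secondary_prob=0.0,
        astrocyte_coupling_on=False,
        background_epoch_s=720.0,    # render the whole short session
        noise_sd=3.0,
        seed=seed,
    )
    return base.replace(**overrides)


PRESETS = {
    "hek": hek_preset,
    "slice": slice_preset,
    "invivo": invivo_preset,
    "baseline": baseline_preset,
}
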