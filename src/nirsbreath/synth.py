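"""Class-conditioned synthetic NIRS breathing signals.

Generates chest-hemodynamic concentration-change series for the four breathing
tasks — normal, breath-hold, slow (10 breaths/min) and rapid (30 breaths/min)
— so that every downstream stage (preprocessing, augmentation, training,
evaluation) is exercisable without the study's recordings.

Each channel is modelled as::

    DC offset + linear drift + skewed breathing oscillation
    + cardiac ripple + white noise + Poisson impulse artifacts

A participant draw (shared across the four channels of a recording) fixes the
DC level, oscillation amplitude, waveform skew and drift; channel-specific
gains differentiate the two photodetector depths, and deoxyhemoglobin channels
carry a negative oscillation gain so they move opposite to oxyhemoglobin, as
chest O2Hb/HHb do over the respiratory cycle. Breath-hold is a near-flat trace
with a slow monotone drift rather than an oscillation.

Amplitudes default to order-one concentration units with per-window
peak-to-peak spanning roughly 0.4–2.3, so the dataset-statistics-driven
augmentation operators produce order-one scale factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nirs_io
from .nirs_io import CHANNELS, CLASS_NAMES, DatasetSplit, NIRSRecording

__all__ = [
    "BreathingClassSpec",
    "SimConfig",
    "default_class_specs",
    "simulate_recording",
    "make_dataset",
]

#: Oscillation gain per channel: PD2 (deeper optode) sees a larger response;
#: HHb channels are anticorrelated with O2Hb.
CHANNEL_GAINS: tuple[float, ...] = (1.0, -0.55, 1.25, -0.7)


@dataclass
class BreathingClassSpec:
    """Generative parameters of one breathing class.

    Rates are in breaths/min; amplitudes in concentration units; ranges are
    inclusive uniform-draw bounds per participant.
    """

    name: str
    breathing_rate_range: tuple[float, float]  # breaths/min; (0, 0) for hold
    oscillation_amplitude_range: tuple[float, float] = (0.25, 1.0)
    waveform_skew_range: tuple[float, float] = (-0.6, 0.6)
    dc_offset_range: tuple[float, float] = (-0.5, 0.5)
    drift_slope_range: tuple[float, float] = (-0.01, 0.01)  # units/s
    cardiac_rate_range: tuple[float, float] = (1.0, 1.5)  # Hz
    cardiac_amplitude: float = 0.04
    noise_sd: float = 0.02
    impulse_rate: float = 0.0  # events/min
    impulse_magnitude: float = 4.0

    def __post_init__(self) -> None:
        if self.breathing_rate_range[0] < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be non-negative")
        if self.oscillation_amplitude_range[0] < 0:
            raise ValueError("amplitude range must be non-negative")


def default_class_specs(impulse_rate: float = 0.0) -> dict[str, BreathingClassSpec]:
    """The four study tasks.

    Slow and rapid breathing are paced at 10 and 30 breaths/min; normal
    breathing spans the physiological resting range 12–20 breaths/min, chosen
    to overlap neither paced rate exactly so the classes are learnable but not
    trivially separated. Breath-hold is a near-flat trace with a monotone
    hemodynamic drift. ``impulse_rate`` (events/min) adds voltage-transient
    artifacts for exercising the preprocessing stage.
    """
    specs = {
        "normal": BreathingClassSpec("normal", (12.0, 20.0)),
        "hold": BreathingClassSpec(
            "hold",
            (0.0, 0.0),
            oscillation_amplitude_range=(0.0, 0.02),
            drift_slope_range=(0.02, 0.08),
        ),
        "slow": BreathingClassSpec("slow", (9.5, 10.5)),
        "rapid": BreathingClassSpec("rapid", (29.0, 31.0)),
    }
    if impulse_rate > 0:
        specs = {k: replace(v, impulse_rate=impulse_rate) for k, v in specs.items()}
    return specs


@dataclass
class SimConfig:
    n_participants: int = 14
    duration_per_task: float = 120.0  # seconds, the paced-task length
    sampling_rate: float = 120.0
    window_length: int = nirs_io.DEFAULT_WINDOW_LENGTH
    stride: int = nirs_io.DEFAULT_STRIDE
    n_test_participants: int = 3
    seed: int = 0
    impulse_rate: float = 0.0
    class_specs: dict[str, BreathingClassSpec] | None = field(default=None)

    def __post_init__(self) -> None:
        if min(self.n_participants, self.duration_per_task, self.sampling_rate) <= 0:
            raise ValueError("simulation sizes must be positive")


def draw_participant(rng: np.random.Generator) -> dict[str, float]:
    """Participant-level traits shared across that person's recordings."""
    return {
        "dc": float(rng.uniform(-0.5, 0.5)),
        "amplitude_factor": float(rng.uniform(0.6, 1.4)),
        "skew": float(rng.uniform(-0.6, 0.6)),
        "drift_sign": float(rng.choice([-1.0, 1.0])),
        "cardiac_rate": float(rng.uniform(1.0, 1.5)),
    }


def _breathing_wave(t: np.ndarray, rate_hz: float, skew: float,
                    phase: float) -> np.ndarray:
    """Skewed unit-amplitude breathing oscillation.

    Phase modulation ``sin(theta + skew*sin(theta))`` sharpens one half of the
    cycle relative to the other, emulating unequal inspiration/expiration
    durations, while keeping the fundamental frequency at ``rate_hz``.
    """
    theta = 2 * np.pi * rate_hz * t + phase
    return np.sin(theta + skew * np.sin(theta))


def simulate_recording(
    spec: BreathingClassSpec,
    participant: dict[str, float],
    duration: float,
    fs: float,
    rng: np.random.Generator,
    participant_id: str = "",
) -> NIRSRecording:
    """Simulate one task recording for one participant."""
    n = int(round(duration * fs))
    if n < 1:
        raise ValueError("duration * fs must be >= 1 sample")
    t = np.arange(n) / fs

    rate_bpm = rng.uniform(*spec.breathing_rate_range)
    amp = rng.uniform(*spec.oscillation_amplitude_range) * participant["amplitude_factor"]
    skew = participant["skew"]
    phase = rng.uniform(0, 2 * np.pi)
    drift = rng.uniform(*spec.drift_slope_range) * participant["drift_sign"]
    cardiac_rate = participant["cardiac_rate"]
    cardiac_phase = rng.uniform(0, 2 * np.pi)

    osc = _breathing_wave(t, rate_bpm / 60.0, skew, phase) if rate_bpm > 0 else np.zeros(n)
    cardiac = np.sin(2 * np.pi * cardiac_rate * t + cardiac_phase)

    values = np.empty((len(CHANNELS), n))
    for c, gain in enumerate(CHANNEL_GAINS):
        x = (
            participant["dc"] * np.sign(gain)
            + drift * t
            + amp * gain * osc
            + spec.cardiac_amplitude * abs(gain) * cardiac
            + rng.normal(0.0, spec.noise_sd, n)
        )
        values[c] = x

    if spec.impulse_rate > 0:
        n_events = rng.poisson(spec.impulse_rate * duration / 60.0, size=len(CHANNELS))
        for c in range(len(CHANNELS)):
            if n_events[c] == 0:
                continue
            pos = rng.integers(1, n - 1, size=n_events[c])
            sign = rng.choice([-1.0, 1.0], size=n_events[c])
            values[c, pos] += sign * spec.impulse_magnitude

    return NIRSRecording(
        values=values,
        channels=CHANNELS,
        sampling_rate=fs,
        participant_id=participant_id,
        task_label=spec.name,
    )


def make_dataset(cfg: SimConfig) -> DatasetSplit:
    """Simulate all four tasks for every participant, window, and split.

    Fully deterministic under ``cfg.seed``. The split holds out
    ``cfg.n_test_participants`` people (the study shape is 3 of 14), so no
    participant contributes windows to both sides.
    """
    if cfg.n_participants < 2:
        raise ValueError("need at least 2 participants to split")
    rng = np.random.default_rng(cfg.seed)
    specs = cfg.class_specs or default_class_specs(impulse_rate=cfg.impulse_rate)
    samples = []
    for p in range(cfg.n_participants):
        pid = f"P{p:02d}"
        traits = draw_participant(rng)
        for name in CLASS_NAMES:
            rec = simulate_recording(
                specs[name], traits, cfg.duration_per_task, cfg.sampling_rate,
                rng, participant_id=pid,
            )
            samples.extend(
                nirs_io.window_recording(rec, cfg.window_length, cfg.stride)
            )
    return nirs_io.split_by_participant(
        samples, n_test=cfg.n_test_participants, seed=cfg.seed
    )
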