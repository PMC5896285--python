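"""Synthetic EEG trial generator.

Produces labeled multi-channel trials whose spectra carry the structure the
band-peak features exploit: one dominant alpha-band (8-13 Hz) oscillation and
two weaker beta-band (13-30 Hz) oscillations riding on 1/f-like background
noise.  Amplitudes differ by task class, which is what makes the downstream
classification problem non-trivial but solvable.

The five task labels follow the mental/motor imagery protocol the pipeline
targets: resting state (RS), mental arithmetic (MA), right/left hand motor
imagery (RH/LH), and visual imagination of the letter "A" (LA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TASKS",
    "DEFAULT_CHANNELS",
    "TaskSpectralProfile",
    "TrialRecording",
    "ProfileError",
    "default_profiles",
    "generate_trials",
]

#: Fixed task enumeration; its order is the tie-break order everywhere.
TASKS = ("RS", "MA", "RH", "LH", "LA")

#: Default 9-channel montage (frontal, central, parietal, occipital).
DEFAULT_CHANNELS = ("F3", "F4", "C3", "C4", "P3", "P4", "Pz", "O1", "O2")

ALPHA_RANGE = (8.0, 13.0)   # alpha_freq must lie strictly inside
BETA_RANGE = (13.0, 30.0)   # beta freqs in (13, 30]


class ProfileError(ValueError):
    """A task spectral profile violates a band or amplitude constraint."""


@dataclass(frozen=True)
class TaskSpectralProfile:
    """Spectral recipe for one task class.

    Amplitudes are in arbitrary microvolt-like units; frequencies in Hz.
    ``channel_gains`` scales the oscillatory part per channel (the 1/f noise
    is channel-independent and controlled by ``noise_scale`` alone).
    """

    task_label: str
    alpha_amp: float
    alpha_freq: float
    beta1_amp: float
    beta1_freq: float
    beta2_amp: float
    beta2_freq: float
    noise_scale: float = 1.0
    channel_gains: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.task_label not in TASKS:
            raise ProfileError(
                f"unknown task label {self.task_label!r}; expected one of {TASKS}"
            )
        lo, hi = ALPHA_RANGE
        if not lo < self.alpha_freq < hi:
            raise ProfileError(
                f"{self.task_label}: alpha_freq={self.alpha_freq} not strictly "
                f"inside [{lo}, {hi}]"
            )
        lo, hi = BETA_RANGE
        for name, f in (("beta1_freq", self.beta1_freq), ("beta2_freq", self.beta2_freq)):
            if not lo < f <= hi:
                raise ProfileError(
                    f"{self.task_label}: {name}={f} not inside ({lo}, {hi}]"
                )
        if self.beta1_freq == self.beta2_freq:
            raise ProfileError(f"{self.task_label}: beta1_freq equals beta2_freq")
        for name, a in (
            ("alpha_amp", self.alpha_amp),
            ("beta1_amp", self.beta1_amp),
            ("beta2_amp", self.beta2_amp),
            ("noise_scale", self.noise_scale),
        ):
            if a < 0:
                raise ProfileError(f"{self.task_label}: {name}={a} is negative")
        if any(g < 0 for g in self.channel_gains):
            raise ProfileError(f"{self.task_label}: negative channel gain")


@dataclass(frozen=True)
class TrialRecording:
    """One task trial: a channels x time sample matrix with its metadata."""

    samples: np.ndarray          # shape (n_channels, n_samples), float64
    fs: float                    # sampling rate, Hz
    duration_s: float
    task_label: str
    trial_id: str
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"trial {self.trial_id}: {samples.shape[0]} sample rows but "
                f"{len(self.channel_names)} channel names"
            )
        expected = round(self.fs * self.duration_s)
        if samples.shape[1] != expected:
            raise ValueError(
                f"trial {self.trial_id}: {samples.shape[1]} samples, expected "
                f"round(fs*duration)={expected}"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.task_label not in TASKS:
            raise ValueError(f"unknown task label {self.task_label!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def default_profiles(
    n_channels: int = 9, noise_scale: float = 1.0
) -> list[TaskSpectralProfile]:
    """Default five-task profile set.

    The class structure mirrors what single-channel resting/imagery EEG shows:
    the alpha peak is strongest at rest (RS), letter imagination (LA) keeps a
    high alpha, and the motor imagery tasks (RH/LH) show reduced beta peaks
    (event-related desynchronization).  Motor tasks get a mild contralateral
    gain boost over the central channels when the default montage is in use.
    """
    base = np.ones(n_channels)

    def gains(boost: dict[int, float]) -> tuple[float, ...]:
        g = base.copy()
        for idx, val in boost.items():
            if idx < n_channels:
                g[idx] = val
        return tuple(g)

    # channel indices in DEFAULT_CHANNELS: C3=2, C4=3
    return [
        TaskSpectralProfile("RS", 3.0, 10.0, 1.2, 18.0, 0.9, 24.0,
                            noise_scale, gains({})),
        TaskSpectralProfile("MA", 1.5, 10.5, 1.1, 19.0, 0.8, 23.0,
                            noise_scale, gains({})),
        TaskSpectralProfile("RH", 1.8, 9.5, 0.6, 20.0, 0.45, 25.0,
                            noise_scale, gains({2: 1.15})),
        TaskSpectralProfile("LH", 1.8, 10.0, 0.6, 18.0, 0.45, 26.0,
                            noise_scale, gains({3: 1.15})),
        TaskSpectralProfile("LA", 2.4, 10.0, 1.0, 19.0, 0.85, 24.0,
                            noise_scale, gains({})),
    ]


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f-shaped Gaussian noise with unit standard deviation (analytic norm).

    White Gaussian noise is shaped in the frequency domain with amplitude
    proportional to 1/sqrt(f) for f >= 1 Hz and flat below 1 Hz, then
    normalized by its analytically expected standard deviation so that the
    caller's ``noise_scale`` is (in expectation) the output std.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, 1.0))
    # expected variance of the shaped series: E|W_k|^2 = n per rfft bin
    weight = np.full(f.shape, 2.0)
    weight[0] = 1.0
    if n % 2 == 0:
        weight[-1] = 1.0
    expected_std = np.sqrt(np.sum(weight * shape**2) / n)
    return np.fft.irfft(spec * shape, n) / expected_std


def generate_trials(
    profiles: list[TaskSpectralProfile],
    n_trials_per_task: int,
    fs: float = 512.0,
    duration_s: float = 10.0,
    seed: int = 0,
    jitter: bool = True,
) -> list[TrialRecording]:
    """Generate ``n_trials_per_task`` trials for every profile.

    Each trial's per-channel signal is

        gain_c * (alpha + beta1 + beta2 sinusoids) + noise_scale * pink_noise

    With ``jitter`` (the default), every oscillation draws a per-trial
    amplitude factor uniform in [0.8, 1.2] and a phase uniform in [0, 2*pi),
    shared across channels (the oscillation is one source seen by all
    electrodes); the noise is drawn independently per channel.  With
    ``jitter=False`` the amplitude factor is 1 and the phase 0, so a
    noiseless profile yields an exact, reproducible sum of sines.

    Identical arguments (including ``seed``) give byte-identical output.
    """
    if n_trials_per_task < 1:
        raise ValueError("n_trials_per_task must be >= 1")
    if fs <= 2 * BETA_RANGE[1]:
        raise ValueError(f"fs={fs} must exceed twice the top band edge (60 Hz)")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not profiles:
        raise ValueError("at least one profile is required")
    n_channels = len(profiles[0].channel_gains)
    for p in profiles:
        if len(p.channel_gains) != n_channels:
            raise ProfileError(
                f"{p.task_label}: channel_gains length {len(p.channel_gains)} "
                f"differs from {n_channels}"
            )
    if n_channels <= len(DEFAULT_CHANNELS):
        channel_names = DEFAULT_CHANNELS[:n_channels]
    else:
        channel_names = tuple(f"ch{i}" for i in range(n_channels))

    n = round(fs * duration_s)
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    trials: list[TrialRecording] = []
    for profile in profiles:
        for k in range(n_trials_per_task):
            osc = np.zeros(n)
            for amp, freq in (
                (profile.alpha_amp, profile.alpha_freq),
                (profile.beta1_amp, profile.beta1_freq),
                (profile.beta2_amp, profile.beta2_freq),
            ):
                if jitter:
                    factor = rng.uniform(0.8, 1.2)
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                else:
                    factor, phase = 1.0, 0.0
                osc += amp * factor * np.sin(2.0 * np.pi * freq * t + phase)
            samples = np.empty((n_channels, n))
            for c, gain in enumerate(profile.channel_gains):
                noise = (
                    profile.noise_scale * _pink_noise(rng, n, fs)
                    if profile.noise_scale > 0
                    else 0.0
                )
                samples[c] = gain * osc + noise
            trials.append(
                TrialRecording(
                    samples=samples,
                    fs=fs,
                    duration_s=duration_s,
                    task_label=profile.task_label,
                    trial_id=f"{profile.task_label}-{k:04d}",
                    channel_names=channel_names,
                )
            )
    return trials
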