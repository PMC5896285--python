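"""Preprocessing: low-pass filtering and epoch segmentation.

A trial is filtered as a whole (10th-order 50 Hz low-pass Butterworth by
default, applied causally), then the task-preparation prefix is dropped and
the remainder cut into equal parts.  One (channel, part) segment — 4 s of a
single channel under the defaults — is the classification unit downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synth import TASKS, TrialRecording

__all__ = ["Epoch", "lowpass_filter", "segment_trial", "segment_trials"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Epoch:
    """A single-channel segment used as one classification sample."""

    samples: np.ndarray      # 1-D float64
    fs: float
    channel_name: str
    task_label: str
    trial_id: str
    part_index: int          # 1-based

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("epoch samples must be a non-empty 1-D array")
        if self.part_index < 1:
            raise ValueError("part_index is 1-based")
        if self.task_label not in TASKS:
            raise ValueError(f"unknown task label {self.task_label!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size


def butter_lowpass_sos(cutoff: float, fs: float, order: int = 10) -> np.ndarray:
    """Design the digital low-pass Butterworth in second-order sections.

    Bilinear transform with pre-warped cutoff (scipy's default), so the
    magnitude response is exactly -3.01 dB at ``cutoff``.  SOS form keeps the
    10th-order design numerically stable.
    """
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff={cutoff} Hz must lie in (0, Nyquist={fs / 2}) Hz")
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


def lowpass_filter(
    trial: TrialRecording, cutoff: float = 50.0, order: int = 10
) -> TrialRecording:
    """Low-pass filter every channel of a trial (causal forward pass).

    Causal filtering is used rather than zero-phase: it preserves causality of
    the epochs and matches a plain digital-Butterworth reading.  The phase lag
    is irrelevant to the downstream features, which are phase-blind PSDs.  The
    filter state is initialized to the step steady state of each channel's
    first sample, which removes the startup transient (a DC signal passes
    through unchanged) while remaining linear in the input.
    """
    sos = butter_lowpass_sos(cutoff, trial.fs, order)
    zi = signal.sosfilt_zi(sos)  # shape (n_sections, 2), unit step steady state
    x0 = trial.samples[:, :1]    # (n_channels, 1)
    filtered = np.empty_like(trial.samples)
    for c in range(trial.n_channels):
        filtered[c], _ = signal.sosfilt(sos, trial.samples[c], zi=zi * x0[c, 0])
    return TrialRecording(
        samples=filtered,
        fs=trial.fs,
        duration_s=trial.duration_s,
        task_label=trial.task_label,
        trial_id=trial.trial_id,
        channel_names=trial.channel_names,
    )


def segment_trial(
    trial: TrialRecording, prep_duration: float = 2.0, n_parts: int = 2
) -> list[Epoch]:
    """Drop the preparation prefix and cut the remainder into equal epochs.

    Defaults mirror the acquisition protocol: the first 2 s of a 10 s trial
    are task preparation and are excluded; the remaining 8 s are split into
    two 4 s parts, so each trial yields ``n_channels * n_parts`` epochs.
    Concatenating the parts of one channel reproduces the post-preparation
    samples exactly.  A remainder that does not divide evenly is truncated
    from the trial end (with a warning).
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    if trial.duration_s <= prep_duration:
        raise ValueError(
            f"trial {trial.trial_id}: duration {trial.duration_s}s does not exceed "
            f"preparation period {prep_duration}s"
        )
    start = round(trial.fs * prep_duration)
    usable = trial.n_samples - start
    part_len = usable // n_parts
    if part_len < 1:
        raise ValueError(f"trial {trial.trial_id}: too short for {n_parts} parts")
    if usable % n_parts:
        log.warning(
            "trial %s: %d trailing samples truncated (not divisible into %d parts)",
            trial.trial_id, usable % n_parts, n_parts,
        )
    epochs = []
    for c, channel in enumerate(trial.channel_names):
        for p in range(n_parts):
            seg = trial.samples[c, start + p * part_len: start + (p + 1) * part_len]
            epochs.append(
                Epoch(
                    samples=seg.copy(),
                    fs=trial.fs,
                    channel_name=channel,
                    task_label=trial.task_label,
                    trial_id=trial.trial_id,
                    part_index=p + 1,
                )
            )
    return epochs


def segment_trials(
    trials: list[TrialRecording], prep_duration: float = 2.0, n_parts: int = 2
) -> list[Epoch]:
    """Segment a list of trials; epoch order follows trial order."""
    out: list[Epoch] = []
    for trial in trials:
        out.extend(segment_trial(trial, prep_duration, n_parts))
    return out
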