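"""Trial-set fixture I/O: a JSON metadata sidecar plus one wide CSV of samples.

The layout is deliberately diffable and language-neutral: ``<stem>.json``
holds sampling rate, duration, channel names and the per-trial labels;
``<stem>.csv`` holds one row per (trial, channel) with full-precision sample
values.  ``read_fixture(write_fixture(trials))`` is lossless.

An optional EDF/BDF importer (read-only) maps external recordings into
:class:`~bandpeak.synth.TrialRecording`; it needs ``mne``, which is imported
lazily so the rest of the package has no such dependency.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synth import TrialRecording

__all__ = ["write_fixture", "read_fixture", "read_edf", "FixtureError"]


class FixtureError(ValueError):
    """Malformed fixture file (bad header, channel-count mismatch, ...)."""


def _paths(path: str | Path) -> tuple[Path, Path]:
    stem = Path(path)
    if stem.suffix in {".json", ".csv"}:
        stem = stem.with_suffix("")
    return stem.with_suffix(".json"), stem.with_suffix(".csv")


def write_fixture(trials: list[TrialRecording], path: str | Path) -> tuple[Path, Path]:
    """Write a trial set; returns the (json, csv) paths actually written."""
    json_path, csv_path = _paths(path)
    if trials:
        fs = trials[0].fs
        duration_s = trials[0].duration_s
        channel_names = trials[0].channel_names
        for tr in trials:
            if (tr.fs, tr.duration_s, tr.channel_names) != (fs, duration_s, channel_names):
                raise FixtureError(
                    f"trial {tr.trial_id}: heterogeneous fs/duration/channels in one set"
                )
    else:
        fs, duration_s, channel_names = 0.0, 0.0, ()
    meta = {
        "format": "bandpeak-trials-v1",
        "fs": fs,
        "duration_s": duration_s,
        "channel_names": list(channel_names),
        "trials": [{"trial_id": tr.trial_id, "task_label": tr.task_label} for tr in trials],
    }
    json_path.parent.mkdir(parents=True, exist_ok=True)
    json_path.write_text(json.dumps(meta, indent=1))
    with open(csv_path, "w") as fh:
        fh.write("trial_id,channel,samples...\n")
        for tr in trials:
            for name, row in zip(tr.channel_names, tr.samples):
                vals = ",".join(np.format_float_scientific(v, unique=True) for v in row)
                fh.write(f"{tr.trial_id},{name},{vals}\n")
    return json_path, csv_path


def read_fixture(path: str | Path) -> list[TrialRecording]:
    """Read a trial set written by :func:`write_fixture`."""
    json_path, csv_path = _paths(path)
    try:
        meta = json.loads(json_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FixtureError(f"cannot read fixture metadata {json_path}: {exc}") from exc
    if meta.get("format") != "bandpeak-trials-v1":
        raise FixtureError(f"{json_path}: not a bandpeak trial fixture")
    channel_names = tuple(meta["channel_names"])
    rows: dict[str, dict[str, np.ndarray]] = {}
    with open(csv_path) as fh:
        header = fh.readline()
        if not header.startswith("trial_id,channel"):
            raise FixtureError(f"{csv_path}: malformed header {header.strip()!r}")
        for line in fh:
            parts = line.rstrip("\n").split(",")
            if len(parts) < 3:
                raise FixtureError(f"{csv_path}: malformed sample row {parts[:2]}")
            trial_id, channel = parts[0], parts[1]
            rows.setdefault(trial_id, {})[channel] = np.array(parts[2:], dtype=np.float64)
    trials = []
    for entry in meta["trials"]:
        trial_id = entry["trial_id"]
        chans = rows.get(trial_id, {})
        missing = [c for c in channel_names if c not in chans]
        if missing:
            raise FixtureError(
                f"trial {trial_id}: declared {len(channel_names)} channels but "
                f"missing sample rows for {missing}"
            )
        samples = np.vstack([chans[c] for c in channel_names])
        trials.append(
            TrialRecording(
                samples=samples,
                fs=meta["fs"],
                duration_s=meta["duration_s"],
                task_label=entry["task_label"],
                trial_id=trial_id,
                channel_names=channel_names,
            )
        )
    return trials


def read_edf(
    path: str | Path,
    task_label: str,
    trial_duration_s: float = 10.0,
    channels: list[str] | None = None,
) -> list[TrialRecording]:
    """Import an EDF/BDF recording as consecutive fixed-length trials.

    Requires the optional ``mne`` dependency.  The recording is cut into
    consecutive non-overlapping ``trial_duration_s`` windows, all labeled
    ``task_label`` (EDF files carry no task annotation this pipeline knows
    about); a trailing partial window is dropped.
    """
    try:
        import mne  # noqa: PLC0415 - optional dependency
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "EDF/BDF import requires the optional dependency 'mne' "
            "(pip install bandpeak[edf])"
        ) from exc
    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    if channels:
        raw = raw.pick(channels)
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolt-like units
    n_per_trial = round(fs * trial_duration_s)
    n_trials = data.shape[1] // n_per_trial
    names = tuple(raw.ch_names)
    return [
        TrialRecording(
            samples=data[:, k * n_per_trial:(k + 1) * n_per_trial],
            fs=fs,
            duration_s=trial_duration_s,
            task_label=task_label,
            trial_id=f"{path.stem}-{k:04d}",
            channel_names=names,
        )
        for k in range(n_trials)
    ]
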