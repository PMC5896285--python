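"""End-to-end orchestration: generate -> filter -> segment -> PSD -> features
-> classify -> vote, from one declarative config with deterministic seeding.

A single global seed fans out to per-stage child seeds derived from a fixed
hash of the stage name, so stages are statistically independent but the whole
run is reproducible.  The ``paper`` preset bakes in the protocol defaults
(512 Hz, 10 s trials, 2 s preparation, two parts, 400-point hamming Welch
window, 50/50/100 subsampling) on the synthetic generator's default
five-task profiles.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import features as feat
from .classify import EvaluationResult, KernelSpec, ProtocolSpec, evaluate_pairwise
from .io import read_fixture
from .multiclass import MulticlassResult, evaluate_multiclass, task_pairs
from .preprocess import lowpass_filter, segment_trials
from .spectral import WelchParams, welch_psd
from .synth import DEFAULT_CHANNELS, TASKS, TaskSpectralProfile, default_profiles, generate_trials

__all__ = ["PipelineConfig", "stage_seed", "build_feature_table", "run_pairwise",
           "run_multiclass", "features_to_table"]

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str, *extra: int) -> int:
    """Child seed for a named stage, derived by a fixed hash of its name."""
    h = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([int(global_seed), h, *map(int, extra)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run.  Defaults = paper preset."""

    profiles: list[TaskSpectralProfile] | None = None   # None -> default_profiles
    fixture_path: str | None = None                     # read trials instead of generating
    n_trials_per_task: int = 100
    fs: float = 512.0
    duration_s: float = 10.0
    filter_cutoff: float = 50.0
    filter_order: int = 10
    prep_duration: float = 2.0
    n_parts: int = 2
    welch: WelchParams = field(default_factory=WelchParams)
    alpha: feat.Band = feat.ALPHA
    beta: feat.Band = feat.BETA
    extractor_id: str = "bandpeak"
    classifier_ids: tuple[str, ...] = ("lda", "svm_rbf")
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    multiclass_channels: tuple[str, ...] = ("F3", "F4", "C3", "C4")
    seed: int = 0

    def resolve_profiles(self) -> list[TaskSpectralProfile]:
        if self.profiles is not None:
            return self.profiles
        return default_profiles(n_channels=len(self.channels))


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2fs", stage, time.perf_counter() - self.t0)
    return _Timer()


def _load_trials(config: PipelineConfig):
    if config.fixture_path:
        return read_fixture(config.fixture_path)
    return generate_trials(
        config.resolve_profiles(),
        config.n_trials_per_task,
        fs=config.fs,
        duration_s=config.duration_s,
        seed=stage_seed(config.seed, "generate"),
    )


def build_feature_table(config: PipelineConfig) -> pd.DataFrame:
    """Run generate/load -> filter -> segment -> extract, one row per epoch.

    Columns: trial_id, part, channel, task, extractor, then f1..fk.
    """
    if config.extractor_id not in feat.EXTRACTORS:
        raise ValueError(
            f"unknown extractor {config.extractor_id!r}; expected one of "
            f"{sorted(feat.EXTRACTORS)}"
        )
    with _timed("generate"):
        trials = _load_trials(config)
    with _timed("preprocess"):
        trials = [
            lowpass_filter(t, config.filter_cutoff, config.filter_order) for t in trials
        ]
        epochs = segment_trials(trials, config.prep_duration, config.n_parts)
    with _timed("features"):
        rows = []
        for epoch in epochs:
            if config.extractor_id == "minmaxmeanstd":
                fv = feat.extract_minmaxmeanstd(epoch)
            else:
                spectrum = welch_psd(epoch, config.welch)
                if config.extractor_id == "bandpeak":
                    fv = feat.extract_bandpeak_features(spectrum, config.alpha, config.beta)
                else:
                    fv = feat.extract_bandpower(spectrum, config.alpha, config.beta)
            rows.append(
                {
                    "trial_id": fv.trial_id,
                    "part": fv.part_index,
                    "channel": fv.channel_name,
                    "task": fv.task_label,
                    "extractor": fv.extractor_id,
                    **dict(zip(fv.feature_names, fv.values)),
                }
            )
    return pd.DataFrame(rows)


def features_to_table(table: pd.DataFrame) -> dict:
    """Index a feature table as {task: {channel: (n_epochs, dim) array}}.

    Epoch rows are sorted by (trial_id, part) so all channels of one task are
    aligned row-for-row — required by the multiclass evaluation, where one
    epoch draw is shared across channels.
    """
    value_cols = [
        c for c in table.columns
        if c not in ("trial_id", "part", "channel", "task", "extractor")
    ]
    out: dict[str, dict[str, np.ndarray]] = {}
    for (task, channel), group in table.groupby(["task", "channel"], sort=False):
        group = group.sort_values(["trial_id", "part"])
        out.setdefault(task, {})[channel] = group[value_cols].to_numpy(dtype=np.float64)
    return out


def run_pairwise(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Evaluate every task pair x channel x classifier; optionally write CSVs.

    Returns one row per combination with mean/sd accuracy, sensitivity,
    specificity and AUC, plus a ``best`` flag marking the best channel per
    (pair, classifier).
    """
    if table is None:
        table = build_feature_table(config)
    indexed = features_to_table(table)
    tasks = [t for t in TASKS if t in indexed]
    rows = []
    with _timed("classify"):
        for p_idx, (a, b) in enumerate(task_pairs(tuple(tasks))):
            for c_idx, channel in enumerate(config.channels):
                for k_idx, classifier_id in enumerate(config.classifier_ids):
                    protocol = ProtocolSpec(
                        n_train_per_class=config.protocol.n_train_per_class,
                        n_test_draw=config.protocol.n_test_draw,
                        n_repetitions=config.protocol.n_repetitions,
                        rng_seed=stage_seed(config.seed, "classify", p_idx, c_idx, k_idx),
                    )
                    res = evaluate_pairwise(
                        indexed[a][channel], indexed[b][channel],
                        task_pair=(a, b),
                        classifier_id=classifier_id,
                        protocol=protocol,
                        kernel=config.kernel,
                        channel_name=channel,
                    )
                    rows.append(
                        {
                            "task_a": a, "task_b": b, "channel": channel,
                            "classifier": classifier_id,
                            "mean_accuracy": res.mean_accuracy,
                            "sd_accuracy": res.sd_accuracy,
                            "sensitivity": res.sensitivity,
                            "specificity": res.specificity,
                            "auc": res.auc,
                        }
                    )
    df = pd.DataFrame(rows)
    best_idx = df.groupby(["task_a", "task_b", "classifier"])["mean_accuracy"].idxmax()
    df["best"] = False
    df.loc[best_idx, "best"] = True
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "features.csv", index=False)
        df.to_csv(outdir / "pairwise_results.csv", index=False)
        df[df["best"]].to_csv(outdir / "pairwise_best_channels.csv", index=False)
    return df


def run_multiclass(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    table: pd.DataFrame | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """Two-level max-win multiclass evaluation on the configured channels.

    Returns per-task accuracy rows plus one ``overall`` row per classifier.
    """
    if table is None:
        table = build_feature_table(config)
    indexed = features_to_table(table)
    tasks = tuple(t for t in TASKS if t in indexed)
    rows = []
    with _timed("multiclass"):
        for k_idx, classifier_id in enumerate(config.classifier_ids):
            protocol = ProtocolSpec(
                n_train_per_class=config.protocol.n_train_per_class,
                n_test_draw=config.protocol.n_test_draw,
                n_repetitions=config.protocol.n_repetitions,
                rng_seed=stage_seed(config.seed, "multiclass", k_idx),
            )
            res = evaluate_multiclass(
                indexed,
                channels=config.multiclass_channels,
                classifier_id=classifier_id,
                protocol=protocol,
                kernel=config.kernel,
                weighted=weighted,
                tasks=tasks,
            )
            for task in tasks:
                rows.append(
                    {
                        "classifier": classifier_id, "task": task,
                        "accuracy": res.per_task_accuracy[task],
                        "sd": res.per_task_sd[task],
                    }
                )
            rows.append(
                {
                    "classifier": classifier_id, "task": "overall",
                    "accuracy": res.overall_accuracy, "sd": res.overall_sd,
                }
            )
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "multiclass_results.csv", index=False)
    return df
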