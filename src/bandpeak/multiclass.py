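"""Two-level max-win voting for 5-class decisions from pairwise classifiers.

Level 1: within each channel, all C(5,2)=10 pairwise classifiers vote and the
task with the most pairwise wins is that channel's label.  Level 2: channels
vote for their labels, each weighted by its classification accuracy (CA,
estimated from training-phase pairwise performance); the task with the
largest summed weight is the final decision.  An unweighted level-2 mode
(plain plurality) is also provided.  All ties break by the fixed task
enumeration order RS < MA < RH < LH < LA.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .classify import KernelSpec, ProtocolSpec, _fit_predict, standardize
from .synth import TASKS

__all__ = ["VoteError", "maxwin_vote", "channel_vote", "MulticlassResult",
           "evaluate_multiclass", "task_pairs"]


class VoteError(ValueError):
    """A vote table is incomplete or empty."""


def task_pairs(tasks: Sequence[str] = TASKS) -> list[tuple[str, str]]:
    """All unordered task pairs in enumeration order."""
    return list(combinations(tasks, 2))


def _argmax_task(tally: Mapping[str, float], tasks: Sequence[str]) -> str:
    # ties break by enumeration order, which the iteration order guarantees
    best, best_score = None, -np.inf
    for task in tasks:
        score = tally.get(task, 0.0)
        if score > best_score:
            best, best_score = task, score
    return best


def maxwin_vote(
    pairwise_winners: Mapping[tuple[str, str], str],
    tasks: Sequence[str] = TASKS,
) -> str:
    """Max-win vote over one epoch's pairwise contest winners.

    ``pairwise_winners`` maps every unordered task pair to the task that won
    that contest.  Missing pairs are an error; the winner of each pair must
    be one of its two tasks.
    """
    expected = task_pairs(tasks)
    normalized = {tuple(sorted(pair, key=tasks.index)): w
                  for pair, w in pairwise_winners.items()}
    missing = [p for p in expected if p not in normalized]
    if missing:
        raise VoteError(f"missing pairwise winners for pairs: {missing}")
    wins: dict[str, int] = {t: 0 for t in tasks}
    for pair in expected:
        w = normalized[pair]
        if w not in pair:
            raise VoteError(f"winner {w!r} is not a member of pair {pair}")
        wins[w] += 1
    return _argmax_task(wins, tasks)


def channel_vote(
    per_channel_labels: Mapping[str, str],
    channel_weights: Mapping[str, float] | None = None,
    tasks: Sequence[str] = TASKS,
) -> str:
    """CA-weighted vote across channels; ``None`` weights means plurality."""
    if not per_channel_labels:
        raise VoteError("no channels to vote")
    if channel_weights is not None:
        missing = [c for c in per_channel_labels if c not in channel_weights]
        if missing:
            raise VoteError(f"missing weights for channels: {missing}")
    tally: dict[str, float] = {}
    for channel, label in per_channel_labels.items():
        w = 1.0 if channel_weights is None else float(channel_weights[channel])
        tally[label] = tally.get(label, 0.0) + w
    return _argmax_task(tally, tasks)


@dataclass
class MulticlassResult:
    """Per-task and overall accuracy over protocol repetitions (percent)."""

    tasks: tuple[str, ...]
    channels: tuple[str, ...]
    classifier_id: str
    per_task_accuracy: dict        # task -> mean accuracy %
    per_task_sd: dict              # task -> sd over repetitions
    overall_accuracies: np.ndarray  # per-repetition overall accuracy %

    @property
    def overall_accuracy(self) -> float:
        return float(np.mean(self.overall_accuracies))

    @property
    def overall_sd(self) -> float:
        return (float(np.std(self.overall_accuracies, ddof=1))
                if len(self.overall_accuracies) > 1 else 0.0)


def evaluate_multiclass(
    epoch_features: Mapping[str, Mapping[str, np.ndarray]],
    channels: Sequence[str],
    classifier_id: str = "svm_rbf",
    protocol: ProtocolSpec | None = None,
    kernel: KernelSpec | None = None,
    weighted: bool = True,
    tasks: Sequence[str] = TASKS,
) -> MulticlassResult:
    """Full 5-class evaluation by two-level max-win voting.

    ``epoch_features[task][channel]`` is an (n_epochs, dim) array; the rows of
    all channels of one task must be aligned (same epoch order), because one
    epoch draw is shared across channels — an epoch is one time segment seen
    by every electrode.

    Per repetition: draw ``n_train_per_class`` epochs per task (without
    replacement) for training; draw a balanced test set from the remainder
    (``n_test_draw`` split evenly across tasks, so chance level is exactly
    1/n_tasks); train all 10 pairwise classifiers per channel; label each test
    epoch per channel by max-win voting, then across channels by CA-weighted
    voting, where a channel's CA is the mean training-set accuracy of its
    pairwise classifiers.
    """
    protocol = protocol or ProtocolSpec()
    if not channels:
        raise VoteError("no channels to evaluate")
    pairs = task_pairs(tasks)
    n_tr = protocol.n_train_per_class
    per_test_task = max(1, protocol.n_test_draw // len(tasks))

    X = {}
    n_epochs = {}
    for task in tasks:
        for channel in channels:
            try:
                arr = np.asarray(epoch_features[task][channel], dtype=np.float64)
            except KeyError as exc:
                raise ValueError(f"missing features for task {task}, channel {channel}") from exc
            X[task, channel] = arr
            n_epochs.setdefault(task, len(arr))
            if len(arr) != n_epochs[task]:
                raise ValueError(f"task {task}: channels disagree on epoch count")
        if n_epochs[task] < n_tr + per_test_task:
            raise ValueError(
                f"task {task}: needs >= {n_tr + per_test_task} epochs, has {n_epochs[task]}"
            )

    rng = np.random.default_rng(protocol.rng_seed)
    correct = {t: np.zeros(protocol.n_repetitions) for t in tasks}
    overall = np.empty(protocol.n_repetitions)

    for rep in range(protocol.n_repetitions):
        train_idx, test_idx = {}, {}
        for task in tasks:
            perm = rng.permutation(n_epochs[task])
            train_idx[task] = perm[:n_tr]
            test_idx[task] = rng.choice(perm[n_tr:], size=per_test_task, replace=False)

        # per channel: fit the 10 pairwise classifiers, record training CA,
        # and predict the pairwise winner for every test epoch
        channel_ca: dict[str, float] = {}
        # votes[channel][task_of_epoch] -> (n_test, n_pairs) winner labels
        channel_winners: dict[str, dict[str, list[np.ndarray]]] = {}
        for channel in channels:
            test_X = {t: X[t, channel][test_idx[t]] for t in tasks}
            train_accs = []
            winners: dict[str, list[np.ndarray]] = {t: [] for t in tasks}
            for a, b in pairs:
                Xa = X[a, channel][train_idx[a]]
                Xb = X[b, channel][train_idx[b]]
                X_train = np.vstack([Xa, Xb])
                y_train = np.r_[np.ones(len(Xa), dtype=int), np.zeros(len(Xb), dtype=int)]
                stack = np.vstack([test_X[t] for t in tasks])
                X_train_z, X_train_self, stack_z = standardize(X_train, X_train, stack)
                y_pred_tr, _ = _fit_predict(classifier_id, X_train_z, y_train,
                                            X_train_self, kernel)
                train_accs.append(float(np.mean(y_pred_tr == y_train)))
                y_pred, _ = _fit_predict(classifier_id, X_train_z, y_train, stack_z, kernel)
                pred_labels = np.where(y_pred == 1, a, b)
                offset = 0
                for t in tasks:
                    winners[t].append(pred_labels[offset:offset + per_test_task])
                    offset += per_test_task
            channel_ca[channel] = 100.0 * float(np.mean(train_accs))
            channel_winners[channel] = winners

        n_correct_total = 0
        for task in tasks:
            n_correct = 0
            for e in range(per_test_task):
                labels = {}
                for channel in channels:
                    table = {
                        pair: channel_winners[channel][task][j][e]
                        for j, pair in enumerate(pairs)
                    }
                    labels[channel] = maxwin_vote(table, tasks)
                final = channel_vote(labels, channel_ca if weighted else None, tasks)
                n_correct += final == task
            correct[task][rep] = 100.0 * n_correct / per_test_task
            n_correct_total += n_correct
        overall[rep] = 100.0 * n_correct_total / (per_test_task * len(tasks))

    return MulticlassResult(
        tasks=tuple(tasks),
        channels=tuple(channels),
        classifier_id=classifier_id,
        per_task_accuracy={t: float(np.mean(correct[t])) for t in tasks},
        per_task_sd={
            t: (float(np.std(correct[t], ddof=1)) if protocol.n_repetitions > 1 else 0.0)
            for t in tasks
        },
        overall_accuracies=overall,
    )
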