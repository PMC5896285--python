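"""Two-level max-win voting and the 5-class evaluation."""

import numpy as np
import pytest

from bandpeak import (
    ProtocolSpec,
    TASKS,
    VoteError,
    channel_vote,
    evaluate_multiclass,
    maxwin_vote,
    task_pairs,
)
from conftest import maxwin_tally_oracle


def full_table(winner_of):
    """Build a complete 10-pair winner table from a chooser function."""
    return {pair: winner_of(pair) for pair in task_pairs()}


# ------------------------------------------------------------ maxwin_vote


def test_unanimous_winner():
    table = full_table(lambda pair: "RH" if "RH" in pair else pair[0])
    assert maxwin_vote(table) == "RH"


def test_tie_breaks_by_enumeration_order():
    # RS beats MA, RH, LH; LA beats RS, MA... construct RS=3, LA=3
    wins = {
        ("RS", "MA"): "RS", ("RS", "RH"): "RS", ("RS", "LH"): "RS",
        ("RS", "LA"): "LA", ("MA", "LA"): "LA", ("RH", "LA"): "LA",
        ("MA", "RH"): "MA", ("MA", "LH"): "MA", ("RH", "LH"): "RH",
        ("LH", "LA"): "LH",
    }
    tally = {t: sum(1 for w in wins.values() if w == t) for t in TASKS}
    assert tally["RS"] == tally["LA"] == 3
    assert maxwin_vote(wins) == "RS"


def test_missing_pair_is_reported():
    table = full_table(lambda pair: pair[0])
    del table[("MA", "LH")]
    with pytest.raises(VoteError, match="MA"):
        maxwin_vote(table)


def test_winner_must_belong_to_pair():
    table = full_table(lambda pair: pair[0])
    table[("RS", "MA")] = "LA"
    with pytest.raises(VoteError, match="not a member"):
        maxwin_vote(table)


def test_matches_tally_oracle_on_random_tables():
    rng = np.random.default_rng(99)
    pairs = task_pairs()
    for _ in range(1000):
        table = {p: p[rng.integers(0, 2)] for p in pairs}
        assert maxwin_vote(table) == maxwin_tally_oracle(table, TASKS)


def test_permutation_covariance():
    """Relabeling tasks permutes the winner accordingly."""
    rng = np.random.default_rng(17)
    pairs = task_pairs()
    perm = dict(zip(TASKS, ("LA", "RS", "LH", "MA", "RH")))
    for _ in range(200):
        table = {p: p[rng.integers(0, 2)] for p in pairs}
        tally = {t: sum(1 for w in table.values() if w == t) for t in TASKS}
        best = max(tally.values())
        if sum(1 for v in tally.values() if v == best) > 1:
            continue  # tie-break depends on enumeration order, not covariant
        mapped = {
            tuple(perm[t] for t in p): perm[w] for p, w in table.items()
        }
        assert maxwin_vote(mapped) == perm[maxwin_vote(table)]


# ----------------------------------------------------------- channel_vote


def test_channel_unanimity_ignores_weights():
    labels = {c: "MA" for c in ("F3", "F4", "C3", "C4")}
    weights = {"F3": 1.0, "F4": 99.0, "C3": 0.5, "C4": 10.0}
    assert channel_vote(labels, weights) == "MA"


def test_weighted_vote_arithmetic():
    labels = {"F3": "RS", "F4": "RS", "C3": "RH", "C4": "RH"}
    weights = {"F3": 90.0, "F4": 90.0, "C3": 95.0, "C4": 95.0}
    assert channel_vote(labels, weights) == "RH"  # 190 > 180


def test_equal_weight_split_tie_breaks_by_order():
    assert channel_vote({"F3": "MA", "F4": "RS"}, None) == "RS"


def test_unweighted_equals_plurality():
    rng = np.random.default_rng(31)
    channels = [f"c{i}" for i in range(7)]
    for _ in range(200):
        labels = {c: TASKS[rng.integers(0, 5)] for c in channels}
        counts = {t: sum(1 for v in labels.values() if v == t) for t in TASKS}
        best = max(counts.values())
        plurality = next(t for t in TASKS if counts[t] == best)
        assert channel_vote(labels, None) == plurality
        ones = {c: 1.0 for c in channels}
        assert channel_vote(labels, ones) == plurality


def test_empty_channel_set_rejected():
    with pytest.raises(VoteError):
        channel_vote({}, None)
    with pytest.raises(VoteError, match="weights"):
        channel_vote({"F3": "RS"}, {"F4": 1.0})


# ---------------------------------------------------- evaluate_multiclass


def well_separated_features(rng, n=80, dim=3, spread=0.05):
    """Tight per-task clusters at distinct corners, two channels."""
    centers = {t: rng.uniform(1, 10, size=dim) * (i + 1)
               for i, t in enumerate(TASKS)}
    return {
        t: {
            ch: centers[t] + spread * rng.standard_normal((n, dim))
            for ch in ("F3", "F4")
        }
        for t in TASKS
    }


def test_separated_clusters_classified_near_perfectly():
    rng = np.random.default_rng(41)
    feats = well_separated_features(rng)
    protocol = ProtocolSpec(n_train_per_class=30, n_test_draw=25,
                            n_repetitions=5, rng_seed=4)
    res = evaluate_multiclass(feats, ["F3", "F4"], "lda", protocol)
    assert res.overall_accuracy >= 99.0
    # balanced draws: overall equals the mean of per-task accuracies
    assert res.overall_accuracy == pytest.approx(
        np.mean(list(res.per_task_accuracy.values()))
    )


def test_identical_distributions_hit_chance_level():
    rng = np.random.default_rng(43)
    feats = {
        t: {ch: rng.standard_normal((80, 3)) for ch in ("F3", "F4")}
        for t in TASKS
    }
    protocol = ProtocolSpec(n_train_per_class=30, n_test_draw=25,
                            n_repetitions=30, rng_seed=6)
    res = evaluate_multiclass(feats, ["F3", "F4"], "lda", protocol)
    assert 12.0 <= res.overall_accuracy <= 28.0


def test_single_channel_reduces_to_maxwin():
    """With one channel, the channel vote is the identity on its label."""
    rng = np.random.default_rng(47)
    feats = well_separated_features(rng)
    protocol = ProtocolSpec(n_train_per_class=30, n_test_draw=25,
                            n_repetitions=3, rng_seed=8)
    weighted = evaluate_multiclass(feats, ["F3"], "lda", protocol, weighted=True)
    unweighted = evaluate_multiclass(feats, ["F3"], "lda", protocol, weighted=False)
    np.testing.assert_array_equal(weighted.overall_accuracies,
                                  unweighted.overall_accuracies)


def test_multiclass_input_validation():
    rng = np.random.default_rng(51)
    feats = {t: {"F3": rng.standard_normal((20, 3))} for t in TASKS}
    with pytest.raises(ValueError, match="epochs"):
        evaluate_multiclass(feats, ["F3"], "lda", ProtocolSpec())
    with pytest.raises(VoteError):
        evaluate_multiclass(feats, [], "lda", ProtocolSpec())
    with pytest.raises(ValueError, match="missing features"):
        evaluate_multiclass(feats, ["F9"], "lda",
                            ProtocolSpec(n_train_per_class=5, n_test_draw=5,
                                         n_repetitions=1))
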