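"""Pairwise classifiers, the subsampling protocol, and ROC/AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import bandpeak.classify as classify
from bandpeak import (
    KernelSpec,
    ProtocolSpec,
    evaluate_pairwise,
    fit_predict_lda,
    fit_predict_svm,
    roc_auc,
)
from conftest import auc_concordance_oracle, two_class_profiles


def gaussian_clouds(rng, n=60, sep=4.0, dim=3):
    a = rng.standard_normal((n, dim))
    b = rng.standard_normal((n, dim)) + sep
    X = np.vstack([a, b])
    y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
    return X, y


# ----------------------------------------------------------------- LDA


def test_lda_point_masses_pick_nearest_class():
    X = np.array([[0.0, 0, 0]] * 5 + [[1.0, 1, 1]] * 5)
    y = np.array([0] * 5 + [1] * 5)
    labels, scores = fit_predict_lda(X, y, np.array([[0.9, 0.9, 0.9]]))
    assert labels[0] == 1
    assert scores[0] > 0


def test_lda_zero_score_breaks_to_lower_class():
    """A point equidistant from both class means under the pooled metric."""
    rng = np.random.default_rng(0)
    X0 = rng.standard_normal((40, 2)) * 0.1 + [-1, 0]
    X = np.vstack([X0, -X0])  # exact point symmetry: midpoint is the origin
    y = np.r_[np.zeros(40, dtype=int), np.ones(40, dtype=int)]
    labels, scores = fit_predict_lda(X, y, np.array([[0.0, 0.0]]))
    assert scores[0] == 0.0
    assert labels[0] == 0


def test_lda_null_distributions_give_chance_accuracy():
    """Identical class distributions: accuracy ~ 50% over repetitions."""
    rng = np.random.default_rng(3)
    accs = []
    for _ in range(50):
        X = rng.standard_normal((120, 3))
        y = np.r_[np.zeros(60, dtype=int), np.ones(60, dtype=int)]
        labels, _ = fit_predict_lda(X[:100], y[:100], X[100:])
        accs.append(np.mean(labels == y[100:]))
    assert 0.40 < np.mean(accs) < 0.60


def test_lda_agrees_with_reference_implementation():
    """On well-conditioned balanced data the closed-form LDA matches
    scikit-learn's (lsqr solver, no shrinkage) predictions."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(14)
    for _ in range(10):
        X, y = gaussian_clouds(rng, n=50, sep=1.5)
        test = rng.standard_normal((40, 3)) + 0.75
        labels, scores = fit_predict_lda(X, y, test)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        assert np.mean(labels == ref.predict(test)) == 1.0
        # scores agree up to the covariance-denominator scale convention
        ref_scores = ref.decision_function(test)
        assert np.corrcoef(scores, ref_scores)[0, 1] > 0.9999


def test_lda_survives_singular_scatter():
    """Collinear features (singular within-class scatter) must not crash."""
    rng = np.random.default_rng(4)
    base = rng.standard_normal(40)
    X = np.column_stack([base, 2 * base, -base])
    y = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
    X[y == 1] += 1.0
    labels, scores = fit_predict_lda(X, y, X[:5])
    assert np.all(np.isfinite(scores))


# ----------------------------------------------------------------- SVM


def test_svm_separable_classes_are_perfect():
    rng = np.random.default_rng(5)
    X, y = gaussian_clouds(rng, sep=10.0)
    test_X, test_y = gaussian_clouds(rng, n=30, sep=10.0)
    labels, _ = fit_predict_svm(X, y, test_X)
    assert np.mean(labels == test_y) == 1.0


def test_svm_solves_xor_where_lda_cannot():
    rng = np.random.default_rng(6)
    centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float) * 4
    cls = np.array([0, 0, 1, 1])
    idx = rng.integers(0, 4, size=400)
    X = centers[idx] + 0.3 * rng.standard_normal((400, 2))
    y = cls[idx]
    svm_labels, _ = fit_predict_svm(X[:300], y[:300], X[300:])
    lda_labels, _ = fit_predict_lda(X[:300], y[:300], X[300:])
    assert np.mean(svm_labels == y[300:]) > 0.90
    assert 0.3 < np.mean(lda_labels == y[300:]) < 0.7


def test_svm_conflicting_duplicate_is_robust():
    X = np.array([[0.0, 0.0]] * 2 + [[1.0, 1.0]] * 3 + [[0.0, 0.0]])
    y = np.array([0, 0, 1, 1, 1, 1])  # duplicate point with both labels
    labels, scores = fit_predict_svm(X, y, X, kernel=KernelSpec(C=0.1))
    assert np.all(np.isfinite(scores))


def test_kernel_parameter_validation():
    with pytest.raises(ValueError):
        KernelSpec(sigma=0.0)
    with pytest.raises(ValueError):
        KernelSpec(C=-1.0)
    assert KernelSpec(sigma=2.0).resolve_sigma(np.zeros((3, 2))) == 2.0
    # degenerate training set: heuristic falls back to 1.0
    assert KernelSpec().resolve_sigma(np.zeros((3, 2))) == 1.0


# ----------------------------------------------------------------- ROC


def test_roc_perfect_and_worthless():
    perfect = roc_auc(np.array([1.0, 2.0, 8.0, 9.0]), np.array([0, 0, 1, 1]))
    assert perfect.auc == 1.0
    rng = np.random.default_rng(8)
    scores = rng.standard_normal(10000)
    labels = rng.integers(0, 2, size=10000)
    assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.02)


def test_roc_hand_computed_example():
    curve = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
    assert curve.auc == 0.75
    assert curve.fpr[0] == 0.0 and curve.tpr[-1] == 1.0
    assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    st.lists(st.integers(-5, 5), min_size=4, max_size=30),
    st.data(),
)
def test_auc_equals_concordance_probability(score_ints, data):
    """AUC == Mann-Whitney pair-concordance on arbitrary tied instances."""
    scores = np.array(score_ints, dtype=float)
    labels = np.array(
        data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
    )
    if labels.sum() in (0, len(labels)):
        labels[0] = 1 - labels[0]
    got = roc_auc(scores, labels).auc
    assert got == pytest.approx(auc_concordance_oracle(scores, labels))
    # independent library cross-check
    assert got == pytest.approx(roc_auc_score(labels, scores))


# ------------------------------------------------------------- protocol


def synthetic_feature_sets(noise_scale=0.5, seed=21):
    from bandpeak import (extract_bandpeak_features, generate_trials,
                          lowpass_filter, segment_trials, welch_psd)
    trials = generate_trials(two_class_profiles(noise_scale=noise_scale), 100,
                             seed=seed)
    feats = {"RS": [], "MA": []}
    for epoch in segment_trials([lowpass_filter(t) for t in trials]):
        fv = extract_bandpeak_features(welch_psd(epoch))
        feats[epoch.task_label].append(fv.values)
    return np.array(feats["RS"]), np.array(feats["MA"])


def test_protocol_shape_and_reproducibility():
    Xa, Xb = synthetic_feature_sets()
    assert Xa.shape == (200, 3)
    protocol = ProtocolSpec(rng_seed=77)
    r1 = evaluate_pairwise(Xa, Xb, ("RS", "MA"), "lda", protocol)
    r2 = evaluate_pairwise(Xa, Xb, ("RS", "MA"), "lda", protocol)
    assert len(r1.accuracies) == 100
    np.testing.assert_array_equal(r1.accuracies, r2.accuracies)
    # accuracy identity: mean accuracy recomputed from confusion counts
    c = r1.confusion
    total = c["tp"] + c["tn"] + c["fp"] + c["fn"]
    assert total == 100 * 50
    assert r1.mean_accuracy == pytest.approx(100.0 * (c["tp"] + c["tn"]) / total)


def test_protocol_separated_classes_high_accuracy():
    Xa, Xb = synthetic_feature_sets(noise_scale=0.5)
    res = evaluate_pairwise(Xa, Xb, ("RS", "MA"), "svm_rbf", ProtocolSpec(rng_seed=1))
    assert res.mean_accuracy >= 95.0
    assert res.auc > 0.98


def test_protocol_insufficient_epochs_reports_counts():
    X = np.zeros((30, 3))
    with pytest.raises(ValueError, match="51"):
        evaluate_pairwise(X, X, ("RS", "MA"), "lda", ProtocolSpec())


def test_degenerate_constant_classifier_metrics(monkeypatch):
    """Always predicting the positive class on balanced draws: accuracy 50%,
    sensitivity 100%, specificity 0%."""

    def always_positive(classifier_id, X_train, y_train, X_test, kernel):
        return np.ones(len(X_test), dtype=int), np.zeros(len(X_test))

    monkeypatch.setattr(classify, "_fit_predict", always_positive)
    rng = np.random.default_rng(2)
    Xa = rng.standard_normal((200, 3))
    Xb = rng.standard_normal((200, 3))
    res = classify.evaluate_pairwise(Xa, Xb, ("RS", "MA"), "lda",
                                     ProtocolSpec(n_repetitions=50, rng_seed=5))
    assert res.sensitivity == 100.0
    assert res.specificity == 0.0
    assert res.mean_accuracy == pytest.approx(50.0, abs=3.0)


def test_null_calibration_both_classifiers():
    """Label-permuted (identical-distribution) features: 45-55% accuracy."""
    rng = np.random.default_rng(13)
    X = rng.standard_normal((400, 3))
    Xa, Xb = X[:200], X[200:]
    for clf in ("lda", "svm_rbf"):
        res = evaluate_pairwise(Xa, Xb, ("RS", "MA"), clf, ProtocolSpec(rng_seed=3))
        assert 45.0 <= res.mean_accuracy <= 55.0
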