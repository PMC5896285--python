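"""Shared fixtures and independently coded reference oracles.

The oracles here are deliberately written from first principles (explicit
loops, textbook formulas) and never call the implementation paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from bandpeak import PowerSpectrum, TaskSpectralProfile, generate_trials


# ---------------------------------------------------------------- oracles


def welch_psd_oracle(x, fs, nperseg=400, overlap_fraction=0.5):
    """Mean of modified periodograms, coded from the textbook definition.

    Periodic hamming window, per-segment mean removal, one-sided per-Hz
    density scaling with window power normalization, trailing partial
    segments dropped.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    hop = int(nperseg * (1 - overlap_fraction))
    w = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(nperseg) / nperseg)
    u = np.sum(w**2)
    periodograms = []
    start = 0
    while start + nperseg <= n:
        seg = x[start:start + nperseg]
        seg = seg - np.mean(seg)
        X = np.fft.rfft(seg * w)
        p = (np.abs(X) ** 2) / (fs * u)
        p[1:] *= 2.0
        if nperseg % 2 == 0:
            p[-1] /= 2.0
        periodograms.append(p)
        start += hop
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, np.mean(periodograms, axis=0)


def band_peaks_oracle(freqs, psd, lo, hi, closed_hi, k):
    """Exhaustive neighbor-scan peak search over the band slice."""
    in_band = [
        i for i, f in enumerate(freqs)
        if (lo <= f <= hi if closed_hi else lo <= f < hi)
    ]
    f = [freqs[i] for i in in_band]
    v = [psd[i] for i in in_band]
    peaks = [
        i for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] > v[i + 1]
    ]
    peaks.sort(key=lambda i: (-v[i], f[i]))
    chosen = peaks[:k]
    if len(chosen) < k:
        rest = sorted(
            (i for i in range(len(v)) if i not in chosen),
            key=lambda i: (-v[i], f[i]),
        )
        chosen += rest[: k - len(chosen)]
    chosen.sort(key=lambda i: (-v[i], f[i]))
    return [(f[i], v[i]) for i in chosen]


def auc_concordance_oracle(scores, labels):
    """AUC as the fraction of concordant (positive, negative) score pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def maxwin_tally_oracle(pairwise_winners, tasks):
    """Brute-force win tally with enumeration-order tie-break."""
    wins = {t: sum(1 for w in pairwise_winners.values() if w == t) for t in tasks}
    best = max(wins.values())
    for t in tasks:
        if wins[t] == best:
            return t


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_spectrum(rng):
    """A 201-bin spectrum on the default 1.28 Hz grid with random PSD."""
    freqs = np.arange(201) * 1.28
    return PowerSpectrum(freqs=freqs, psd=rng.uniform(0, 10, size=201))


def make_spectrum(peak_list, resolution=1.28, n_bins=201):
    """Build a spectrum with values injected at the bins nearest given freqs."""
    freqs = np.arange(n_bins) * resolution
    psd = np.zeros(n_bins)
    for f, v in peak_list:
        psd[int(round(f / resolution))] = v
    return PowerSpectrum(freqs=freqs, psd=psd)


def two_class_profiles(alpha_a=1.0, alpha_b=3.0, noise_scale=0.5):
    """Two single-channel profiles differing only in alpha amplitude."""
    common = dict(beta1_amp=0.8, beta1_freq=18.0, beta2_amp=0.6, beta2_freq=24.0,
                  noise_scale=noise_scale, channel_gains=(1.0,))
    return [
        TaskSpectralProfile("RS", alpha_a, 10.0, **common),
        TaskSpectralProfile("MA", alpha_b, 10.0, **common),
    ]


@pytest.fixture
def small_trials():
    """Ten 2-channel trials for quick structural tests."""
    profiles = [
        TaskSpectralProfile("RS", 3.0, 10.0, 1.0, 18.0, 0.7, 24.0, 1.0, (1.0, 0.9)),
        TaskSpectralProfile("MA", 1.0, 10.5, 1.1, 19.0, 0.8, 23.0, 1.0, (1.0, 1.1)),
    ]
    return generate_trials(profiles, 5, fs=512.0, duration_s=10.0, seed=11)
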