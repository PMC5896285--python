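"""Feature extraction from epochs and their spectra.

The primary extractor is the band-peak feature set: from one epoch's Welch
PSD it takes

* ``f1`` — the highest local-peak PSD value in the alpha band (8-13 Hz),
* ``f2``, ``f3`` — the two highest local-peak PSD values in the beta band
  (13-30 Hz), in descending order.

PSD values are used on a linear scale (not dB) and the peak *values* are the
features; peak frequencies are kept only as metadata.  Two baseline
extractors are provided for comparison: time-domain (min, max, mean, sample
std) and alpha/beta band power.

Band-edge convention: alpha is half-open [8, 13) and beta closed [13, 30],
so the shared 13 Hz edge belongs to beta only and no bin is double-counted.
A local peak is a bin strictly greater than both of its neighbors within the
band; if a band has fewer interior peaks than requested, the output is padded
with the largest remaining band values (edge bins included) so the feature
vector always has its declared dimension.  Ties break toward the lower
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Epoch
from .spectral import PowerSpectrum

__all__ = [
    "Band",
    "ALPHA",
    "BETA",
    "FeatureVector",
    "find_band_peaks",
    "extract_bandpeak_features",
    "extract_minmaxmeanstd",
    "extract_bandpower",
    "EXTRACTORS",
]


@dataclass(frozen=True)
class Band:
    """A frequency band [lo, hi) — or [lo, hi] when ``closed_hi`` is set."""

    name: str
    lo: float
    hi: float
    closed_hi: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        if self.closed_hi:
            return (freqs >= self.lo) & (freqs <= self.hi)
        return (freqs >= self.lo) & (freqs < self.hi)


ALPHA = Band("alpha", 8.0, 13.0, closed_hi=False)
BETA = Band("beta", 13.0, 30.0, closed_hi=True)


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    feature_names: tuple[str, ...]
    extractor_id: str
    channel_name: str = ""
    task_label: str = ""
    trial_id: str = ""
    part_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.feature_names):
            raise ValueError("values and feature_names must have equal length")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")


def find_band_peaks(
    spectrum: PowerSpectrum, band: Band, k: int
) -> list[tuple[float, float]]:
    """Top-``k`` (frequency, PSD value) local peaks within a band.

    Interior local maxima (strictly greater than both band neighbors) are
    selected first; if fewer than ``k`` exist the selection is padded with
    the largest remaining band bins.  The returned list is sorted by
    descending PSD value with lower-frequency tie-break.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = band.mask(spectrum.freqs)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}] spans only {idx.size} bins at "
            f"resolution {spectrum.resolution:.4g} Hz; need >= 3"
        )
    f = spectrum.freqs[idx]
    v = spectrum.psd[idx]
    interior = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1

    def order(positions: np.ndarray) -> list[int]:
        # descending value, ascending frequency on ties
        return sorted(positions, key=lambda i: (-v[i], f[i]))

    chosen = order(interior)[:k]
    if len(chosen) < k:
        remaining = np.setdiff1d(np.arange(idx.size), chosen)
        chosen += order(remaining)[: k - len(chosen)]
    chosen = sorted(chosen, key=lambda i: (-v[i], f[i]))
    return [(float(f[i]), float(v[i])) for i in chosen]


def extract_bandpeak_features(
    spectrum: PowerSpectrum, alpha: Band = ALPHA, beta: Band = BETA
) -> FeatureVector:
    """The 3-dimensional band-peak feature vector [f1, f2, f3]."""
    (a_peak,) = find_band_peaks(spectrum, alpha, k=1)
    b_peaks = find_band_peaks(spectrum, beta, k=2)
    return FeatureVector(
        values=np.array([a_peak[1], b_peaks[0][1], b_peaks[1][1]]),
        feature_names=("f1", "f2", "f3"),
        extractor_id="bandpeak",
        channel_name=spectrum.channel_name,
        task_label=spectrum.task_label,
        trial_id=spectrum.trial_id,
        part_index=spectrum.part_index,
        metadata={
            "f1_freq": a_peak[0],
            "f2_freq": b_peaks[0][0],
            "f3_freq": b_peaks[1][0],
        },
    )


def extract_minmaxmeanstd(epoch: Epoch) -> FeatureVector:
    """Time-domain baseline: [min, max, mean, sample std] (n-1 denominator)."""
    x = epoch.samples
    if x.size == 0:
        raise ValueError("empty epoch")
    std = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return FeatureVector(
        values=np.array([float(np.min(x)), float(np.max(x)), float(np.mean(x)), std]),
        feature_names=("min", "max", "mean", "std"),
        extractor_id="minmaxmeanstd",
        channel_name=epoch.channel_name,
        task_label=epoch.task_label,
        trial_id=epoch.trial_id,
        part_index=epoch.part_index,
    )


def extract_bandpower(
    spectrum: PowerSpectrum, alpha: Band = ALPHA, beta: Band = BETA
) -> FeatureVector:
    """Band-power baseline: trapezoidal integral of the PSD over each band.

    Integration uses all bins with lo <= f <= hi regardless of the band's
    half-open classification convention (an integration measure has no use
    for edge exclusivity).
    """
    out = []
    for band in (alpha, beta):
        if band.lo < spectrum.freqs[0] or band.hi > spectrum.freqs[-1]:
            raise ValueError(
                f"band {band.name} [{band.lo}, {band.hi}] outside the spectrum "
                f"range [{spectrum.freqs[0]}, {spectrum.freqs[-1]}]"
            )
        sel = (spectrum.freqs >= band.lo) & (spectrum.freqs <= band.hi)
        out.append(float(np.trapezoid(spectrum.psd[sel], spectrum.freqs[sel])))
    return FeatureVector(
        values=np.array(out),
        feature_names=("alpha_power", "beta_power"),
        extractor_id="bandpower",
        channel_name=spectrum.channel_name,
        task_label=spectrum.task_label,
        trial_id=spectrum.trial_id,
        part_index=spectrum.part_index,
    )


#: extractor_id -> (input kind, dimension); used by the pipeline.
EXTRACTORS = {
    "bandpeak": ("spectrum", 3),
    "minmaxmeanstd": ("epoch", 4),
    "bandpower": ("spectrum", 2),
}
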