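"""Windowed IMU signal features for stair-walking classification.

Each 1.5 s window yields a fixed, named feature vector: 23 per-axis
features on each of the three axes of a sensor, plus the 3 pairwise
cross-axis Pearson correlations, i.e. 72 features per sensor.  The
accelerometer additionally contributes the per-axis signal range (x3)
and a step-band wavelet energy of the vertical axis (x1), for 76
accelerometer features and 148 in total when both sensors are present.

The per-axis set (canonical order) is: mean, min, max, median, variance,
std, RMS, skewness, excess kurtosis, amplitude-histogram entropy,
spectral entropy, lag-1 autocorrelation, dominant frequency, FFT energy,
percentiles 5/20/25/75/80/95, IQR, mean absolute deviation, and
mean-crossing count.  Windows are deliberately *not* detrended first:
DC-sensitive features (mean, median, percentiles) retain the gravity /
trunk-orientation component of the vertical and anterior-posterior axes,
which carries most of the ascent-vs-descent contrast.

Degenerate-input conventions (constant window): entropies, variance and
autocorrelation are defined as 0, correlations between constant channels
as 0, dominant frequency as 0 Hz.  All features are finite by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats

from .segmentation import SegmentWindow

__all__ = [
    "FeatureVector",
    "AXIS_FEATURES",
    "feature_names",
    "extract_features",
    "histogram_entropy",
    "spectral_entropy",
    "lag1_autocorrelation",
    "fft_energy",
    "dominant_frequency",
    "stepband_wavelet_energy",
]

AXES = ("x", "y", "z")
AXIS_PAIRS = ("xy", "xz", "yz")

#: Canonical per-axis feature order (23 features per axis, both sensors).
AXIS_FEATURES = (
    "mean",
    "min",
    "max",
    "median",
    "variance",
    "std",
    "rms",
    "skewness",
    "kurtosis",
    "hist_entropy",
    "spectral_entropy",
    "autocorr_lag1",
    "dominant_freq",
    "fft_energy",
    "p5",
    "p20",
    "p25",
    "p75",
    "p80",
    "p95",
    "iqr",
    "mad",
    "zero_crossings",
)

_HIST_BINS = 10
_STEPBAND_PERIOD_S = 0.5  # pseudo-period of the step-band wavelet, seconds
_STEPBAND_WAVELET = "gaus2"


@dataclass(frozen=True)
class FeatureVector:
    """Named feature values for one window."""

    values: dict[str, float]
    sensor_set: str  # {"accel", "gyro", "both"}

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def feature_names(sensor_set: str = "both") -> list[str]:
    """Canonical ordered feature names for a sensor set.

    76 names for ``accel``, 72 for ``gyro``, 148 for ``both``.
    """
    sensors = _sensors_for(sensor_set)
    names: list[str] = []
    for sensor in sensors:
        for axis in AXES:
            names += [f"{sensor}_{axis}_{f}" for f in AXIS_FEATURES]
        names += [f"{sensor}_{pair}_corr" for pair in AXIS_PAIRS]
        if sensor == "accel":
            names += [f"accel_{axis}_range" for axis in AXES]
            names.append("accel_x_stepband_energy")
    return names


def _sensors_for(sensor_set: str) -> tuple[str, ...]:
    if sensor_set == "both":
        return ("accel", "gyro")
    if sensor_set in ("accel", "gyro"):
        return (sensor_set,)
    raise ValueError(f"sensor_set must be accel|gyro|both, got {sensor_set!r}")


# ---------------------------------------------------------------------------
# scalar feature primitives


def histogram_entropy(x: np.ndarray, bins: int = _HIST_BINS) -> float:
    """Shannon entropy (bits) of the equal-width amplitude histogram.

    ``bins`` equal-width bins over [min(x), max(x)], maximum inclusive in
    the last bin; a zero-variance input has entropy 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def spectral_entropy(x: np.ndarray) -> float:
    """Shannon entropy (bits) of the normalized non-DC power spectrum."""
    x = np.asarray(x, dtype=float)
    power = np.abs(np.fft.rfft(x)[1:]) ** 2
    total = power.sum()
    if total <= 0.0:
        return 0.0
    p = power[power > 0] / total
    return float(-(p * np.log2(p)).sum())


def lag1_autocorrelation(x: np.ndarray) -> float:
    """Pearson correlation of the window with itself shifted by one sample.

    Zero-variance windows return 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    return _safe_pearson(x[:-1], x[1:])


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r) if np.isfinite(r) else 0.0


def fft_energy(x: np.ndarray, fs: float) -> float:
    """Sum of squared non-DC FFT magnitudes divided by the window length."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    mags = np.abs(np.fft.rfft(x)[1:])
    return float((mags**2).sum() / x.size)


def dominant_frequency(x: np.ndarray, fs: float) -> float:
    """Frequency (Hz) of the largest non-DC FFT magnitude; 0 if spectrum is empty."""
    x = np.asarray(x, dtype=float)
    mags = np.abs(np.fft.rfft(x)[1:])
    if mags.size == 0 or mags.max() <= 0.0:
        return 0.0
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)[1:]
    return float(freqs[int(np.argmax(mags))])


def stepband_wavelet_energy(
    x_vertical: np.ndarray,
    fs: float,
    *,
    period_s: float = _STEPBAND_PERIOD_S,
) -> float:
    """Energy of the vertical axis in the foot-contact "step band".

    Continuous wavelet response (Gaussian-derivative mother wavelet) at
    the scale whose pseudo-period is ``period_s`` (default 0.5 s, i.e.
    the band of step-to-step transients), summed as squared coefficients
    and normalized by window length.  Quadratically homogeneous in the
    signal amplitude.
    """
    x = np.asarray(x_vertical, dtype=float)
    scale = pywt.central_frequency(_STEPBAND_WAVELET) * fs * period_s
    coef, _ = pywt.cwt(x, [scale], _STEPBAND_WAVELET)
    return float((coef[0] ** 2).sum() / x.size)


def _zero_crossings(x: np.ndarray) -> float:
    """Number of mean-level crossings (sign changes of the centered signal)."""
    xc = x - x.mean()
    nonneg = xc >= 0.0
    return float(np.count_nonzero(nonneg[1:] != nonneg[:-1]))


# ---------------------------------------------------------------------------
# per-window extraction


def _axis_features(x: np.ndarray, fs: float) -> dict[str, float]:
    var = float(np.var(x))
    constant = var == 0.0
    p5, p20, p25, p75, p80, p95 = np.percentile(x, [5, 20, 25, 75, 80, 95])
    out = {
        "mean": float(np.mean(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": float(np.median(x)),
        "variance": var,
        "std": float(np.std(x)),
        "rms": float(np.sqrt(np.mean(x**2))),
        "skewness": 0.0 if constant else float(stats.skew(x)),
        "kurtosis": 0.0 if constant else float(stats.kurtosis(x)),
        "hist_entropy": histogram_entropy(x),
        "spectral_entropy": spectral_entropy(x),
        "autocorr_lag1": lag1_autocorrelation(x),
        "dominant_freq": dominant_frequency(x, fs),
        "fft_energy": fft_energy(x, fs),
        "p5": float(p5),
        "p20": float(p20),
        "p25": float(p25),
        "p75": float(p75),
        "p80": float(p80),
        "p95": float(p95),
        "iqr": float(p75 - p25),
        "mad": float(np.mean(np.abs(x - np.mean(x)))),
        "zero_crossings": _zero_crossings(x),
    }
    return out


def extract_features(win: SegmentWindow, sensor_set: str = "both") -> FeatureVector:
    """Compute the canonical named feature vector for one window.

    Raises a configuration error if the window lacks the channels the
    requested ``sensor_set`` needs (e.g. gyro features from an
    accelerometer-only recording).
    """
    sensors = _sensors_for(sensor_set)
    if "gyro" in sensors and win.gyro is None:
        raise ValueError(
            f"sensor_set={sensor_set!r} requires gyroscope channels, "
            "but the window is accelerometer-only"
        )
    values: dict[str, float] = {}
    for sensor in sensors:
        data = win.accel if sensor == "accel" else win.gyro
        assert data is not None
        for i, axis in enumerate(AXES):
            for name, v in _axis_features(data[:, i], win.fs).items():
                values[f"{sensor}_{axis}_{name}"] = v
        for pair in AXIS_PAIRS:
            i, j = AXES.index(pair[0]), AXES.index(pair[1])
            values[f"{sensor}_{pair}_corr"] = _safe_pearson(data[:, i], data[:, j])
        if sensor == "accel":
            for i, axis in enumerate(AXES):
                col = data[:, i]
                values[f"accel_{axis}_range"] = float(col.max() - col.min())
            values["accel_x_stepband_energy"] = stepband_wavelet_energy(
                data[:, 0], win.fs
            )
    expected = feature_names(sensor_set)
    assert list(values) == expected, "feature ordering drifted from canonical"
    return FeatureVector(values=values, sensor_set=sensor_set)
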