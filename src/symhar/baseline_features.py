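"""Time- and frequency-domain feature extraction for the shallow baselines.

Every feature has one documented standard definition (see the formula ledger
in the package docs); the extracted vector has a fixed name order and defined
defaults for degenerate inputs (constant windows give 0 skewness, kurtosis,
autocorrelation and zero-crossing rate), so no value is ever missing.

Frequency features are derived from the magnitude spectrum of a fast Fourier
transform; a single-level Haar wavelet decomposition can stand in for the FFT
(the same feature list computed from the wavelet coefficient magnitudes).
Cross-axis terms (Pearson correlation, lag-0 normalized cross-correlation,
signal-magnitude area) are computed at the instance level where all three
axes are available.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import stats

from .data_model import ParameterError

__all__ = [
    "time_features",
    "freq_features",
    "instance_features",
    "TIME_FEATURE_NAMES",
    "FREQ_FEATURE_NAMES",
]

TIME_FEATURE_NAMES = (
    "min",
    "max",
    "amplitude",
    "amplitude_peak",
    "sum",
    "abs_sum",
    "euclidean_norm",
    "mean",
    "abs_mean",
    "mean_square",
    "mean_abs_dev",
    "sum_square_error",
    "variance",
    "std",
    "zero_crossing_rate",
    "skewness",
    "kurtosis",
    "autocorr_lag1",
    "area",
    "abs_area",
)

FREQ_FEATURE_NAMES = (
    "energy",
    "energy_normalized",
    "power",
    "centroid",
    "entropy",
    "dc_component",
    "peak",
    "coefficient_sum",
)


def _zero_crossing_rate(values: np.ndarray) -> float:
    signs = np.sign(values)
    signs = signs[signs != 0]
    if len(signs) < 2:
        return 0.0
    return float(np.count_nonzero(np.diff(signs)) / (len(values) - 1))


def time_features(values: np.ndarray) -> dict[str, float]:
    """Statistical descriptors of one window (fixed order, no missing values)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ParameterError("time features need >= 2 samples")
    mean = float(values.mean())
    var = float(values.var())  # population
    sd = float(np.sqrt(var))
    centered = values - mean
    degenerate = sd < 1e-12
    return {
        "min": float(values.min()),
        "max": float(values.max()),
        "amplitude": float(values.max() - values.min()),
        "amplitude_peak": float(np.abs(values).max()),
        "sum": float(values.sum()),
        "abs_sum": float(np.abs(values).sum()),
        "euclidean_norm": float(np.linalg.norm(values)),
        "mean": mean,
        "abs_mean": float(np.abs(values).mean()),
        "mean_square": float(np.mean(values**2)),
        "mean_abs_dev": float(np.abs(centered).mean()),
        "sum_square_error": float(np.sum(centered**2)),
        "variance": var,
        "std": sd,
        "zero_crossing_rate": _zero_crossing_rate(values),
        "skewness": 0.0 if degenerate else float(stats.skew(values)),
        "kurtosis": 0.0 if degenerate else float(stats.kurtosis(values)),
        "autocorr_lag1": 0.0
        if degenerate
        else float(np.dot(centered[:-1], centered[1:]) / np.dot(centered, centered)),
        "area": float(np.trapezoid(values)),
        "abs_area": float(np.trapezoid(np.abs(values))),
    }


def _spectrum_features(mags: np.ndarray, energy: float, n: int, mean: float) -> dict[str, float]:
    half = max(len(mags) - 1, 1)
    total = float(mags.sum())
    nondc = mags[1:]
    out = {
        "energy": energy,
        "energy_normalized": energy / half,
        "power": energy / n,
        "dc_component": mean,
        "coefficient_sum": total,
    }
    if nondc.size == 0 or nondc.sum() <= 0:
        out.update({"centroid": 0.0, "entropy": 0.0, "peak": 0.0})
        return out
    bins = np.arange(1, len(mags))
    out["centroid"] = float(np.dot(bins, nondc) / nondc.sum())
    p = mags**2
    p = p[p > 0] / p[p > 0].sum() if p.sum() > 0 else p
    raw_entropy = float(-(p * np.log(p)).sum()) if p.size else 0.0
    out["entropy"] = raw_entropy / np.log(len(mags)) if len(mags) > 1 else 0.0
    out["peak"] = float(1 + int(np.argmax(nondc)))
    return out


def freq_features(values: np.ndarray, transform: str = "fft") -> dict[str, float]:
    """Spectral descriptors of one window.

    ``energy`` uses the Parseval-consistent scaling ``sum|F|^2 / n`` (equal to
    the time-domain ``sum x^2``); the ``peak`` is the non-DC bin of maximum
    magnitude; ``entropy`` is the normalized Shannon entropy of the magnitude-
    squared distribution (0 log 0 := 0, all-zero windows give 0).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 4:
        raise ParameterError("frequency features need >= 4 samples")
    if transform == "fft":
        spec = np.fft.rfft(values)
        mags = np.abs(spec)
        energy = float(np.sum(np.abs(np.fft.fft(values)) ** 2) / n)
    elif transform == "wavelet":
        approx, detail = pywt.dwt(values, "haar")
        coeffs = np.concatenate([approx, detail])
        mags = np.abs(coeffs)
        energy = float(np.sum(coeffs**2))  # orthonormal Haar preserves energy
    else:
        raise ParameterError(f"unknown transform {transform!r}")
    feats = _spectrum_features(mags, energy, n, float(values.mean()))
    return {k: feats[k] for k in FREQ_FEATURE_NAMES}


def instance_features(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, domain: str = "time"
) -> dict[str, float]:
    """Concatenated per-axis features plus cross-axis terms for one instance."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not len(x) == len(y) == len(z):
        raise ParameterError("axis vectors must have equal length")
    out: dict[str, float] = {}
    for axis, series in (("x", x), ("y", y), ("z", z)):
        if domain == "time":
            feats = time_features(series)
        else:
            feats = freq_features(series, transform="fft" if domain == "fft" else "wavelet")
        out.update({f"{axis}_{k}": v for k, v in feats.items()})
    if domain == "time":
        for (na, a), (nb, b) in (((("x", x)), ("y", y)), (("x", x), ("z", z)), (("y", y), ("z", z))):
            sa, sb = a.std(), b.std()
            corr = 0.0 if sa < 1e-12 or sb < 1e-12 else float(np.corrcoef(a, b)[0, 1])
            out[f"corr_{na}{nb}"] = corr
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            out[f"xcorr_{na}{nb}"] = 0.0 if denom == 0 else float(np.dot(a, b) / denom)
        out["signal_magnitude_area"] = float(
            np.mean(np.abs(x) + np.abs(y) + np.abs(z))
        )
    return out
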