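"""84-dimensional feature vectors from bilateral 3-second windows.

The vector is built from a data-driven registry so alternative feature lists
can be swapped in: 20 temporal statistics per side (computed on the filtered,
median-centered signal), 20 spectral statistics per side (computed on the PSD
restricted to the 0-10 Hz analysis band), and 4 cross-channel features that
couple the two sides.  The cross-channel block is what separates left from
right chewing: the Pearson correlation, the signal magnitude area, the
left/right RMS log-ratio and the lag of the maximum normalized
cross-correlation all respond to side-asymmetric activity.

Feature order is: temporal left, temporal right, spectral left, spectral
right, cross-channel.  Names are stable across the package version.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from hingeforce.behaviors import Behavior
from hingeforce.preprocess import LabeledWindow, SpectrumPair

#: Upper edge (Hz) of the spectral analysis band.
SPECTRAL_BAND_HZ = 10.0
#: Chewing fundamental band (Hz): population 5th-95th percentile.
CHEW_BAND_HZ = (0.94, 2.17)
#: Band-power partition (Hz) of the 0-10 Hz analysis band.
POWER_BANDS_HZ = (
    (0.0, 0.5),
    (0.5, 1.0),
    (1.0, 1.5),
    (1.5, 2.0),
    (2.0, 3.0),
    (3.0, 5.0),
    (5.0, 10.0),
)
#: Peak-detection prominence, as a fraction of the channel standard deviation.
PEAK_PROMINENCE_FRAC = 0.1
#: Cross-correlation lag search half-width (s).
XCORR_MAX_LAG_S = 0.5

TEMPORAL_NAMES = (
    "mean",
    "median",
    "std",
    "variance",
    "rms",
    "mean_abs_dev",
    "iqr",
    "skewness",
    "kurtosis",
    "min",
    "max",
    "peak_to_peak",
    "zero_crossings",
    "peak_count",
    "mean_peak_height",
    "mean_peak_interval",
    "mean_abs_diff1",
    "mean_abs_diff2",
    "waveform_length",
    "energy",
)

SPECTRAL_NAMES = (
    "total_power",
    "peak_freq",
    "peak_power",
    "centroid",
    "spread",
    "spectral_skewness",
    "spectral_kurtosis",
    "spectral_entropy",
    "median_freq",
    "edge_freq_95",
    "band_power_0.0_0.5",
    "band_power_0.5_1.0",
    "band_power_1.0_1.5",
    "band_power_1.5_2.0",
    "band_power_2.0_3.0",
    "band_power_3.0_5.0",
    "band_power_5.0_10.0",
    "chew_band_fraction",
    "peak_to_total_ratio",
    "spectral_peak_count",
)

CROSS_NAMES = (
    "cross_pearson_r",
    "cross_sma",
    "cross_log_rms_ratio",
    "cross_xcorr_lag_s",
)


def feature_names() -> list[str]:
    """The 84 feature names, in extraction order."""
    names = [f"t_{n}_left" for n in TEMPORAL_NAMES]
    names += [f"t_{n}_right" for n in TEMPORAL_NAMES]
    names += [f"s_{n}_left" for n in SPECTRAL_NAMES]
    names += [f"s_{n}_right" for n in SPECTRAL_NAMES]
    names += list(CROSS_NAMES)
    return names


N_FEATURES = 84


@dataclass(frozen=True)
class FeatureVector:
    """84 feature values with their names, behavior label and subject id."""

    values: np.ndarray
    names: tuple[str, ...]
    label: Behavior
    subject_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "names", tuple(self.names))


def _temporal(x: np.ndarray, sample_rate: float) -> list[float]:
    sd = float(np.std(x))
    dx = np.diff(x)
    ddx = np.diff(x, n=2)
    zero_crossings = int(np.count_nonzero(x[:-1] * x[1:] < 0))
    if sd > 0:
        peaks, props = sps.find_peaks(x, prominence=PEAK_PROMINENCE_FRAC * sd)
    else:
        peaks = np.array([], dtype=int)
    peak_count = len(peaks)
    mean_peak_height = float(np.mean(x[peaks])) if peak_count else 0.0
    mean_peak_interval = (
        float(np.mean(np.diff(peaks)) / sample_rate) if peak_count >= 2 else 0.0
    )
    return [
        float(np.mean(x)),
        float(np.median(x)),
        sd,
        float(np.var(x)),
        float(np.sqrt(np.mean(x**2))),
        float(np.mean(np.abs(x - np.mean(x)))),
        float(np.subtract(*np.percentile(x, [75, 25]))),
        float(stats.skew(x)) if sd > 0 else 0.0,
        float(stats.kurtosis(x)) if sd > 0 else 0.0,
        float(np.min(x)),
        float(np.max(x)),
        float(np.ptp(x)),
        float(zero_crossings),
        float(peak_count),
        mean_peak_height,
        mean_peak_interval,
        float(np.mean(np.abs(dx))),
        float(np.mean(np.abs(ddx))),
        float(np.sum(np.abs(dx))),
        float(np.sum(x**2)),
    ]


def _spectral(freqs: np.ndarray, psd: np.ndarray) -> list[float]:
    band = freqs <= SPECTRAL_BAND_HZ
    f = freqs[band]
    p = psd[band]
    df = f[1] - f[0] if len(f) > 1 else 1.0
    total = float(np.sum(p) * df)
    if total <= 0:
        # silent channel: all power-derived statistics collapse to zero
        return [0.0] * len(SPECTRAL_NAMES)
    w = p / p.sum()
    centroid = float(np.sum(w * f))
    spread = float(np.sqrt(np.sum(w * (f - centroid) ** 2)))
    if spread > 0:
        skew = float(np.sum(w * (f - centroid) ** 3) / spread**3)
        kurt = float(np.sum(w * (f - centroid) ** 4) / spread**4)
    else:
        skew = 0.0
        kurt = 0.0
    nz = w[w > 0]
    entropy = float(-np.sum(nz * np.log(nz)) / np.log(len(w))) if len(w) > 1 else 0.0
    cum = np.cumsum(w)
    median_freq = float(f[np.searchsorted(cum, 0.5)])
    edge95 = float(f[np.searchsorted(cum, 0.95)])
    band_powers = [
        float(np.sum(p[(f >= lo) & (f < hi)]) * df) for lo, hi in POWER_BANDS_HZ
    ]
    chew = (f >= CHEW_BAND_HZ[0]) & (f <= CHEW_BAND_HZ[1])
    chew_fraction = float(np.sum(p[chew]) * df / total)
    peak_idx = int(np.argmax(p))
    spectral_peaks, _ = sps.find_peaks(p, height=0.1 * p.max())
    return [
        total,
        float(f[peak_idx]),
        float(p[peak_idx]),
        centroid,
        spread,
        skew,
        kurt,
        entropy,
        median_freq,
        edge95,
        *band_powers,
        chew_fraction,
        float(p[peak_idx] / p.sum()),
        float(len(spectral_peaks)),
    ]


def _cross(left: np.ndarray, right: np.ndarray, sample_rate: float) -> list[float]:
    eps = np.finfo(float).tiny
    sd_l, sd_r = np.std(left), np.std(right)
    if sd_l > 0 and sd_r > 0:
        r = float(np.corrcoef(left, right)[0, 1])
    else:
        r = 0.0
    sma = float(np.mean(np.abs(left) + np.abs(right)))
    rms_l = np.sqrt(np.mean(left**2))
    rms_r = np.sqrt(np.mean(right**2))
    log_ratio = float(np.log((rms_l + eps) / (rms_r + eps)))
    energy = np.sqrt(np.sum(left**2) * np.sum(right**2))
    if energy > 0:
        c = sps.correlate(left, right, mode="full") / energy
        lags = sps.correlation_lags(len(left), len(right), mode="full")
        max_lag = int(round(XCORR_MAX_LAG_S * sample_rate))
        window = np.abs(lags) <= max_lag
        best = np.argmax(c[window])
        lag_s = float(lags[window][best] / sample_rate)
    else:
        lag_s = 0.0
    return [r, sma, log_ratio, lag_s]


def extract(w: LabeledWindow, s: SpectrumPair) -> FeatureVector:
    """Extract the 84 features from a preprocessed window and its spectrum.

    ``w`` should be median-centered and low-pass filtered; ``s`` must be the
    spectrum of the same window.
    """
    if np.any(~np.isfinite(w.left)) or np.any(~np.isfinite(w.right)):
        raise ValueError("window contains non-finite samples")
    if len(s.freqs) != len(w.left) // 2 + 1:
        raise ValueError("spectrum does not match window length")
    values = np.array(
        _temporal(w.left, w.sample_rate)
        + _temporal(w.right, w.sample_rate)
        + _spectral(s.freqs, s.psd_left)
        + _spectral(s.freqs, s.psd_right)
        + _cross(w.left, w.right, w.sample_rate),
        dtype=float,
    )
    return FeatureVector(
        values=values,
        names=tuple(feature_names()),
        label=w.label,
        subject_id=w.subject_id,
    )


@dataclass(frozen=True)
class Scaler:
    """Per-feature z-score standardization parameters."""

    location: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        loc = np.asarray(self.location, dtype=float)
        sc = np.asarray(self.scale, dtype=float)
        if loc.shape != (N_FEATURES,) or sc.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} locations and scales")
        if np.any(sc <= 0):
            raise ValueError("scales must be positive")
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "scale", sc)


def fit_scaler(vectors: list[FeatureVector]) -> Scaler:
    """Fit per-feature mean/std on a training set.

    Zero-variance features fall back to unit scale (with a warning) so the
    transform stays defined.  To avoid leakage, fit only on training folds.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors to fit a scaler")
    X = np.stack([v.values for v in vectors])
    location = X.mean(axis=0)
    scale = X.std(axis=0)
    degenerate = scale == 0
    if degenerate.any():
        names = [vectors[0].names[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance features scaled by 1: {names}", stacklevel=2
        )
        scale = np.where(degenerate, 1.0, scale)
    return Scaler(location=location, scale=scale)


def apply_scaler(scaler: Scaler, vectors: list[FeatureVector]) -> list[FeatureVector]:
    """Standardize feature values; labels and subject ids are untouched."""
    return [
        replace(v, values=(v.values - scaler.location) / scaler.scale)
        for v in vectors
    ]


def to_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Feature table: one row per window, 84 named columns + label + subject_id."""
    names = vectors[0].names if vectors else tuple(feature_names())
    frame = pd.DataFrame([v.values for v in vectors], columns=list(names))
    frame["label"] = [v.label.name for v in vectors]
    frame["subject_id"] = [v.subject_id for v in vectors]
    return frame


def from_table(frame: pd.DataFrame) -> list[FeatureVector]:
    """Inverse of :func:`to_table`."""
    names = tuple(c for c in frame.columns if c not in ("label", "subject_id"))
    return [
        FeatureVector(
            values=row[list(names)].to_numpy(dtype=float),
            names=names,
            label=Behavior.from_code(row["label"]),
            subject_id=str(row["subject_id"]),
        )
        for _, row in frame.iterrows()
    ]
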