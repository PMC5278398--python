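"""Windowing, median centering, low-pass filtering and spectra.

A recording is cut into consecutive non-overlapping 3-second windows (one
behavior label per window; mixed-label windows are discarded so training
labels stay pure).  Each window is centered by subtracting the per-channel
median — the pre-load offset depends on head size and wearing condition and
carries no behavioral information — then low-pass filtered with a zero-phase
5th-order Butterworth at 10 Hz, since chewing never exceeds ~3 Hz and the
band above 10 Hz varies too little across behaviors to help classification.
Spectra are computed per window with a Hann taper against leakage; a 3-s
window gives a 1/3 Hz frequency resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from hingeforce.behaviors import Behavior, SubjectRecording


@dataclass(frozen=True)
class LabeledWindow:
    """One fixed-duration bilateral window carrying a single behavior label."""

    subject_id: str
    label: Behavior
    sample_rate: float
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "left", np.asarray(self.left, dtype=float))
        object.__setattr__(self, "right", np.asarray(self.right, dtype=float))
        if len(self.left) != len(self.right):
            raise ValueError("left and right must have equal length")

    def __len__(self) -> int:
        return len(self.left)


@dataclass(frozen=True)
class SpectrumPair:
    """Single-sided amplitude spectra and PSDs of a window's two channels.

    ``amp_*`` is scaled so a unit-amplitude sinusoid at a bin center reads
    1.0; ``psd_*`` follows the periodogram convention (power per Hz; summing
    over bins times the bin width recovers the mean signal power).
    """

    freqs: np.ndarray
    amp_left: np.ndarray
    amp_right: np.ndarray
    psd_left: np.ndarray
    psd_right: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if np.any(f < 0) or np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be nonnegative and ascending")
        for name in ("amp_left", "amp_right", "psd_left", "psd_right"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != f.shape:
                raise ValueError(f"{name} must match freqs in length")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "freqs", f)


def segment(rec: SubjectRecording, window_s: float = 3.0) -> list[LabeledWindow]:
    """Cut a recording into consecutive non-overlapping single-label windows.

    A window is emitted only if all its samples share one label; windows
    spanning a behavior transition, and any trailing partial window, are
    dropped.
    """
    n = int(round(window_s * rec.sample_rate))
    if len(rec) < n or n < 1:
        raise ValueError("recording shorter than one window")
    windows = []
    for start in range(0, len(rec) - n + 1, n):
        labels = rec.labels[start : start + n]
        if labels.min() != labels.max():
            continue  # mixed-label window: label purity rule
        windows.append(
            LabeledWindow(
                subject_id=rec.subject.subject_id,
                label=Behavior(int(labels[0])),
                sample_rate=rec.sample_rate,
                left=rec.left[start : start + n].copy(),
                right=rec.right[start : start + n].copy(),
            )
        )
    return windows


def median_center(w: LabeledWindow) -> LabeledWindow:
    """Subtract each channel's own median, removing the pre-load offset."""
    return replace(
        w, left=w.left - np.median(w.left), right=w.right - np.median(w.right)
    )


def lowpass(w: LabeledWindow, cutoff: float = 10.0, order: int = 5) -> LabeledWindow:
    """Zero-phase (forward-backward) Butterworth low-pass per channel.

    Forward-backward filtering squares the magnitude response, so the
    effective amplitude gain at frequency f is 1 / (1 + (f/cutoff)^(2*order)).
    """
    if cutoff >= w.sample_rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, cutoff, btype="low", fs=w.sample_rate, output="sos")
    return replace(
        w, left=sps.sosfiltfilt(sos, w.left), right=sps.sosfiltfilt(sos, w.right)
    )


def hann_taper(n: int) -> np.ndarray:
    """Symmetric Hann window w[k] = 0.5 * (1 - cos(2 pi k / (n - 1)))."""
    return np.hanning(n)


def spectrum(w: LabeledWindow, taper: bool = True) -> SpectrumPair:
    """Single-sided amplitude spectrum and periodogram PSD of both channels.

    The channels should already be median-centered.  With ``taper`` (the
    default) a Hann window suppresses spectral leakage; ``taper=False`` gives
    the raw rectangular-window periodogram, whose integral equals the mean
    signal power exactly (Parseval).
    """
    n = len(w)
    if n < 8:
        raise ValueError("window too short for a spectrum (need >= 8 samples)")
    win = hann_taper(n) if taper else np.ones(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / w.sample_rate)

    # doubling applies to all interior bins (not DC, not Nyquist if present)
    one_sided = np.ones(len(freqs))
    one_sided[1:] = 2.0
    if n % 2 == 0:
        one_sided[-1] = 1.0

    def channel(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.fft.rfft(x * win)
        amp = one_sided * np.abs(X) / win.sum()
        psd = one_sided * np.abs(X) ** 2 / (w.sample_rate * np.sum(win**2))
        return amp, psd

    amp_l, psd_l = channel(w.left)
    amp_r, psd_r = channel(w.right)
    return SpectrumPair(
        freqs=freqs, amp_left=amp_l, amp_right=amp_r, psd_left=psd_l, psd_right=psd_r
    )


def preprocess_window(
    w: LabeledWindow, cutoff: float = 10.0, order: int = 5
) -> tuple[LabeledWindow, SpectrumPair]:
    """Standard chain for one window: center, filter, and take the spectrum."""
    filtered = lowpass(median_center(w), cutoff=cutoff, order=order)
    return filtered, spectrum(filtered)
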