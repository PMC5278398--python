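"""Domain types: behavior classes, food textures, subject profiles and recordings.

Six facial/ingestive behaviors are distinguished, with a fixed integer label
used throughout the package (feature tables, classifiers, confusion matrices):

====  =====  =========================
code  label  behavior
====  =====  =========================
NHM   1      natural head movement
LC    2      left chewing
RC    3      right chewing
LW    4      left wink
RW    5      right wink
TK    6      talking
====  =====  =========================
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class Behavior(enum.IntEnum):
    """The six behavior classes, in fixed label order 1-6."""

    NHM = 1
    LC = 2
    RC = 3
    LW = 4
    RW = 5
    TK = 6

    @property
    def label(self) -> int:
        return int(self.value)

    @classmethod
    def from_code(cls, code: "str | int | Behavior") -> "Behavior":
        """Resolve a behavior from its code string ('LC'), label (2) or itself."""
        if isinstance(code, Behavior):
            return code
        if isinstance(code, (int, np.integer)):
            return cls(int(code))
        try:
            return cls[str(code).upper()]
        except KeyError:
            raise ValueError(f"unknown behavior code: {code!r}") from None


#: Class order used for confusion matrices and reports.
CLASS_ORDER: tuple[Behavior, ...] = (
    Behavior.NHM,
    Behavior.LC,
    Behavior.RC,
    Behavior.LW,
    Behavior.RW,
    Behavior.TK,
)


@dataclass(frozen=True)
class TextureClass:
    """A food texture regime for chewing segments.

    ``amplitude_scale`` multiplies the chewing oscillation amplitude (hard and
    crispy textures load the temporalis harder than soft, tacky ones) and
    ``burst_irregularity`` widens the per-cycle amplitude jitter.
    """

    code: str
    amplitude_scale: float
    burst_irregularity: float

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be > 0")
        if self.burst_irregularity < 0:
            raise ValueError("burst_irregularity must be >= 0")


#: Default texture regimes: chip (hard/crispy) > bread (soft) > jelly (tacky)
#: in amplitude.  The mapping is a modeling choice; only the ordering matters
#: to the downstream pipeline.
TEXTURES: dict[str, TextureClass] = {
    "bread": TextureClass("bread", amplitude_scale=1.0, burst_irregularity=0.20),
    "chip": TextureClass("chip", amplitude_scale=1.4, burst_irregularity=0.30),
    "jelly": TextureClass("jelly", amplitude_scale=0.7, burst_irregularity=0.12),
}

#: 5th/95th percentiles of adult chewing frequency (Hz); the 3-s analysis
#: window is sized to hold several cycles at the low end of this range.
CHEW_FREQ_RANGE: tuple[float, float] = (0.94, 2.17)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generative parameters.

    Parameters
    ----------
    preload_left, preload_right : float
        Resting compressive force (N) at each hinge; depends on head size and
        wearing condition, and is removed downstream by per-window median
        subtraction.
    gain : float
        Dimensionless subject-level scaling of all muscle-driven amplitudes.
    noise_sd : float
        Standard deviation (N) of broadband measurement noise.
    chew_freq : float
        Mastication cycle rate (Hz); must lie in ``CHEW_FREQ_RANGE``.
    dominant_side_ratio : float
        Amplitude ratio of the chewing side over the contralateral side
        (> 1); bilateral coupling means the idle side still oscillates.
    """

    subject_id: str
    preload_left: float = 3.0
    preload_right: float = 3.0
    gain: float = 1.0
    noise_sd: float = 0.03
    chew_freq: float = 1.5
    dominant_side_ratio: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = CHEW_FREQ_RANGE
        if not (lo <= self.chew_freq <= hi):
            raise ValueError(
                f"chew_freq must lie in [{lo}, {hi}] Hz, got {self.chew_freq}"
            )
        if self.dominant_side_ratio <= 1:
            raise ValueError("dominant_side_ratio must be > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


@dataclass
class SubjectRecording:
    """A continuous two-channel (left/right hinge) force trace with labels.

    ``labels`` holds the per-sample integer behavior label (1-6).
    """

    subject: SubjectProfile
    sample_rate: float
    left: np.ndarray
    right: np.ndarray
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not (len(self.left) == len(self.right) == len(self.labels)):
            raise ValueError("left, right and labels must have equal length")
        if self.sample_rate <= 20:
            raise ValueError("sample_rate must exceed 20 Hz")

    def __len__(self) -> int:
        return len(self.left)

    @property
    def duration_s(self) -> float:
        return len(self.left) / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: ``time_s, left, right, label`` (code strings)."""
        time_s = np.arange(len(self)) / self.sample_rate
        codes = [Behavior(int(v)).name for v in self.labels]
        return pd.DataFrame(
            {"time_s": time_s, "left": self.left, "right": self.right, "label": codes}
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, subject: SubjectProfile, sample_rate: float
    ) -> "SubjectRecording":
        labels = [Behavior.from_code(c).label for c in frame["label"]]
        return cls(
            subject=subject,
            sample_rate=sample_rate,
            left=frame["left"].to_numpy(),
            right=frame["right"].to_numpy(),
            labels=np.asarray(labels),
        )
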