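"""Synthetic bilateral hinge-force recordings for the six behavior classes.

The generator emulates the morphology of hinge load-cell traces: every class
rides on a subject-specific pre-load offset, chewing is a quasi-periodic
oscillation (fundamental plus second harmonic, per-cycle amplitude jitter)
that is stronger on the chewing side, winks are short unilateral transient
pulses, talking is irregular low-amplitude broadband activity with weak
left/right coupling, and natural head movement is slow drift plus noise.

All randomness flows through one ``numpy`` Generator seeded by the caller, so
identical arguments and seed give bitwise-identical recordings.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from hingeforce.behaviors import (
    CHEW_FREQ_RANGE,
    TEXTURES,
    Behavior,
    SubjectProfile,
    SubjectRecording,
    TextureClass,
)

# Base amplitudes (N, at gain 1 and texture scale 1).  The study's force
# scale is not published numerically, so these are free parameters chosen to
# respect the qualitative ordering visible in bilateral hinge traces:
# wink > chew >> talk > head-movement drift >> noise floor.
CHEW_AMPLITUDE = 1.0
WINK_AMPLITUDE = 1.2
TALK_AMPLITUDE = 0.25
DRIFT_SD = 0.05
HARMONIC_RATIO = 0.35
TALK_COUPLING = 0.3  # weak inter-channel correlation of talking bursts


def _drift(
    n: int, sample_rate: float, rng: np.random.Generator, drift_sd: float
) -> np.ndarray:
    """Slow (<0.5 Hz) random-walk drift rescaled to standard deviation drift_sd."""
    if n == 0 or drift_sd == 0:
        return np.zeros(n)
    walk = np.cumsum(rng.normal(0.0, 1.0, n))
    sos = sps.butter(2, 0.5, btype="low", fs=sample_rate, output="sos")
    slow = sps.sosfiltfilt(sos, walk) if n > 21 else walk
    sd = slow.std()
    if sd > 0:
        slow = slow * (drift_sd / sd)
    return slow


def _chew_channel(
    t: np.ndarray,
    freq: float,
    base_amp: float,
    irregularity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sinusoid-plus-harmonic oscillation with per-cycle amplitude jitter."""
    phase = 2 * np.pi * freq * t
    cycle = np.floor(freq * t).astype(int)
    n_cycles = cycle.max() + 1 if len(cycle) else 1
    jitter = 1.0 + irregularity * rng.uniform(-1.0, 1.0, n_cycles)
    amp = base_amp * jitter[cycle]
    return amp * (np.sin(phase) + HARMONIC_RATIO * np.sin(2 * phase))


#: Wink recurrence span (s): every such span holds 1-3 pulses, so each 3-s
#: analysis window of a wink block contains wink activity.
WINK_SPAN_S = 3.0


def _wink_channel(
    n: int, sample_rate: float, amp: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth (Hann-shaped) 100-300 ms transient pulses, 1-3 per 3-s span."""
    out = np.zeros(n)
    span = int(round(WINK_SPAN_S * sample_rate))
    for start0 in range(0, n, span):
        m = min(span, n - start0)
        n_pulses = int(rng.integers(1, 4))
        for _ in range(n_pulses):
            width = int(round(rng.uniform(0.1, 0.3) * sample_rate))
            width = max(width, 4)
            if width >= m:
                start, width = start0, m
            else:
                start = start0 + int(rng.integers(0, m - width))
            pulse = amp * (1.0 + 0.2 * rng.uniform(-1, 1)) * np.hanning(width)
            out[start : start + width] += pulse
    return out


def _talk_envelope(
    n: int, sample_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """On/off burst envelope with utterance- and pause-like run lengths."""
    env = np.zeros(n)
    i = 0
    on = rng.random() < 0.5
    while i < n:
        dur = int(round(rng.uniform(0.15, 0.6) * sample_rate))
        dur = max(dur, 1)
        if on:
            env[i : i + dur] = 1.0
        on = not on
        i += dur
    # soften edges so bursts are band-limited rather than square
    win = int(round(0.05 * sample_rate))
    if win >= 3:
        kernel = np.hanning(win)
        env = np.convolve(env, kernel / kernel.sum(), mode="same")
    return env


def _talk_channels(
    n: int, sample_rate: float, amp: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Irregular broadband bursts, weakly correlated across channels."""
    sos = sps.butter(4, 8.0, btype="low", fs=sample_rate, output="sos")

    def band_noise() -> np.ndarray:
        x = rng.normal(0.0, 1.0, n)
        x = sps.sosfiltfilt(sos, x) if n > 33 else x
        sd = x.std()
        return x / sd if sd > 0 else x

    common = band_noise()
    rho = TALK_COUPLING
    left = amp * _talk_envelope(n, sample_rate, rng) * (
        rho * common + np.sqrt(1 - rho**2) * band_noise()
    )
    right = amp * _talk_envelope(n, sample_rate, rng) * (
        rho * common + np.sqrt(1 - rho**2) * band_noise()
    )
    return left, right


def _segment(
    behavior: Behavior,
    duration_s: float,
    profile: SubjectProfile,
    sample_rate: float,
    texture: TextureClass,
    confusability: float,
    drift_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Muscle-driven component (no pre-load, no noise) of one labeled block."""
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    gain = profile.gain
    zeros = np.zeros(n)

    if behavior is Behavior.NHM:
        return (
            _drift(n, sample_rate, rng, drift_sd) * gain,
            _drift(n, sample_rate, rng, drift_sd) * gain,
        )

    if behavior in (Behavior.LC, Behavior.RC):
        # confusability -> 1 collapses the left/right asymmetry
        ratio = 1.0 + (profile.dominant_side_ratio - 1.0) * (1.0 - confusability)
        base = CHEW_AMPLITUDE * texture.amplitude_scale * gain
        strong = _chew_channel(
            t, profile.chew_freq, base, texture.burst_irregularity, rng
        )
        weak = _chew_channel(
            t, profile.chew_freq, base / ratio, texture.burst_irregularity, rng
        )
        if behavior is Behavior.LC:
            return strong, weak
        return weak, strong

    if behavior in (Behavior.LW, Behavior.RW):
        pulses = _wink_channel(n, sample_rate, WINK_AMPLITUDE * gain, rng)
        if behavior is Behavior.LW:
            return pulses, zeros
        return zeros, pulses

    if behavior is Behavior.TK:
        # confusability -> 1 shrinks the talking/head-movement amplitude gap
        amp = drift_sd + (TALK_AMPLITUDE - drift_sd) * (1.0 - confusability)
        return _talk_channels(n, sample_rate, amp * gain, rng)

    raise ValueError(f"unknown behavior: {behavior!r}")


def generate_recording(
    profile: SubjectProfile,
    schedule: Sequence[tuple[Behavior | str | int, float]],
    sample_rate: float = 100.0,
    texture: TextureClass | str = "bread",
    seed: int | np.random.SeedSequence = 0,
    confusability: float = 0.0,
    drift_sd: float = DRIFT_SD,
) -> SubjectRecording:
    """Generate one labeled two-channel recording.

    Parameters
    ----------
    profile
        Subject-level generative parameters (pre-loads, gain, chewing rate,
        side dominance, noise level).
    schedule
        Ordered ``(behavior, duration_s)`` blocks; each block carries a single
        label for all its samples.
    sample_rate
        Samples per second per channel; must be at least 50 Hz so the 10 Hz
        analysis band is well inside Nyquist.
    texture
        Food-texture regime applied to chewing blocks (name or instance).
    seed
        Seed (or SeedSequence) for the recording's random stream.
    confusability
        In [0, 1); 0 gives the cleanest class structure, larger values shrink
        the left/right chewing asymmetry and the talking/head-movement
        amplitude gap to make classes harder to separate.
    drift_sd
        Standard deviation (N) of the slow head-movement drift; 0 disables
        drift entirely.
    """
    if sample_rate < 50:
        raise ValueError("sample_rate must be at least 50 Hz")
    if not 0 <= confusability < 1:
        raise ValueError("confusability must lie in [0, 1)")
    if isinstance(texture, str):
        try:
            texture = TEXTURES[texture]
        except KeyError:
            raise ValueError(f"unknown texture: {texture!r}") from None
    rng = np.random.default_rng(seed)

    lefts, rights, labels = [], [], []
    for code, duration_s in schedule:
        behavior = Behavior.from_code(code)
        if duration_s <= 0:
            raise ValueError(f"non-positive duration for {behavior.name}")
        n = int(round(duration_s * sample_rate))
        left, right = _segment(
            behavior, duration_s, profile, sample_rate, texture, confusability,
            drift_sd, rng,
        )
        noise_l = rng.normal(0.0, profile.noise_sd, n) if profile.noise_sd else 0.0
        noise_r = rng.normal(0.0, profile.noise_sd, n) if profile.noise_sd else 0.0
        lefts.append(profile.preload_left + left + noise_l)
        rights.append(profile.preload_right + right + noise_r)
        labels.append(np.full(n, behavior.label, dtype=np.int8))

    return SubjectRecording(
        subject=profile,
        sample_rate=sample_rate,
        left=np.concatenate(lefts),
        right=np.concatenate(rights),
        labels=np.concatenate(labels),
    )


def draw_profile(subject_id: str, rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject from the cohort distributions.

    Pre-loads are uniform on [2, 5] N (head-size dependent), gains uniform on
    [0.8, 1.25], noise on [0.02, 0.05] N, chewing rate uniform inside the
    population 5th-95th percentile band, and chewing-side dominance uniform
    on [2.5, 4].
    """
    lo, hi = CHEW_FREQ_RANGE
    return SubjectProfile(
        subject_id=subject_id,
        preload_left=rng.uniform(2.0, 5.0),
        preload_right=rng.uniform(2.0, 5.0),
        gain=rng.uniform(0.8, 1.25),
        noise_sd=rng.uniform(0.02, 0.05),
        chew_freq=rng.uniform(lo + 0.05, hi - 0.05),
        dominant_side_ratio=rng.uniform(2.5, 4.0),
    )


def generate_cohort(
    n_subjects: int,
    per_class_windows: int,
    sample_rate: float = 100.0,
    seed: int | np.random.SeedSequence = 0,
    window_s: float = 3.0,
    confusability: float = 0.0,
) -> list[SubjectRecording]:
    """Generate a cohort in which every subject performs all six behaviors.

    Each behavior block lasts ``per_class_windows * window_s`` seconds, so
    non-overlapping segmentation yields exactly
    ``n_subjects * 6 * per_class_windows`` single-label windows.  Food texture
    cycles bread/chip/jelly across subjects.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    if per_class_windows < 1:
        raise ValueError("per_class_windows must be at least 1")
    root = np.random.SeedSequence(seed)
    profile_rng = np.random.default_rng(root.spawn(1)[0])
    textures = list(TEXTURES)
    recordings = []
    for i, child in enumerate(root.spawn(n_subjects + 1)[1:]):
        profile = draw_profile(f"S{i + 1:02d}", profile_rng)
        schedule = [(b, per_class_windows * window_s) for b in Behavior]
        recordings.append(
            generate_recording(
                profile,
                schedule,
                sample_rate=sample_rate,
                texture=textures[i % len(textures)],
                seed=child,
                confusability=confusability,
            )
        )
    return recordings


def write_cohort(recordings: Iterable[SubjectRecording], out_dir: str | Path) -> Path:
    """Write one CSV per subject plus a cohort manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject.subject_id}.csv"
        rec.to_frame().to_csv(out_dir / fname, index=False, float_format="%.6g")
        rows.append(
            {
                "subject_id": rec.subject.subject_id,
                "file": fname,
                "sample_rate": rec.sample_rate,
                "preload_left": rec.subject.preload_left,
                "preload_right": rec.subject.preload_right,
                "gain": rec.subject.gain,
                "noise_sd": rec.subject.noise_sd,
                "chew_freq": rec.subject.chew_freq,
                "dominant_side_ratio": rec.subject.dominant_side_ratio,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SubjectRecording]:
    """Read a cohort previously written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    recordings = []
    for row in manifest.itertuples():
        profile = SubjectProfile(
            subject_id=row.subject_id,
            preload_left=row.preload_left,
            preload_right=row.preload_right,
            gain=row.gain,
            noise_sd=row.noise_sd,
            chew_freq=row.chew_freq,
            dominant_side_ratio=row.dominant_side_ratio,
        )
        frame = pd.read_csv(manifest_path.parent / row.file)
        recordings.append(
            SubjectRecording.from_frame(frame, profile, row.sample_rate)
        )
    return recordings
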