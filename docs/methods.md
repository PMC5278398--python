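# Methods

## Lever mechanics

The temple–hinge–headpiece assembly is modeled as a rigid lever about the
hinge joint: `F_hinge = (L_temple / L_hinge) · F_temple`, with the default
geometry `L_temple = 69 mm`, `L_hinge = 9 mm` (factor 7.67). The bench
simulator drives the temple contact as an ideal linear spring
(`F_temple = k · max(0, d − d₀)`, default stiffness `k = 0.44 N/mm`, contact
onset `d₀ = 0`, 0.05 mm steps) and adds independent Gaussian noise to each
measured channel. The model deliberately omits hinge friction, the temple's
own weight, and the sub-0.5 N contactless regime of a physical bench; these
are the reasons a real apparatus reads a slightly smaller factor than the
geometric one, while the simulator recovers it exactly in the noise-free
limit. The amplification estimate is the ordinary least-squares slope of
`F_hinge` on `F_temple`; the p-value is the two-sided t-test of zero slope
(equivalent to the one-predictor regression F-test). A constant response is
reported as slope 0 with R² = 0 rather than an error, and the p-value of an
exact line is clamped to the smallest positive float so it stays in (0, 1].

## Synthetic recordings

The generator emulates bilateral hinge load-cell traces sampled at 100 Hz
(no rate is canonical for this sensor; 100 Hz puts the 10 Hz analysis band
an order of magnitude under Nyquist and is configurable). Channels are
labeled in newtons; since every window is median-centered downstream, units
and offsets are a labeling convention only.

Per subject: pre-loads uniform on [2, 5] N per side (head-size surrogate),
amplitude gain on [0.8, 1.25], broadband noise SD on [0.02, 0.05] N, chewing
frequency uniform inside the population 5th–95th percentile band
[0.94, 2.17] Hz, and chewing-side dominance ratio on [2.5, 4].

Per class (muscle-driven component on top of pre-load and noise):

- **NHM** — slow drift on both channels: a Gaussian random walk low-passed
  below 0.5 Hz and rescaled to 0.05 N SD.
- **LC/RC** — fundamental-plus-second-harmonic oscillation at the subject's
  chewing frequency; the chewing side carries the full amplitude
  (1.0 N × texture scale × gain) and the contralateral side that amplitude
  divided by the dominance ratio; amplitude re-jittered every cycle.
- **LW/RW** — 1–3 Hann-shaped pulses of 100–300 ms per 3-s span, 1.2 N
  scale, on the named side only.
- **TK** — utterance-like on/off bursts (0.15–0.6 s runs) of 8 Hz
  band-limited noise at 0.25 N on both channels, sharing a common component
  with correlation 0.3.

Amplitudes are free parameters (no published amplitude statistics exist for
this device); they were fixed once to the qualitative ordering
wink > chew ≫ talk > head-movement drift ≫ noise floor, with textures
chip (1.4×) > bread (1.0×) > jelly (0.7×). A `confusability` knob in [0, 1)
linearly shrinks the LC/RC asymmetry and the TK/NHM amplitude gap toward
zero to emulate the misclassification structure seen in real data; the
default is 0 (the easy-separation regime).

What the generator does **not** emulate: within-window label transitions,
walking/locomotion artifacts, sensor drift across a session, inter-subject
variation in waveform shape (only rate, amplitude and laterality vary), or
the soft nonlinearities of skin contact. Passing tests therefore show that
the pipeline recovers the structure the generator encodes — laterality,
rhythmicity, burst irregularity — not that real recordings of these
behaviors would classify at the same accuracy; on this synthetic cohort the
classes are nearly perfectly separable, whereas real bilateral recordings
confuse LC with RC and NHM with TK at the ~10% level.

## Preprocessing

Recordings are cut into consecutive, non-overlapping windows of exactly
3 s — long enough for several mastication cycles at 0.94 Hz. Windows whose
samples disagree on the label are dropped (label purity over majority vote:
the emulated protocol records homogeneous behavior blocks, so mixed windows
only arise at block boundaries). Each window is centered by its per-channel
median, then filtered with a 5th-order Butterworth low-pass at 10 Hz applied
forward-backward (zero phase; the effective gain is the squared magnitude,
`1/(1+(f/fc)^{2n})` with bilinear frequency prewarping in the digital
design). Temporal features use this filtered signal directly; spectra
additionally apply a symmetric Hann taper against leakage and are computed
as single-sided amplitude spectra and periodogram PSDs (no Welch averaging —
the 3-s window is the atomic unit of the analysis, so there is nothing to
average within it). A 3-s window at 100 Hz gives a 1/3 Hz bin width; a tone
between bins (e.g. 1.5 Hz) peaks at the nearest bin.

## Features

84 per window = 20 temporal × 2 sides + 20 spectral × 2 sides + 4
cross-channel, built from a data-driven registry so an alternate list can be
swapped in without touching the pipeline. Notable conventions: peak
detection uses a prominence threshold of 0.1 × the channel SD (scale-free,
hence invariant under channel rescaling and side swaps); mean inter-peak
interval is 0 when fewer than two peaks exist; spectral statistics treat the
0–10 Hz PSD as a probability mass (entropy normalized by log of the bin
count); the signal magnitude area is `mean(|left| + |right|)`; the
cross-correlation lag is the argmax of the normalized cross-correlation
within ±0.5 s, positive when the left channel lags the right; the log-RMS
ratio guards zero denominators with the smallest positive float. A silent
channel yields all-zero spectral features rather than NaNs.

Scaling is z-score standardization. Zero-variance features fall back to unit
scale with a warning. The scaler is always fit on training subjects only and
applied to the held-out subject — fitting on the pooled set would leak the
test subject's distribution into training, inflating LOSO scores.

## Classification and model selection

Multiclass one-vs-one SVM with RBF kernel `exp(−γ‖u−v‖²)` (scikit-learn's
SVC is the margin solver; the protocol around it is this package's).
Hyperparameters come from a two-step exponential grid: coarse lattice
C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} × γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}, then a fine lattice
spanning ±2 octaves around the coarse optimum at quarter-octave steps. Every
pair is scored by pooled window-level LOSO accuracy (each fold holds out all
windows of one subject). Ties prefer the smaller C, then the smaller γ — the
flatter model. Note that on z-scored 84-dimensional features the useful γ
region sits around 2⁻⁹…2⁻⁵ (≈ 1/dimension); accuracy saturates in C once
the data are separable.

## Evaluation

Confusion counts are indexed `[predicted, actual]` in class order NHM, LC,
RC, LW, RW, TK. Precision is row-normalized, recall column-normalized, F1
their harmonic mean, the headline score the arithmetic mean of the six F1s,
and accuracy the trace over the total. Classes with an empty row or column
are flagged as undefined (NaN) instead of silently scored 0. Comparisons
against printed report tables round half-up to one decimal in percent. The
packaged reference matrix (10 subjects, 3,450 windows per class, 20,700
total) reproduces its published precision/recall/F1 cells under these
equations, with one known exception: the published RC precision (89.6%) is
arithmetically inconsistent with the published counts, which give
3084/3444 = 89.5%.

## Problem sizes and determinism

The test suite and acceptance script run cohorts of 10 subjects × 60
windows per class (3,600 windows) with a reduced 3 × 3 grid
(C ∈ {2⁰, 2⁴, 2⁸}, γ ∈ {2⁻⁹, 2⁻⁷, 2⁻⁵}) — sizes chosen so a full LOSO grid
search completes in tens of seconds while every class still contributes
hundreds of windows; the analysis scripts use 20 windows per class with the
two-step grid. All randomness flows through `numpy.random.Generator` seeded
from explicit arguments (cohorts spawn per-subject `SeedSequence` children),
so identical arguments and seed give bitwise-identical outputs end to end.

## Known limitations

- The synthetic cohort is much easier than real recordings; end-to-end
  scores near 100% characterize the pipeline's correctness, not expected
  field performance.
- The 84-feature list is a documented reconstruction constrained by the
  stated design (temporal + spectral per side, correlation features,
  total 84); the original device study's verbatim feature list is not
  public.
- The lever model is quasi-static and rigid; compliance of the frame and
  distributed skin contact would lower the effective amplification.
- Non-overlapping windows only; no online/streaming segmentation.
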