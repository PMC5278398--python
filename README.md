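# hingeforce

Classification of ingestive and facial behaviors — chewing, winking, talking,
natural head movement — from the forces measured at the hinges of a pair of
glasses.

## The problem

The temporalis muscle thickens rhythmically during mastication. A pair of
glasses presses on the skin over that muscle through its temples, and the
temple acts as a lever about the hinge joint: a weak force `F_temple` applied
at the epidermis contact point (lever arm `L_temple` from the joint) is
balanced at a hinge-mounted load cell a much shorter arm `L_hinge` away.
Moment equilibrium gives

```
F_hinge = (L_temple / L_hinge) · F_temple
```

so the hinge sees the muscle force amplified by a purely geometric factor
(7.67 for the default 69 mm / 9 mm geometry). With one load cell per side,
the bilateral force traces distinguish six behaviors: natural head movement
(NHM), left/right chewing (LC/RC), left/right wink (LW/RW), and talking (TK).

The package implements the full analysis chain for this sensing principle,
driven by a synthetic signal generator (no human recordings are required):

1. **synthetic** — bilateral recordings with per-subject pre-loads, gains,
   chewing rates (0.94–2.17 Hz), side dominance, and three food-texture
   amplitude regimes;
2. **mechanics** — the lever model, a bench-sweep simulator, and the
   least-squares regressions that estimate the amplification factor;
3. **preprocess** — consecutive 3-s single-label windows, per-window median
   centering (removes the subject-dependent pre-load), zero-phase 5th-order
   Butterworth low-pass at 10 Hz, Hann-tapered spectra (1/3 Hz resolution);
4. **features** — 84 features per window: 20 temporal × 2 sides, 20 spectral
   × 2 sides (PSD restricted to 0–10 Hz), 4 cross-channel (Pearson r, signal
   magnitude area, left/right log-RMS ratio, cross-correlation lag);
5. **classify** — one-vs-one RBF-SVM with a two-step exponential (C, γ) grid
   search scored by leave-one-subject-out (LOSO) cross-validation, scaler
   refit per fold;
6. **evaluate** — 6×6 confusion matrix (predicted in rows) with per-class
   precision, recall, F1, average F1 and accuracy. The published reference
   confusion matrix (20,700 windows) ships with the package.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
their tables under `results/`:

```sh
python analysis/01_bench_mechanics.py
python analysis/02_simulate_cohort.py
python analysis/03_extract_features.py
python analysis/04_grid_search_svm.py
python analysis/05_evaluate.py
```

`01_bench_mechanics.py` simulates the displacement-sweep bench (0.44 N/mm
temple contact stiffness, 2% measurement noise) and prints

```
theoretical amplification factor: 7.67
experimental factor (slope):      7.67 (R^2=0.996, p=1.28e-121)
hinge  slope: 3.37 N/mm
temple slope: 0.44 N/mm
```

— the regression slope of hinge force on temple force recovers the geometric
factor, and the hinge responds to displacement ~7.7× more steeply than the
temple, which is the whole point of the lever.

`03_extract_features.py` shows why the classes separate (class-wise feature
means on a 10-subject cohort):

```
       s_chew_band_fraction_left  cross_log_rms_ratio  cross_sma  t_peak_count_left
LC                         0.822                1.177      0.919              4.895
LW                         0.294                2.880      0.107             11.140
NHM                        0.124               -0.075      0.032             20.590
RC                         0.818               -1.180      0.919              4.970
RW                         0.150               -2.856      0.104             20.935
TK                         0.183                0.012      0.225             16.925
```

Chewing concentrates power in the 0.94–2.17 Hz band on both sides; the
left/right log-RMS ratio signs the chewing/wink side; talking sits between
head movement and chewing in total magnitude.

`04`/`05` then run the LOSO grid search and score the selected model; on the
default easy-separation cohort the out-of-fold metrics are 100% across the
board, and the reference-matrix cross-check prints

```
     precision  recall    f1
NHM       95.7    95.4  95.5
LC        89.3    89.5  89.4
RC        89.5    89.4  89.5
LW        98.6    98.4  98.5
RW        98.1    97.2  97.6
TK        92.7    94.0  93.3
average F1: 94.0%   accuracy: 94.0%
```

matching the published report (the dominant confusions being LC↔RC and
NHM↔TK).

A `hingeforce` console command exposes the same stages
(`simulate | mechanics | featurize | train | evaluate | run`); every
subcommand is a thin wrapper over the library functions.

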