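# Methods

## Problem and signal model

`edapain` estimates self-reported pain intensity from wrist-worn
electrodermal activity (EDA, also called galvanic skin response, GSR).
Skin conductance, measured in microsiemens (µS), is driven by sudomotor
(sweat-gland) activity: sympathetic arousal — including pain — raises both
the slowly varying conductance level and the rate and size of fast
skin-conductance responses (SCRs). The package turns raw 4 Hz wristband
recordings plus sparse numeric-rating-scale (NRS, 0–10) self-reports into
four binary classifiers: baseline (BL) versus each of four merged pain
levels (PL1–PL4).

The signal is modelled additively,

    y(t) = tonic(t) + phasic(t) + e(t),

with `phasic = (driver ⊛ h)`, where the driver is a sparse, non-negative
sudomotor impulse train and `h` is the Bateman kernel
`h(t) = exp(-t/τ0) − exp(-t/τ1)` (unit peak; defaults τ0 = 2 s, τ1 = 0.7 s,
the canonical SCR shape). The tonic level is a clamped cubic B-spline with
knots every 10 s plus an affine drift term.

## Decomposition

Components are recovered from the preprocessed signal by the convex program

    minimize_{q ≥ 0, ℓ, d}  ½‖y − Mq − Bℓ − Cd‖² + α·Σq + ½γ‖ℓ‖²

where `M` is the banded Toeplitz convolution operator of the truncated
Bateman kernel (truncated where the tail falls below 1e-7 of peak), `B` the
spline basis, `C = [1, t]`, `q` the driver, and α = 8e-4, γ = 1e-2 by
default. The α term is an L1 penalty on the (non-negative) driver and
promotes sparsity; γ ridge-penalizes the spline coefficients only, so pure
affine trends are absorbed free of charge and decompose to a near-zero
phasic.

The program is solved with L-BFGS-B over sparse operators with bound
constraints on `q` (the objective is smooth once `q ≥ 0` makes the L1 term
linear). Convergence tolerances derive from `solver_tol` (default 1e-7:
`ftol = solver_tol²`, `gtol = solver_tol/100`). Tests compare the attained
objective against an independent dense FISTA projected-gradient solve; on
≤ 200-sample inputs the relative gap is below 1e-5. The residual is defined
as `y − tonic − phasic`, so reconstruction is exact by construction, and the
driver is non-negative exactly because the bound is enforced by the solver.
Decomposition runs on whole recordings rather than per window — the tonic
spline is poorly conditioned on 5.5 s segments — and windows are sliced
afterwards.

## Preprocessing

Order: down-sample → moving-average smooth → normalize; a zero-phase
low-pass Butterworth filter is applied to the *phasic* component after
decomposition. Down-sampling only engages above the target rate (4 Hz
native data is left untouched) and uses polyphase resampling with
linear-edge padding. Smoothing uses a centred 1 s window with shrinking
edges (no padding values are fabricated). Normalization defaults to
per-recording z-scoring (population SD) so that distance-based classifiers
see scale-free features; min-max and none are available. The Butterworth
default is order 2, cutoff 1 Hz, applied forward-backward (zero phase, DC
gain 1). Constant signals normalize to zeros with a warning rather than an
error.

## Windowing, labels, augmentation

Each NRS self-report labels a 5.5 s window (2.75 s either side of the
timestamp; 22 samples at 4 Hz). Windows that would cross a recording edge
are skipped with a warning. NRS levels are merged 0→BL, 1–3→PL1, 4→PL2,
5–7→PL3, 8–10→PL4; re-binning a label histogram preserves totals exactly.

Baseline windows are scarce in self-report data, so extra NRS-0 events are
planted near reported baselines: candidates on a 1-sample grid strictly
within 10 s of a reported baseline are accepted earliest-first whenever
their 5.5 s window lies inside the recording and overlaps no other event's
window (reported or previously accepted). "Overlap" is evaluated at window
level because the window is the unit feature extraction consumes, and the
10 s bound is event-to-event. Placement is deterministic; an optional
per-event cap tunes class balance.

## Features

Eleven statistics per window: peak count and maximum peak amplitude from
the filtered phasic series (a peak is a strict local maximum above a
configurable amplitude threshold, default 0.01 normalized units; plateaus
take their first index); mean, range, population SD, interquartile range
(linear-interpolation quartiles), RMS, mean of strict local minima/maxima
(falling back to the global extremum on monotone or constant windows), and
the mean absolute lag-1 (`mavfd`) and lag-2 (`mavsd`) differences, all on
the preprocessed window. The nine-feature "fixed" subset used for
reference-comparison runs excludes the peak count and the mean.

## Models and evaluation

Binary tasks BL vs PL1..PL4 are evaluated by leave-one-subject-out (LOSO)
cross-validation: one fold per subject, the model rebuilt from scratch on
the remaining subjects, fold accuracy the fraction of the held-out
subject's windows classified correctly, and the reported accuracy the
unweighted mean over folds. Classifiers are k-nearest-neighbour (k 1–20)
and random forest (depth 1–10, 100 trees by default).

All data-dependent choices are made inside the training fold by an inner
LOSO loop over the training subjects: feature subsets (features ranked by
random-forest mean-decrease-impurity/Gini importance on the training fold,
top-k prefixes for k = 2..11 scored by inner accuracy, ties to smaller k)
and the classifier hyperparameter (same criterion). Per-fold subsets are
consolidated to the modal subset, ties broken by higher mean inner
accuracy, then smaller cardinality, then lexicographically. This inner-loop
rule is the package's design choice for making the search leak-free; tests
assert that perturbing a held-out subject's features cannot change the
model that scores that subject, and that equal seeds give byte-identical
reports.

## Synthetic cohort

Real postoperative recordings are emulated per subject as 30 min of 4 Hz
conductance: tonic level 2 µS plus a bounded random walk (SD 0.15 µS);
SCRs as Bateman pulses from a Poisson process whose rate (2→24 per min)
and lognormal mean amplitude (0.05→0.8 µS, shape 0.4) increase strictly
with the planted merged pain class within ±2.75 s of each label event;
a 1-per-min background SCR rate; Gaussian sensor noise (SD 0.02 µS); and
brief biphasic motion-artifact spikes (0.3 per min, 0.5–2 µS) that exercise
the smoothing stage. The cohort-wide event histogram defaults to the
imbalanced distribution typical of sparse self-reports (counts 37, 52, 37,
61, 83, 44, 32, 16, 46, 26, 4 for NRS 0–10), split round-robin across
subjects; event times are uniform with a 12 s minimum separation away from
recording edges. Everything is reproducible per (seed, subject index).

What the simulator does *not* model: non-stationary artifact bursts
correlated with pain (reported in real patients), inter-subject baseline
physiology differences beyond the random walk, TENS stimulation phases,
sensor detachment, and temperature effects. Passing the end-to-end tests
therefore shows the pipeline recovers a planted monotone effect and is
calibrated under the null — not that real-patient accuracies are
reproduced; the real dataset is unreleased.

## Problem sizes and evaluation scale

The end-to-end checks use a 10-subject cohort at the default 30 min / 4 Hz
geometry (~50 labeled windows per subject after augmentation). Evaluation
inside the acceptance script and the heavier tests uses 50-tree forests —
half the package default — which the selection and tuning loops repeat
hundreds of times per fold; the Gini ranking is insensitive to the forest
size at these data sizes. The permutation-null check shuffles labels within
subjects (100 replicates) and compares the mean LOSO accuracy to the 95%
binomial band around the majority-class rate with n equal to the task's
window count, the sampling unit of a single replicate's accuracy.

## Known limitations

* The α, γ defaults are tuned for z-scored input; decomposing raw
  microsiemens signals of very different dynamic range may need rescaling.
* L-BFGS-B drives most driver samples to exactly zero but, unlike an
  interior-point solve with explicit complementarity, can leave tiny
  positive values near active constraints; sparsity counts use a relative
  threshold.
* The within-training-fold selection rule (inner LOSO) is one defensible
  choice among several; selected subsets — though not the leak-freedom —
  depend on it.
* KNN folds with fewer training rows than k are skipped in inner loops;
  this only matters for extremely small cohorts.
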