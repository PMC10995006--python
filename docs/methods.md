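# Methods

This note documents the models, numerical conventions and design choices
behind `n2oeeg`, in the order the pipeline runs them.

## Synthetic cohort generator

**What it emulates.** A 12-participant crossover design: one recording per
participant per end-tidal N₂O condition (0/20/30/40%), 32 BioSemi 10-10
scalp channels at 256 Hz, 30 clean 2-s epochs per recording (roughly the
one-minute eyes-open segment such studies analyse).

**Signal model.** Each epoch is a sum over the four canonical bands of
independent band-limited Gaussian noise per channel, synthesised in the
rfft domain: complex-Gaussian coefficients on the native 0.5 Hz grid inside
each band, scaled so that E|X_k|² = S·fs·n/2, which makes the one-sided
Hann-periodogram density equal the planted level S (µV²/Hz). Band powers in
this package are *per-frequency means*, so the planted S for a band IS the
band power the spectra stage should recover. This is deliberately the
simplest model whose band powers are exactly controllable — the analysis
consumes nothing but band powers, so AR or 1/f structure would add realism
the pipeline never sees.

Two refinements matter numerically:

* **Outer-edge padding.** The lowest band is extended one native bin below
  1 Hz and the top band one bin above 30 Hz. The Hann taper's mainlobe
  spans ±1 native bin; without padding the periodogram at the outermost
  analysis frequencies (1 and 30 Hz) misses the neighbour-bin contribution
  and under-reads by ~17% at those points (~6% on the delta mean). With
  padding, recovery is within ~4% for all bands; real EEG likewise has
  energy just outside the analysis range. Interior band edges keep a small
  (≤4%) cross-talk between adjacent bands — an honest property of
  Hann-tapered estimation at shared edges.
* **Variance hierarchy.** The planted target for channel c, band b, dose d,
  epoch e factorises as
  `baseline(b) · participant(b) · channel(b,c) · dose_mult(b, region(c), d) · jitter(e,b)`
  with log-normal multipliers: per (participant, band) with σ_log = 0.6,
  per (participant, band, channel) with σ_log = 0.2, per (epoch, band) with
  σ_log = 0.1. The channel-level term gives each participant an
  idiosyncratic scalp topography. It is essential: if participant and epoch
  multipliers are shared across channels, cross-channel contrasts are
  noise-free and a linear classifier can exploit the few-percent band-edge
  cross-talk, making even information-free lesioned sets separable. With
  it, lesioned sets that carry no planted effect score at chance.

**Planted effect.** At 40% N₂O: delta ×0.6 and beta ×1.5 on frontal and
central channels, ×1 elsewhere; doses 20/30 interpolate log-linearly, so
dose 0 maps to multiplier 1 identically. Direction (delta down, beta up,
frontal/central) mirrors the reported pharmacology of low-dose N₂O; the
magnitudes are *calibration placeholders*, not physiological estimates.

**Calibration.** The free noise scales were set once so that the default
binary task lands in a realistic 80–95% accuracy band rather than
saturating: with (participant 0.6, channel 0.2) the mean LOPO accuracy over
8 generator seeds is 0.90, only-theta/only-alpha lesions sit at chance
(0.51/0.53), and null cohorts fall inside the shuffle band on 10/10 seeds.

**Randomness.** A single cohort seed derives named substreams
(`participant/P07`, `recording/P07/40`, `epoch/e`, `shuffle/it/fold`) via
`numpy.random.SeedSequence` spawn keys, so any participant, recording or
shuffle iteration can be regenerated in isolation, bit-identically.

**EDF export.** One file per recording, one 2-s data record per epoch,
16-bit samples over a fixed ±500 µV physical range (quantization step
1000/65535 ≈ 0.0153 µV, the bound asserted by the round-trip tests).
Channel labels longer than the 16-byte header field are truncated and
logged. Reading goes through MNE's EDF reader, which doubles as an
independent check on the writer. Artifact screening on import is a simple
amplitude gate (drop any epoch whose |sample| exceeds a threshold) standing
in for the manual/ICA cleaning a real recording would need — the generator
emits clean epochs, so it defaults to off.

## Spectra and features

Spectral estimation is a single-taper Hann periodogram per 2-s epoch
(scipy, one-sided density scaling), averaged across epochs in the power
domain, subset at the integer frequencies 1..30 Hz (the native 0.5 Hz grid
is subset, not zero-padded). Per-epoch averaging commutes with band
averaging by linearity (tested exactly). Band edges are half-open [lo, hi)
with beta closing at 30 Hz inclusive, so the four bands partition the grid:
delta {1,2,3}, theta {4..7}, alpha {8..13}, beta {14..30}. Features are
absolute power by default; `relative=` (per-channel share across bands) and
`log10=` switches exist because the literature is split on the transform.

The channel→region map (frontal 7, lateral 8, central 7, occipital 10
channels) is a documented, overridable default — published descriptions of
this grouping rarely list the exact assignment.

## Classifiers

* **Linear SVM**: soft-margin hinge loss with L2 penalty, C = 1, no feature
  standardization, no kernel — everything "left at default". The QP is
  solved by libsvm (scikit-learn) at tolerance 1e-6; weights, bias and
  class order are extracted into a plain serialisable model. On tiny
  separable sets the solution matches a brute-force maximum-margin search
  to 1e-3.
* **One-versus-one**: one pairwise SVM per unordered class pair (6 for four
  classes), each trained only on its pair's rows. Prediction is by vote
  count; ties break first by the larger summed |decision value| among the
  tied classes' winning votes, then by the smallest class label —
  deterministic and documented, since vote-decoding conventions vary.
* **PCA + Fisher LDA**: components from training-fold-centred features only
  (test rows are projected with training means — no leakage); the Fisher
  discriminant on retained scores uses pooled within-class scatter with a
  1e-8·trace ridge for singular cases; the threshold is the midpoint of the
  projected class means under that metric.

## Evaluation

LOPO folds are ordered by sorted participant id; every participant is the
test participant exactly once. Accuracy is reported as the mean over folds,
which equals the pooled proportion on the balanced design (asserted), with
an exact Clopper–Pearson 95% CI on the pooled correct/total counts — the
exact-interval convention reproduces the printed intervals of the
motivating analysis (22/24 → [73%, 99%]; 25/48 → [37%, 67%]).

The shuffle baseline permutes each fold's *training* labels independently
per iteration and per fold (a dedicated substream each); test labels are
never permuted. 100 iterations by default; the grand mean estimates chance
(~50% binary, ~25% four-class on balanced designs), and the per-fold
iteration means give the baseline "model" one paired value per fold so it
can enter rank comparisons alongside the real models.

## Lesioning and model comparison

Band lesioning yields 8 tables (only-/without- × 4 bands; 32 and 96
columns); region lesioning removes all four bands of a region's channels.
All 10 models (complete, shuffle, 8 lesions) are evaluated on identical
folds with the same seed discipline, so within-fold comparisons are paired.

The Friedman statistic is computed from within-fold ranks with the standard
tie correction (equal to the classic formula when no ties; cross-checked
against scipy and a brute-force oracle); a fully tied matrix returns
statistic 0, p = 1 by convention rather than NaN. Ranks are oriented so
higher accuracy → higher rank (k = best). The Nemenyi critical difference
uses the published two-tailed q table (k = 2..10, α ∈ {0.05, 0.10});
CD(k=10, N=12, α=0.05) = 3.164·√(110/72) ≈ 3.91. Grouping emits the maximal
sets of rank-consecutive models whose mean-rank span is below CD — the
horizontal bars of a critical-difference diagram. The Shapiro–Wilk check on
the paired differences is computed and logged but never switches the test:
the model-vs-baseline contrast is always the two-tailed paired Wilcoxon
signed-rank (zero differences dropped; exact null when scipy can).

## Problem sizes

Defaults throughout are the full study geometry: 12 participants, 30
epochs × 2 s × 32 channels per recording, 100 shuffle iterations. The test
suite uses reduced cohorts (fewer participants/epochs) for shape and
contract checks and full-geometry cohorts across ≥10 seeds for the
simulation-based properties; the sizes are stated in each test.

## Limitations

* The generator plants stationary Gaussian band power only — no 1/f slope,
  no blinks/muscle artifacts, no eyes-open/closed distinction, no
  pharmacokinetic wash-in. Passing tests demonstrate that the *pipeline*
  recovers known spectral structure across participant variability; they
  say nothing about real N₂O EEG effect sizes.
* Effect magnitudes (×0.6, ×1.5) are calibration placeholders chosen to
  produce realistic accuracy, not physiological estimates.
* The multi-class decoder assumes vote counting; loss-weighted decoding is
  a plausible alternative convention.
* Nemenyi constants are tabulated for k ≤ 10 models only.
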