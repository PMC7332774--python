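# Methods

`neostress` quantifies how bradycardic events in preterm-infant monitoring
relate to a stress burden (any non-zero pain score the day before the
recording). The pipeline runs in four stages: event detection, univariate
feature extraction, network-physiology feature extraction, and
leave-one-patient-out classification. A synthetic cohort generator with
controllable effect sizes provides test beds at every stage.

## Signals and conventions

A record couples 8 monopolar EEG channels (Fp1, Fp2, C3, C4, T3, T4, O1,
O2 referenced to Cz; default 256 Hz, microvolts), the RR tachogram
(`rr[i]` is the interval in seconds ending at `beat_times[i]`), and SpO2
(%, 1 Hz). Time is seconds from record start; all epoch intervals are
half-open `[start, end)`. Beats with RR outside [0.2, 2.0] s are treated
as artifacts and dropped at ingest; no other RR cleaning is applied.
Before feature extraction the EEG is band-passed 1–20 Hz with a zero-phase
4th-order Butterworth filter.

## Event detection

* **Bradycardia** — a maximal run of beats with RR above 1.5x the mean RR
  of the entire tachogram (event beats included), whose supra-threshold RR
  durations sum to at least 4 s. Runs separated by fewer than 5
  sub-threshold beats are merged. The peak is the earliest maximal RR.
  "Return to stationarity" is operationalized as the first beat after the
  peak where RR stays at or below 1.1x the mean RR for 5 consecutive
  beats (capped at the next event's onset); a bare threshold re-cross
  would leave slow recovery tails inside the "post" epoch.
* **Desaturation** — SpO2 below a causal 60-s running-median baseline by
  the working threshold (3, 5 or 10 percentage points), extended outward
  to the re-crossing of baseline minus half the threshold; depth =
  baseline-at-onset minus nadir.
* **Hypoxic event** — a bradycardia paired with a desaturation whose
  interval intersects [onset − 30 s, offset + 60 s]; assignment is greedy
  by nadir-to-peak distance and each desaturation is used at most once.
  The pairing tolerance is a free parameter chosen so co-timed raised-
  cosine injections always pair.
* **Epochs** — the analysis window is 3 min on each side of the
  bradycardia peak (truncated and flagged at record edges): pre =
  [window start, onset), during = [onset, offset), post = [offset, window
  end). SpO2 temporal statistics use analogous pre/post epochs keyed on
  the desaturation's own onset/offset.

## Univariate features

All time–frequency quantities use the analytic Morlet wavelet
(omega0 = 6) on a geometric scale grid of 12 voices per octave, with
samples inside the cone of influence (e-folding time sqrt(2)·scale)
excluded from epoch statistics. The tachogram and SpO2 are linearly
interpolated onto a uniform 8 Hz grid for spectral, PRSA and coupling
analysis; the high-frequency band (0.2–4] Hz then sits below Nyquist.

* **Temporal**: mean and sample SD of RR per epoch; of SpO2 on the
  desaturation-keyed pre/post epochs.
* **Spectral (HRV)**: per-sample |CWT|^2 summed over HF = (0.2–4] Hz and
  LF = (0.08–0.2] Hz; mean and SD per epoch of HF, LF, HF/(LF+HF) and
  LF/HF. Power-like features are natural-log transformed at assembly
  (ln(x + tiny)); the bounded fraction HF/(LF+HF) stays linear.
* **Poincare** (whole window, once per event): lag tau = first
  non-positive lag of the unbiased sample ACF (integer lag, capped and
  flagged at n/2); SD1/SD2 are the singular values of the column-centred
  [x(t), x(t+tau)] matrix scaled by 1/sqrt(n−1); centroids are the
  uncentred column means.
* **PRSA** (whole window): anchors where the T-second mean after a sample
  drops below (direction "down") or rises above ("up") the T-second mean
  before it; 120-s fragments centred on anchors are averaged
  (edge-crossing fragments dropped). Features are the OLS slope of the
  whole averaged curve and the slope over [anchor, anchor + T], for
  T in {1, 5, 10, 20, 50, 100} s. RR uses "up" anchors (bradycardia = RR
  lengthening), SpO2 "down" (desaturation). Note the anchor selection
  itself biases the overall slope slightly away from zero even for white
  noise (a piecewise-step conditional-mean effect of order 1e-5 at
  T = 10 s, 8 Hz); the calibration tests therefore use the exact down/up
  symmetry null rather than a naive zero expectation.

## EEG features

* **Delta power**: |CWT|^2 summed over (0.5–4] Hz per sample; mean/SD per
  epoch, plus raw-amplitude mean/SD per epoch, per channel.
* **Multifractality**: wavelet-leader log-cumulants c1 (dominant Hurst
  exponent) and c2 (singularity-spectrum width). The signal is demeaned
  and integrated (cumulative sum) first, so increment-like signals
  (fractional Gaussian noise, band-passed EEG) acquire positive Holder
  regularity — the standard fractional-integration device; c2 is
  unaffected. The transform is a Daubechies-3 DWT (periodized, signal
  truncated to a power of two); leaders are suprema of L1-normalized
  coefficient magnitudes over the 3-neighbourhood at all finer scales;
  the per-scale mean and variance of log-leaders are regressed on scale
  (weights = leaders per scale) over octaves j1..j2, default j1 = 3,
  j2 = floor(log2 n) − 3. On generated fractional noise the estimator
  recovers H within ±0.1 (median over 20 realizations) and |c2| < 0.05;
  on multifractal-random-walk increments with intermittency 0.05 it
  returns c2 near −0.05.
* Inside the pipeline, c1/c2 of the raw channel use a band-aware octave
  range (scales whose Daubechies-3 centre frequency falls inside the
  1–20 Hz pass-band, about j = 2..5 at 64 Hz), because the band-pass
  removes the coarse-scale energy the default range would regress on.
  Fractality is computed on the pre and post epochs only (the "during"
  epoch is too short), both for the raw channel and for its 8 Hz
  delta-power envelope. The mixture of fractional background and smooth
  delta oscillation attenuates an injected background-Hurst shift by
  roughly half; the effect-recovery tests assert a clearly positive,
  monotone response rather than exact recovery.

## Coupling graph and topology

Ten node series on the common 8 Hz grid over the event window: the delta-
power envelope of each EEG channel (block-averaged from the EEG rate), the
RR series and SpO2. Couplings are evaluated in the very-low-frequency band
(0.033–0.08] Hz for the 5-days group and the low-frequency band
(0.08–0.2] Hz for the 34-weeks and PSG groups, reflecting autonomic
maturation.

* **Coherence**: C = S(Wx Wy*) / sqrt(S|Wx|^2 S|Wy|^2) with smoothing S =
  scale-proportional Gaussian in time (sigma = one scale, implemented as
  three boxcar passes of matched variance, O(n) in the window length) and
  a 3-point boxcar across scales. Without smoothing coherence is
  identically 1. Inside the graph builder the scale grid uses 6 voices
  per octave (the coupling bands span ~1.3 octaves, leaving ~8 scales)
  and single-precision fields; both choices change the coupling statistic
  by far less than its sampling noise.
* **Coupling weight**: per time sample, the maximum over in-band scales of
  |imag C| — insensitive to zero-lag co-variation by construction.
* **Significance**: per pair and event window, the time-mean coupling must
  exceed the maximum over 19 AAFT surrogates of the first node (one-sided
  alpha = 1/20). AAFT surrogates preserve the amplitude multiset exactly
  and the spectrum approximately. Non-significant pairs are masked to 0.
  Testing once per pair per window (not per sample) is deliberate: 19
  surrogates give no meaningful per-sample resolution.
* **Topology per time sample**, on four partitions (EEG–EEG, EEG–SpO2,
  EEG–RRi, all connections; each restricted to its participating nodes):
  distances d = 1/weight; characteristic path length (mean finite
  off-diagonal distance), global efficiency (mean 1/d, 0 for disconnected
  pairs), node-averaged Onnela clustering (geometric-mean triangle
  intensity, weights normalized by the matrix maximum), node-averaged
  eccentricity (max finite distance per node; isolated nodes excluded),
  and the redundancy optimum n_sup: with the positive weights ordered
  descending, n_sup is the removal count n maximizing H + E, where H is
  the entropy of the remaining weights renormalized to a distribution
  (the entropy term is otherwise ill-defined) and E is the squared
  deviation from the original weights; smallest n wins ties. A
  configuration switch evaluates H − E instead, since maximizing H + E
  rewards deviation; both variants satisfy the same argmax/tie
  properties. Shortest paths use a Floyd–Warshall vectorized over time
  samples; an independent brute-force implementation serves as the test
  oracle. Per-epoch features are the mean and SD of each index chart over
  in-epoch samples outside the cone of influence.

## Classification

One row per hypoxic event, labelled by the subject's stress status. Within
each leave-one-patient-out fold (all events of one subject held out, per
monitoring group and desaturation threshold), refit from scratch on the
training subjects only: median imputation (training medians; all-NaN
training columns dropped); age correction (features with a Pearson
correlation against post-menstrual age at p < 0.05 on training rows are
replaced by residuals of a training-fit line, applied to train and test);
F-score ranking (Chen–Lin two-class ratio); a greedy correlation filter in
descending F-score order dropping features with |r| > 0.9 against an
already-kept feature; pre-selection of the top 3·floor(n_train/10)
features. The classifier is a bagged ensemble of linear discriminants
(lsqr solver, uniform class priors; shrinkage 0.1 on degenerate
within-class covariance), each learner drawing a stratified bootstrap and
a uniform random feature subset of floor(n_train/10) columns; the ensemble
score is the mean posterior. Ensemble size is chosen from {15, 30, 60} by
10-fold CV AUC inside the training fold (ties to the smaller ensemble).
Uniform priors matter: LOPO folds have slightly different class ratios,
and prior-driven posterior shifts would systematically anti-correlate
pooled scores with the held-out label under the null. Pooled test scores
yield the AUC (Mann–Whitney rank form, identical to trapezoidal ROC
integration) and Cohen's kappa at the 0.5 operating point (kappa defined
as 0 when expected agreement is 1).

## Synthetic cohort

The generator emulates the statistical structure the analysis relies on,
not physiological morphology:

* **Tachogram**: baseline RR 0.42 s modulated (±2 %) by a band-limited
  process s(t) in the group's coupling band plus a 0.2–0.5 Hz
  "breathing" component; beats integrated from the instantaneous RR.
  Bradycardias are raised-cosine RR elongations (depth factor 1.8–2.2,
  duration 6–12 s) with beats re-timed so the beat-time/RR invariant
  holds exactly.
* **SpO2**: baseline 96 % plus AR(1) noise (sigma 0.3 %, rho 0.9 — slow
  oximeter dynamics), with V-shaped desaturations co-timed 2–8 s after
  each bradycardia peak (depth N(12, 2) %, duration 30–50 s).
* **EEG**: per channel, 20 uV of exact fractional Gaussian noise
  (circulant embedding; Hurst 0.55 baseline) plus a 6 uV delta-band
  (0.5–4 Hz) carrier whose amplitude envelope is 1 + k·s_lag(t), where
  s_lag is the Hilbert quarter-period shift of s(t) — the 90-degree
  offset makes the EEG–RR coherence maximally imaginary (k = 0.35
  baseline). The amplitude balance was set so that the wavelet-leader
  scales are background-dominated while the delta-power envelope still
  carries the coupling.
* **Stress effects** (all independently dialable; all zero = null
  cohort): +4 percentage points of desaturation depth; +0.15 EEG Hurst;
  +0.2 coupling weight k; +50 % relative HF modulation power (PSG group
  only).
* Event peak times are uniform with a 210-s edge margin and 360-s minimum
  spacing; the per-subject Poisson event-count draw is capped at that
  capacity (an error is raised only when not even one event fits).
  Groups are half stressed / half not; per-subject seeds derive from the
  master seed via `SeedSequence` spawn keys.

What the generator does **not** emulate: realistic EEG/ECG morphology,
maturational EEG changes (group differences enter only through the
coupling band and demographics), apneas, artifacts, or any feature–PMA
dependence (so age correction is usually a no-op on synthetic data).
Passing end-to-end tests therefore demonstrates that the pipeline recovers
the effects it is told to look for under its own assumptions — not
clinical validity on real recordings.

## Problem sizes and numerical choices

The end-to-end checks (tests and `scripts/acceptance.py`) use 20 subjects
per monitoring group, 20-minute records, on average two hypoxic events per
subject and EEG synthesized at 64 Hz — sizes chosen so the full
stressed-vs-null contrast runs at desk scale; the delta band (<= 4 Hz) and
the 1–20 Hz filter are unaffected by the lower rate. Estimator
calibrations use n = 2^15 samples and 20 realizations. Determinism: every
stochastic stage (synthesis, surrogates, bagging, CV splits) derives its
generator from one integer seed; two runs with the same configuration are
byte-identical. CSV output uses a 13-significant-digit float format, which
round-trips below 1e-9 absolute error over hour-long time axes.

## Known limitations

* The 4-s bradycardia criterion counts summed supra-threshold RR, and the
  whole-record mean RR includes event beats; both follow the stated
  definitions literally, so records that are mostly bradycardic would
  raise the detection threshold.
* The desaturation baseline (60-s running median) is a documented stand-in
  for a published detector whose details are not reproduced here.
* The Eq.-style redundancy objective H + E is evaluated as printed; its
  sign convention is debatable (see the H − E switch).
* Wavelet-leader estimates on short epochs (< 2^10 samples at the working
  rate) are reported missing rather than extrapolated.
* The classifier's ensemble grid and the 0.5 kappa operating point are
  package choices where the underlying method family leaves them open.
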