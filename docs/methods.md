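# Methods and design notes

## Scope and model of the analysis

The package implements a within-subject, three-condition
cardio-respiratory study design: quiet rest (`Rest`), a mental-imagery
control task (`Imag`) and self-induced cognitive trance (`SICT`), one
~12-minute recording per subject and condition, of which a contiguous
11-minute segment (the window length available across a whole cohort
after discarding the trance-induction period) is analysed.  The
analysis makes no assumption about the direction of condition effects;
effects are assessed purely by per-feature decodability under
familywise-controlled permutation inference.

## Cardiac chain

1. **Filtering.** Zero-phase order-5 Butterworth high-pass at 0.5 Hz
   (baseline/DC removal) followed by a mains notch (default 50 Hz,
   Q = 30; configurable to 60 Hz).  Zero-phase application avoids
   shifting R-peak latencies.
2. **R-peak detection.** Derivative → squaring → 150 ms
   moving-window integration; candidate peaks above 25 % of the 99th
   percentile of the envelope, separated by a 200 ms refractory
   period, refined to the extremum of the absolute filtered signal
   (±100 ms), which makes the detector polarity-insensitive.  Events
   within 0.5 s of either recording edge are discarded because
   zero-phase filter transients and truncated complexes there are not
   reliably localizable.
3. **RR artifact correction** (automated stand-in for manual review):
   against a running median of 11 intervals, an interval > 1.65× the
   local median is split into `round(ratio)` parts (missed beats),
   < 0.55× is merged with its successor (spurious detection), and
   intervals outside [300, 2000] ms or deviating > 30 % from the local
   median are replaced by cubic interpolation of the interval profile.
   More than 20 % flagged intervals marks the recording unusable — the
   same attrition rule a human rater applies when a recording is
   dominated by movement artifact.
4. **Spectral HRV.** The RR tachogram is cubically interpolated onto a
   uniform 4 Hz grid and analysed with Welch (120 s Hann segments,
   50 % overlap, constant detrend per segment).  With 660 s segments
   this resolves the 0.04 Hz band edge while averaging ~10
   periodograms.  LF = [0.04, 0.15) Hz, HF = [0.15, 0.4) Hz, both in
   ms²; normalized powers divide by total power over [0.04, 0.4) Hz
   (VLF excluded — a 660 s window cannot estimate VLF meaningfully,
   and including it would make the normalization window-length
   dependent).  When HF = 0, ln HF and LF/HF are reported as missing,
   never as infinities.
5. **Heart-rate correction.** Spectral power scales mechanically with
   cycle length, so each raw spectral metric is also emitted
   multiplied by the segment mean RR interval expressed in seconds
   (suffix `_c`).  The package emits *both* conventions because
   published spectral magnitudes in this literature are often not
   reconcilable with plain ms² values; users comparing magnitudes
   across studies should check which convention a source used.
6. **Approximate entropy.** ApEn(m = 2, r = 0.2·SD), Chebyshev
   distance, self-matches included (the field-standard parameterization
   for series of a few hundred beats).

## Respiratory chain

Linear detrend, zero-phase order-5 Butterworth low-pass at 2 Hz.
Breath landmarks are local extrema with prominence ≥ 0.3 signal SD
(a relative criterion, so detection is amplitude-scale invariant) and
a 1.5 s minimum breath period, pruned to strict trough/peak
alternation.  The *B peak* — the breath event between which BB
intervals are measured — is taken as the inhalation maximum, i.e. the
onset of exhalation; the inspiratory phase is trough → peak and the
expiratory phase peak → next trough.  Feature semantics:
rate = 60000/mean(BB) (breaths/min), amplitude = mean
peak-minus-preceding-trough excursion (channel units; belts are
uncalibrated, so units are arbitrary and the feature is strictly
linear in channel gain), phase-duration ratio = mean inspiratory /
mean expiratory duration, SDBB and RMSSD-BB in ms.

BB artifact correction reuses the RR rule family with respiratory
bounds ([1.5, 20] s, 40 % deviation, split at 1.8×, merge below
0.55×).  Because interval interpolation rebuilds event times by
cumulative summation, corrected event times can drift off the
waveform; the extraction therefore computes *geometric* features
(amplitude, phase ratio) from the detected, waveform-aligned events
and *interval-variability* features (rate, SDBB, RMSSD-BB) from the
corrected series.  Both belts run through identical code.

## Decoding

Single-feature, two-class linear discriminant analysis with pooled
within-class variance and equal priors — which in one dimension
reduces exactly to a midpoint threshold between the class means — under
leave-one-subject-out cross-validation: each fold trains on the paired
observations of the remaining subjects and predicts the held-out
subject's two observations.  Ties at the boundary (including the
degenerate identical-means case) go to the lexicographically lower
condition label, keeping the observed path fully deterministic.

Permutation inference swaps the two condition labels within each
subject with probability ½ — the exchangeability that the paired
design actually licenses (a global label shuffle is available by
option but breaks the one-observation-per-subject-per-class
structure).  The same 1000 resamples are shared by all features of an
analysis so that the per-permutation maximum DA across features is a
coherent joint null; the familywise threshold is the (1 − α) empirical
quantile of those maxima (`method="higher"`), the comparison is strict
(DA > threshold), and by construction the threshold dominates every
feature's own (1 − α) null quantile.  The permutation engine is a
vectorized closed form of the fold loop (verified equal to it in the
tests); with n subjects the observed DA is always a multiple of
100/(2n), and fold counts are reported explicitly.

One caveat documented rather than asserted: DA is *not* invariant to
monotone transforms of a feature (LDA is not rank-based), so e.g. HF
and ln HF legitimately yield different DAs.

## Phasic/tonic analysis

Tonic = Rest value; phasic = task − Rest, exact arithmetic per
subject.  Spearman correlations of tonic vs phasic use an exact
permutation p-value for n ≤ 8 (8! = 40 320 enumerations; beyond that
enumeration is intractable and the t-approximation is accurate) and
the t-approximation otherwise.  Because phasic is defined as
(task − tonic), it anti-correlates with tonic even when the task value
is independent of rest; the correlation output carries a note to this
effect, and strongly negative tonic–phasic correlations should be read
with that construction in mind.  The Pearson dependence check pools
all subject–condition observations of a metric against heart rate or
respiratory rate; it is the instrument for verifying that the
multiplicative heart-rate correction abolishes the mechanical
HRV–heart-rate dependence.

## Synthetic cohort generator

The generator's default profiles define the study conditions the
package emulates.  RR intervals follow direct interval modulation
(mean + LF sinusoid at 0.10 Hz + HF sinusoid at the respiratory
frequency + noise evaluated at beat times) rather than an
integral-pulse-frequency-modulation model: band powers, not
beat-generation physiology, are the ground truth the downstream stages
consume.  The noise term mixes a broadband white component with a
smooth AR(1) (φ = 0.9) component in proportion `hr_entropy_mix`;
regularity (ApEn) is controlled through this mix because ApEn has no
tractable inverse to target directly.  The ECG is a fixed biphasic
QRS-like kernel with its maximum exactly on the R time; morphology
realism (P/T waves, ectopy) is a non-goal.  Respiration is a
piecewise raised-cosine whose inspiratory:expiratory durations are in
exact ratio `ie_ratio`; breath-to-breath jitter is injected directly
on the B-peak times, so ground-truth SDBB equals the configured
jitter.  Boundary breaths approach the midline by half-cosines so the
first and last extrema remain detectable.

Default condition profiles: Rest and Imag are *identical* (mean RR
874 ms ≈ 69 bpm group mean after the curvature of 60000/RR, LF 35 ms,
HF 40 ms, noise 28 ms at mix 0.85, 15.4 breaths/min, amplitude 210,
I:E 0.74, BB jitter 350 ms); SICT shortens mean RR to 750 ms
(≈ 81 bpm), raises LF modulation (65 ms) and broadband noise (42 ms)
while withdrawing HF modulation (12 ms), lowers the entropy mix to
0.05 (a markedly more regular tachogram), and deepens breathing
(amplitude 375, I:E 1.04, BB jitter 900 ms, 14.96 breaths/min).  The
heart-rate targets and effect directions reproduce the published
group-level pattern for this state (trance: faster heart rate, higher
overall RR variability, vagal HF withdrawal, lower entropy, deeper and
more variable breathing with relatively longer inspiration); the BB
jitter magnitudes are set below some published SDBB values, which
plausibly include detector artifacts that the generator does not
emulate.  Per-subject random effects are truncated-normal
multiplicative factors shared across a subject's three conditions
(preserving the pairing), with CVs of 8 % on mean RR, 25 % on the
modulation depths, 15 % on noise, rate and I:E ratio and 30 % on
amplitude and BB jitter.  These CVs are deliberately at the lower end
of published between-subject spreads: printed cohort SDs include
measurement and equipment variance on top of biology, and using them
verbatim as biological random effects would double-count that variance
once the pipeline's own estimator noise is added.

Determinism: every stream derives from
`SeedSequence(master_seed, spawn_key=(subject, condition, channel))`
(reserved condition slots 1000/1001 carry the subject-level
random-effects and self-report streams), so identical configuration
and master seed give bit-identical recordings.

What the generator does **not** emulate — and hence what passing tests
do and do not show: no ectopic beats or electrode artifacts (the
artifact-correction rules are exercised by synthetic corruptions in
the tests, not by the generator), no realistic ECG morphology, no
cardio-respiratory phase coupling beyond the HF modulation frequency
tracking the respiratory rate, no belt calibration to tidal volume,
and no drift or movement noise.  Results on real recordings therefore
depend on detector robustness beyond what the clean-signal
ground-truth recovery tests certify.

A separate generator configuration (`hr_dependent_profiles`) builds a
cohort whose HF modulation depth scales as √(1/mean RR) with
independent per-subject factors, making raw HF power mechanically
proportional to heart rate while rate-corrected HF is independent of
it — the configuration under which the correction property is
verified.

## Problem sizes in simulations

The simulation-based checks run at the study's own scale: 26 subjects
× 3 conditions × 11-minute segments.  The decoding-calibration study
uses 150–200 independent global-null replicates (27 features, 1000
permutations each); the decoding-power study uses 20 independent
cohort replicates on the ground-truth event path, with the raw-signal
path validated separately against the same truth (detection recovers
clean-signal events to within one sample, so the two paths agree to
estimator precision while the event path runs an order of magnitude
faster).

## Known limitations

* EDF input is not implemented; recordings are exchanged as
  `time_s,value` CSV per channel plus a manifest.
* The artifact rules are deliberately simple and deterministic; they
  flag genuine physiology when breath-to-breath variability exceeds
  ~35 % CV (such recordings are excluded by the 20 % rule exactly as a
  conservative human rater would drop them, and paired analyses
  proceed without that subject).
* Spectral magnitudes depend on the interpolation/Welch conventions
  above; only convention-stable quantities (normalized powers, logs,
  ratios, and within-study contrasts) should be compared across
  toolkits.
* The phasic/tonic Spearman correlation inherits the difference-score
  coupling discussed above; it quantifies reactivity scaling, not an
  independent association.
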