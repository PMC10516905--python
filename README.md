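# cardioresp

Cardio-respiratory variability analysis for within-subject studies of
non-ordinary states of consciousness — in particular self-induced
cognitive trance (SICT), a volitional trance state practised while
sitting motionless, studied against a quiet-rest baseline and a
mental-imagery control task.

The package turns raw ECG and respiration-belt recordings into a
27-feature autonomic profile per subject and condition, and asks, for
every feature separately, *can this metric tell the conditions apart?*
using a linear discriminant under leave-one-subject-out
cross-validation with permutation maximum-statistics inference.
Because study recordings of this kind are rarely shareable, the
package ships a synthetic cohort generator with full ground truth so
that every stage — detection, correction, feature extraction,
decoding — is testable end to end.

## What it computes

**Cardiac (16 metrics).** From the filtered ECG (0.5 Hz order-5
high-pass Butterworth + mains notch), R peaks are detected
(derivative–square–integrate with a 200 ms refractory period),
artifact-corrected RR intervals are formed, and an 11-minute segment
is analysed:

* time domain — heart rate (mean of 60000/RR_i), RR mean,
  SDNN = SD(RR), RMSSD = √mean(ΔRR²), pNN50 = %{|ΔRR| > 50 ms};
* frequency domain — Welch PSD of the cubically interpolated 4 Hz RR
  tachogram; LF = power in [0.04, 0.15) Hz, HF = [0.15, 0.4) Hz
  (ms²), normalized LFn/HFn (dividing by total power in
  [0.04, 0.4) Hz), ln HF, LF/HF;
* heart-rate-corrected spectral variants (suffix `_c`) — each raw
  spectral power multiplied by the segment mean RR interval (s), which
  removes the mathematical dependence of spectral HRV on heart rate;
* nonlinear — approximate entropy ApEn(m=2, r=0.2·SD),
  Φ_m − Φ_{m+1} with self-matches, Chebyshev distance.

**Respiratory (11 metrics).** Each belt (thoracic, abdominal) is
detrended and low-passed (2 Hz, order 5), breath landmarks located
(inhalation onset at the trough, B peak at the inhalation maximum =
exhalation onset, minimum breath period 1.5 s): respiratory rate,
amplitude (mean peak-minus-preceding-trough excursion), phase-duration
ratio (mean inspiratory / mean expiratory duration), and the
breath-to-breath variability metrics SDBB and RMSSD-BB, plus the
belt-averaged rate.

**Inference.** For each condition pair (Rest vs SICT, Rest vs Imag,
Imag vs SICT) and each feature, a pooled-variance linear discriminant
is evaluated under leave-one-subject-out cross-validation; decoding
accuracy DA = % correctly classified held-out observations.  A null
distribution is built from 1000 permutations that swap the two
condition labels within each subject (preserving the paired design);
the familywise threshold at α = 0.05 is the 95th percentile of the
per-permutation *maximum* DA across all features, so a feature is
significant only if it beats the best null feature.

**Phasic/tonic vagal analysis.** For a chosen metric (HF by default),
tonic = Rest value, phasic = task − Rest per subject, with Spearman
correlation of tonic vs phasic across subjects (the output documents
the regression-to-the-mean coupling inherent in a difference score).

## Worked example

```python
from cardioresp import CohortConfig, ConditionDecoder, generate_cohort, feature_table

cohort = generate_cohort(CohortConfig(n_subjects=26, master_seed=0), waveforms=False)
table, exclusions = feature_table(cohort, path="truth")
res = ConditionDecoder(table, ("Rest", "SICT")).fit(n_perm=1000, seed=0)
print(res.summary().head(8).to_string(index=False))
print(f"threshold = {res.threshold:.1f}%  ({res.n_perm} permutations, "
      f"{int(res.significant.sum())}/{len(res.features)} features significant)")
```

prints

```
      feature        da  threshold  significant         pair  n_subjects  n_observations
          lfn 98.076923  71.153846         True Rest vs SICT          26              52
        ln_hf 98.076923  71.153846         True Rest vs SICT          26              52
          hfn 98.076923  71.153846         True Rest vs SICT          26              52
        pnn50 96.153846  71.153846         True Rest vs SICT          26              52
      ln_hf_c 96.153846  71.153846         True Rest vs SICT          26              52
           hf 94.230769  71.153846         True Rest vs SICT          26              52
        rmssd 94.230769  71.153846         True Rest vs SICT          26              52
lf_hf_ratio_c 94.230769  71.153846         True Rest vs SICT          26              52
threshold = 71.2%  (1000 permutations, 24/27 features significant)
```

Each row is one single-feature classifier: `da` is its
leave-one-subject-out decoding accuracy over 52 held-out observations
(26 subjects × 2 conditions) and `threshold` the familywise bar that
the best-of-27 null features set; the trance condition is decodable
from almost every vagal and respiratory metric here, while the same
cohort's Rest-vs-Imag contrast (generated identically) yields none.

The same analysis runs from the shell on recordings stored as
`time_s,value` CSVs listed in a manifest:

```bash
cardioresp synth --n-subjects 26 --seed 0 --out cohort/
cardioresp run cohort/manifest.csv --out report/
```

## Layout

```
src/cardioresp/
  channels.py   waveform / event-series containers
  synth.py      synthetic cohort generator with ground truth
  cardiac.py    ECG filtering, R-peak detection, RR correction, HRV
  resp.py       belt preprocessing, breath detection, RRV
  features.py   the 27-feature registry and extraction paths
  decode.py     LOSO-LDA decoding + permutation max statistics
  phasic.py     phasic/tonic analysis, dependence checks
  pipeline.py   end-to-end orchestration with provenance
  io.py, config.py, cli.py
docs/methods.md   modelling and design notes
```
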