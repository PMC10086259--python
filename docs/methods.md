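# Methods

## The measurement model

A stimulus confined to one visual hemifield evokes the early visual ERP
components P1 (positive, within ~200 ms) and N1 (negative, ~150–250 ms)
first over the contralateral occipital cortex and, after transfer
through the splenium of the corpus callosum, over the ipsilateral
cortex. The transfer time (IHTT) is estimated as the indirect-minus-
direct latency difference, averaged over the two hemifield × electrode
cells per pathway:

    IHTT_comp = (L[LVF→ipsi] + L[RVF→ipsi]) / 2 − (L[LVF→contra] + L[RVF→contra]) / 2

For the 128-channel layout shipped with the package the occipital
region-of-interest electrodes are index 65 (left posterior) and index 90
(right posterior). Because the estimator is a difference of means, any
latency distortion common to both pathways (e.g. filter broadening)
cancels exactly; this is verified by the noiseless pipeline tests.

The behavioral analogue subtracts mean correct response times of
uncrossed (stimulus and responding hand on the same side's hemisphere:
direct) from crossed combinations. It is retained for completeness but
is a far noisier instrument: a few milliseconds of crossed–uncrossed
difference sit on top of hundreds of milliseconds of ex-Gaussian RT
variability, so its manipulation check is expected to fail at ordinary
sample sizes (the package's own check quantifies this).

## Synthetic sessions

`ihtt.simulate` generates the study conditions end to end; all defaults
are stated here with units.

| parameter | default | meaning |
|---|---|---|
| `p1_latency_ms` / `n1_latency_ms` | 95 / 165 | direct-pathway peak latencies |
| `ihtt_ms` | 34 | injected transfer delay |
| `p1_amplitude_uv` / `n1_amplitude_uv` | +4 / −6 | peak amplitudes at the ROI electrode |
| `ipsilateral_gain` | 0.8 | indirect-response attenuation |
| `component_width_ms` | 25 | Gaussian FWHM of each component |
| `noise_rms_uv` | 5 | instrument noise RMS per channel |
| `noise_spectrum` | mix | equal-power 1/f + white |
| `blink_rate_hz` / `blink_amplitude_uv` | 0.1 / 120 | Poisson blink artifacts, ~300 ms half-cosine |
| `rt_exgauss` | µ 600, σ 60, τ 100 ms | ex-Gaussian response times |
| `rt_crossed_uncrossed_delta_ms` | 4 | RT penalty on indirect trials |
| `accuracy_p` | 0.9 | Bernoulli correctness |

Design choices worth knowing:

- **Component shape.** Gaussian bumps; `component_width_ms` is the full
  width at half maximum (σ = width/2.355). With the default latencies
  this keeps P1 and N1 separable; a σ-interpretation would not.
- **Scalp topography.** Each hemisphere's evoked pattern is a Gaussian
  in great-circle distance around its ROI electrode, confined to that
  hemisphere's scalp channels, shifted to sum to zero across the scalp
  and rescaled to 1 at the ROI electrode. The zero sum makes average
  referencing exactly latency-preserving; the hemisphere confinement
  keeps the two latencies from mixing into one channel. Bilateral trials
  evoke both hemispheres simultaneously with no delay structure.
- **Injected latencies are snapped to the 1 ms grid** and recorded in
  the returned ground truth, so "exact" recovery is well defined.
- **Bad channels** are contaminated with large narrowband 8–12 Hz
  oscillations (RMS 25 µV, random phase relative to stimuli). This
  drives the differential-average detector past its 50 µV bound without
  tripping the 100 µV per-trial rejection, which is the regime in which
  channel interpolation (rather than trial loss) is the right remedy.
- **Single-trial latency/amplitude jitter defaults to 0** (their true
  magnitudes in real data are unknown); both are exposed as parameters.
- **Cohorts** draw participant-level parameters with between-subject
  SDs (IHTT 8 ms, RT offset 3 ms, latencies 10 ms, RT µ 60 ms) and share
  a participant component across sessions so repeated measures correlate
  at ρ (default 0.3). IHTT values are truncated at 1 ms — the QC stage
  excludes negative estimates, so the generator keeps truth positive.

What the generator does **not** emulate: volume conduction from real
cortical sources, heteroscedastic or non-Gaussian instrument noise,
alpha rhythms and other structured background EEG, drifting electrode
impedances, eye movements other than blinks, and trial-to-trial
component-shape variability. Passing recovery tests therefore show the
pipeline is correct and unbiased under its own assumptions, not that
real recordings meet those assumptions.

## Reduction chain

Fixed order: band-pass → segment → reject → blink removal → bad-channel
interpolation → average reference → baseline → per-condition average.

- **Filtering**: squared magnitude response of 4th-order Butterworth
  high-pass (0.1 Hz) and low-pass (15 Hz) stages applied with zero
  phase. The default realization multiplies the spectrum directly
  (identical to forward–backward IIR filtering up to edge transients and
  stable in single precision); `realization="iir"` runs `sosfiltfilt`.
  The 15 Hz low-pass broadens the P1/N1 bumps and, because they overlap,
  displaces absolute peak latencies by ~3 ms — identically for direct
  and indirect pathways, leaving IHTT untouched (tested both ways).
- **Epochs** are half-open [−200, 1000) ms windows (1200 samples at
  1 kHz), unilateral non-practice trials only.
- **Rejection thresholds** (µV): 100 absolute on scalp channels, 100
  sample-to-sample, 70 on eye channels. Rejection precedes blink
  removal, so most blink-contaminated trials are simply dropped; the ICA
  stage catches blink residue in what remains.
- **Blink removal**: FastICA (fixed seed, 15 components, fit on
  5×-decimated samples) on concatenated retained epochs; a component is
  projected out if its scalp pattern correlates |r| ≥ 0.9 with *either*
  of two built-in frontal templates (the more conservative reading of a
  two-template rule; the removed count is recorded). Decomposition
  failure leaves the data unmodified and sets a flag.
- **"Fast average amplitude"** is implemented as the mean over trials of
  the per-epoch maximum absolute voltage (bound 100 µV), and
  **"differential average amplitude"** as the mean over trials of the
  per-epoch maximum absolute deviation from the channel's across-trial
  mean waveform (bound 50 µV) — gross amplitude vs trial-to-trial
  instability. Eye channels are exempt (they legitimately carry large
  deflections). Flagged channels are replaced by the
  inverse-great-circle-distance weighted mean of their 6 nearest good
  scalp neighbors; more than 20 % bad channels aborts.
- **Average reference** uses scalp (non-eye) channels; baseline is the
  [−200, 0) ms mean per trial and channel.
- **Residual noise** is the plus–minus average: retained correct trials
  averaged with alternating signs (last trial dropped if odd), RMS over
  the full epoch; reported per participant as the mean over the two ROI
  electrodes, with exclusion above 10 µV.
- **Evoked averages** use retained *correct* trials of one visual field
  and are flagged unusable below 5 trials per cell.

## Scoring and QC

Peaks are located by exhaustive search on the 1 ms grid: P1 = most
positive point in [0, 200] ms, N1 = most negative in [150, 250] ms, ties
to the earliest latency. If the extremum lands on a window boundary the
window widens symmetrically in 25 ms steps, clamped to [0, 350] ms,
until the extremum is interior — an automated, audit-flagged stand-in
for per-waveform visual inspection. A flat window returns its start
without flagging.

Participants are excluded when: P1 or N1 IHTT is negative
(physiologically improbable; the flag is per component, so a negative N1
IHTT does not invalidate the P1 analysis), residual noise exceeds 10 µV,
any required cell is under 5 trials, or performance validity fails. The
validity rule is conjunctive: all administered of the first two TOMM
recognition trials below 45 *and* Reliable Digit Span ≤ 6 (a first-trial
score ≥ 45 short-circuits — later trials are typically not
administered). Negative RT differences are legitimate and never exclude.

## Statistical battery

- **Outliers**: |x − median| > 1.5 × IQR, strict inequality, type-7
  (linear interpolation) quantiles; a participant flagged at either
  session is dropped from that measure at both sessions.
- **Mixed 2×2 ANOVA**: complete cases; SS decomposition into group,
  subjects-within-group, session, interaction, and session×subjects
  error; F(1, N−2) for all three effects. Generalized eta squared
  divides each effect SS by itself plus *all* subject-level error SS,
  making between- and within-effects comparable.
- **t-tests**: paired t with d_z = t/√n; independent t pooled by
  default, switching to Welch/Satterthwaite when a median-centered
  Levene pre-test rejects at α = 0.05. Cohen's d always uses the pooled
  form d = t·√(1/n₁+1/n₂).
- **Correlations**: Pearson, pooled across groups by default (a
  per-group option exists), significance declared at α = 0.01.
- **Sensitivity**: minimal detectable d solves the two-sided two-sample
  noncentral-t power equation (noncentrality d·√(n₁n₂/N)) by Brent root
  finding; minimal detectable f for the within-between interaction uses
  the noncentral F with λ = f²·N·m/(1−ρ), df (1, N−groups). Both are
  verified against Monte-Carlo power in the tests. For n = 29/24 at 80 %
  power the exact solution is d = 0.788 (d = 0.80 yields 81.3 % power);
  the package reports the exact value.

## Validation studies and problem sizes

`ihtt.recovery` runs the package's own end-to-end validation: compact
all-unilateral sessions (two 40-trial blocks, so ~40 trials per
visual-field cell — matching the per-cell trial counts of the full
384-trial task at a fraction of the simulation cost), 40 participants
for the 34 ms recovery study and 20 for the 0 ms null study, with
accuracy set to 1 so cell counts are exact. Typical results: mean
recovered P1/N1 IHTT within ~0.5 ms of the injected 34 ms, and |mean|
< 1 ms under the null. The ERP manipulation check (paired t, direct vs
indirect latency, n = 20) rejects with |d_z| ≫ 1; the RT check with a
4 ms offset rejects only rarely, as expected from its effect size
(≈ 0.15 at 40 trials per pathway).

## Known limitations

- The synthetic scalp patterns are stylized (rank-1 per hemisphere); no
  forward head model is used.
- The 128-channel layout is a synthetic approximate-equidistant lattice;
  only relative distances (neighbor sets, interpolation weights,
  left/right tags) are meaningful.
- The blink templates are generated from the montage geometry, not from
  empirical blink averages.
- Peak-based scoring inherits peak-picking's sensitivity to noise at low
  trial counts; no single-trial or amplitude-based IHTT is provided.
- The EDF writer uses a fixed ±3276.7 µV physical range (0.1 µV
  resolution) and pads recordings to whole seconds.
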