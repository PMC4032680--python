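# Methods

## The measurement model

The package operationalizes happiness as a region of a three-dimensional
affect space — physiological arousal × emotional valence × life
satisfaction — measured on the same subjects across three successive
recording epochs: a relax induction, the candidate experience, and a stress
induction. Each dimension is carried by several physiological indexes, and
each index has an expected pattern over the ordered epochs
(relax, candidate, stress):

* **arousal** (HR, SC mean, EEG beta power, pupil size; respiration depth in
  smaller-is-higher form): candidate significantly above relax and
  statistically indistinguishable from stress;
* **valence** (zygomaticus EMG, frontal alpha asymmetry; corrugator EMG and
  orbicularis/startle EMG in smaller-is-higher form): candidate
  indistinguishable from relax and significantly above stress on the
  dimension-positive scale;
* **life satisfaction** (NN50, RMSSD, HF power; LF/HF and LF power in
  smaller-is-higher form): candidate at the extreme relative to *both*
  ground truths, with significant differences in both comparisons.
  Satisfaction rides on vagally mediated HRV because life satisfaction is
  treated as the opposite pole of depression, whose HRV signature
  (low RMSSD/HF, high LF/HF) is well established.

For every index the battery runs a one-way within-subjects ANOVA, Bonferroni
paired comparisons for the two hypothesis-relevant pairs, and orthonormal
linear/quadratic trend contrasts. All three dimension patterns imply a
*concave* quadratic component (candidate epoch elevated against the average
of the two ground truths after smaller-is-higher inversion), so a measure's
pattern is met when: the corrected main effect is significant; every
expected-significant pair is significant with the candidate on the correct
side; every expected-similar pair is non-significant; and the quadratic
contrast is significant with negative (concave) orientation. A
quadratic-only trend (no significant linear trend) is annotated as
*strengthening* the pattern, since it indicates the candidate epoch
dominates both ground truths rather than sitting between them.

"Similarity" between epochs is operationalized as non-significance of the
adjusted pairwise test. Non-significance is of course not equivalence; an
equivalence-test mode (two one-sided tests with a user margin) would be a
straightforward extension but is off by default to match the protocol.

A dimension is *supported* when the fraction of its measures meeting the
pattern strictly exceeds the quorum (default 0.5, i.e. a strict majority; a
tie is recorded as borderline and left unsupported). The final rule:

* `happiness` — all three dimensions supported;
* `not_happiness` — valence or satisfaction actively contradicted
  (an expected-significant pair significant in the opposite direction in a
  majority of that dimension's measures), or both valence and satisfaction
  unsupported;
* `inconclusive` — anything else.

Every report carries a standing guard note that the arousal profile of
happiness is indistinguishable from stress by design, so arousal-only
support can never produce a happiness classification. A second note fires
when HR disagrees with the other cardiovascular indexes, since the
baroreceptor reflex (Mayer waves at ~0.1 Hz) can depress HR and perturb the
sympathovagal balance across dimensions.

## Statistical battery

* **rmANOVA.** F = MS_condition / MS_error from the standard two-way
  (subject × condition) decomposition with the subject effect removed;
  partial η² = SS_condition/(SS_condition+SS_error). Degenerate inputs
  (zero effect *and* zero error variance) report F = 0 with a flag.
* **Sphericity.** Mauchly's W from the orthonormally contrasted condition
  covariance with the usual chi-square approximation; Greenhouse–Geisser ε
  from the double-centred covariance; Huynh–Feldt ε floored at ε_GG and
  capped at 1 (for k = 3 the HF formula exceeds 1 under compound symmetry;
  the cap follows common statistical-package convention). Correction policy:
  none when Mauchly's test is not significant at α; otherwise HF when
  ε_GG > 0.75 (Girden's rule) else GG. Raw and corrected p are always both
  reported, with df shrunk to (ε·df1, ε·df2).
* **Pairwise.** Paired-difference t tests on subject-matched differences;
  p_adj = min(1, m·p_raw) with m = number of comparisons (default 2: the two
  hypothesis-relevant pairs).
* **Contrasts.** Linear (−1,0,1)/√2 and quadratic (1,−2,1)/√6 applied per
  subject; one-sample t on the scores gives F = t² with df (1, n−1). Using
  each contrast's own error term keeps the inference valid under sphericity
  violation.
* **Power.** λ = f²·N·k/(1−ρ), df1 = (k−1)ε, df2 = (N−groups)(k−1)ε,
  power = P(F′(df1,df2,λ) > F_crit). This within-factor convention
  reproduces the canonical planning row for the design — f = 0.25, α = .05,
  k = 3, ρ = .5, ε = 1 → N = 28, λ = 10.5, F_crit = 3.168246, df = (2, 54),
  actual power = 0.8124546. An alternative convention with λ additionally
  scaled by ε is exposed via `PowerSpec(lambda_uses_epsilon=True)`.

## The synthetic cohort generator

No public recordings exist for this three-epoch protocol, so the generator
is a first-class component. What it emulates, per channel:

* **NN series** — generated directly as an event series (tachogram): base
  interval 60000/HR ms plus sinusoidal modulations at 0.10 Hz (LF) and
  0.30 Hz (HF) — the centres of the 0.04–0.15 and 0.15–0.5 Hz analysis
  bands — plus white jitter, floored at 250 ms. The indexes all operate on
  NN intervals, so no waveform ECG is needed; a template renderer
  (Gaussian QRS complexes) exists solely to exercise R-peak detection.
* **Skin conductance** — tonic level + linear drift + Poisson-timed phasic
  responses with 1 s exponential rise and 4 s decay (amplitude ~0.3 µS,
  lognormal-dispersed), clipped at zero.
* **EMG** — zero-mean Gaussian noise under an amplitude envelope (burst
  level vs noise floor), so window RMS equals the envelope; recordings use
  continuously active muscles at the epoch's target RMS.
* **Respiration** — sinusoid at rate/60 Hz with peak-to-trough excursion
  equal to the target depth.
* **EEG** — sums of FFT-band-limited Gaussian noise with realized variance
  scaled exactly to the band-power target; alpha synthesized inside
  8–12 Hz and beta inside 14–28 Hz so spectral leakage stays inside the
  7–13 / 13–30 Hz analysis bands. Left and right differ only in alpha
  power, which sets the ln(R)−ln(L) asymmetry.
* **Pupil** — constant diameter with Poisson-timed 200 ms zero dropouts as
  blinks.

Sampled channels are exported at 256 Hz (one sample every 3.90625 ms; a
300 s epoch is 76,800 samples) except EMG at 1024 Hz, which broadband muscle
activity requires. Epochs default to 300 s and tile the recording
contiguously in relax → candidate → stress order.

**Scenario targets.** `happiness_true` realizes the full hypothesis sign
pattern (e.g. HR 65 → 74 → 74 bpm, SC 4.0 → 6.5 → 6.5 µS, zygomatic
8 → 8 → 3 µV, alpha asymmetry +0.4 → +0.4 → −0.2, HF modulation
25 → 50 → 25 ms). `stress_only` makes the candidate epoch a full stress
replica (arousal pattern present, valence/satisfaction signatures absent);
`null` holds every epoch at the relax baseline. `effect_scale` shrinks all
deviations from the relax baseline; 0 reproduces `null`.

**Variability model.** Stable between-subject differences are a lognormal
multiplicative factor per parameter (sd ≈ 10% of the mean); an independent
per-(subject, epoch) lognormal factor of the same size models session-level
fluctuation. Two equal components put the repeated-measures correlation
near 0.5, matching the ρ used in the power planning. The signed
alpha-asymmetry index instead receives additive Gaussian noise on its
natural scale.

**Effect magnitudes.** The protocol literature specifies directions but not
magnitudes. The defaults encode contrasts typical of real relax/stress
inductions (2–3 µS electrodermal shifts, ~10 bpm cardiac acceleration,
doubled HF modulation), which correspond to large per-measure effects
(Cohen's f ≈ 0.8–1.5). The f = 0.25 planning value is the conservative
*minimum* the design is powered for, reachable with `effect_scale ≈ 0.2`;
it is deliberately not the generator default, because the composite
classification is a conjunction of ~50 component tests across 14 measures
and has near-zero power at uniformly minimum-detectable effects — no
plausible real effect pattern behaves that way.

**What the generator does not emulate**, hence what passing tests do not
show about real data: morphologically realistic ECG/EEG waveforms, ectopic
beats and electrode artifacts beyond amplitude outliers, respiratory sinus
arrhythmia coupling between channels, cross-dimension physiological
interactions (baroreflex), non-stationarity within epochs, and missing
data. Calibration results transfer to real recordings only to the extent
that extraction noise and between/within-subject dispersion resemble the
10%/10% lognormal model.

## Feature extraction: numerical choices

* HRV spectra: NN series resampled to an even 4 Hz tachogram by cubic
  interpolation, linearly detrended, Welch PSD with 128 s Hann segments at
  half overlap, trapezoidal band integration; LF/HF with HF floored at
  1e-12 ms² and flagged undefined when both bands are empty. ≥120 s of data
  required.
* EEG band powers: Welch with 2 s segments; segments containing
  artifact-masked samples (|z| > 5, ±0.5 s guard) are dropped whole.
* EMG: epoch value is the mean of per-1 s-window RMS values.
* Respiration: breath cycles delimited by rising zero crossings of the
  detrended trace; depth = mean per-cycle (peak − trough); rate from mean
  peak-to-peak interval.
* Pupil: samples ≤ 0 are blinks, excluded with a ±100 ms guard band.
* R-peak detection: 5–15 Hz bandpass, derivative, squaring, 150 ms
  moving-window integration, 200 ms refractory, with refinement to the
  local bandpassed maximum (template ECG recovered to within one sample).
* NN50 uses strict |Δ| > 50 ms; startle is orbicularis-oculi RMS over the
  whole epoch (no probe-locked windowing), since the model uses it as an
  epoch-level valence index.

Documented round-trip tolerances on noise-free input: HR ±0.5 bpm, EMG RMS
±10%, respiration depth ±2%, alpha asymmetry ±0.05, ≥90% of LF+HF power in
the LF band for a pure 0.1 Hz modulation.

## Simulation design and problem sizes

Replicate-cohort studies (type-I calibration on 500 null cohorts,
classification recovery on 200 happiness-true and 200 stress-only cohorts,
all at the planning size n = 28) draw index tables directly from the
scenario's index-level distribution (`sample_index_table`) rather than
synthesizing ~20,000 full multi-channel recordings; the signal → extraction
path is tied to the same targets by the round-trip tests and by a
full-signal end-to-end pipeline test. Expected behaviour: corrected
per-measure type-I error ≈ 5% (measured pooled rate 4.9% ± 0.2%), null and
stress-only cohorts essentially never classify as happiness, happiness-true
cohorts classify as happiness in ≈99% of replicates at default effects.

## Sum-of-sinusoids SC fit

Nonlinear least squares on f(t) = Σ₈ aᵢ sin(bᵢt + cᵢ), initialized by
greedily peeling periodogram peaks from the residual (a term is spent on a
near-zero-frequency constant when the residual offset dominates), with five
seeded multi-start restarts. The constant candidate is always evaluated, so
RMSE never exceeds that of the best constant fit; chaining fits with
`warm_start` makes RMSE non-increasing in the number of terms. Presented as
a descriptive tracking decomposition, not a validated electrodermal model.

## Known limitations

* Purely within-subjects: no between-group factors or mixed designs, and no
  MANOVA-style sphericity-free alternative.
* No RSA index, no ectopic-beat correction, no EOG-based EEG artifact
  correction (amplitude-threshold masking only), no gaze analytics.
* The categorical decision has no continuous happiness score; quorum and α
  are configurable but the decision rule itself is fixed.
* Table-driven expectations assume the candidate epoch is recorded under
  the same conditions as the ground-truth inductions; epoch-order and
  habituation effects are not modelled.
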