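# felicity

Psychophysiological measurement of happiness.

Self-report is the dominant way to measure happiness; `felicity` implements
the alternative: an objective, multidimensional psychophysiological protocol.
A candidate experience is recorded between two ground-truth inductions —
a relax epoch and a stress epoch — on the same subjects, and the candidate
epoch qualifies as a *happiness experience* only when three independent
dimensions line up:

| dimension | hypothesis | indexes |
|---|---|---|
| physiological arousal | happiness > relax, happiness ≈ stress | HR, SC mean, EEG beta power, pupil size, respiration depth (inverted) |
| emotional valence | happiness ≈ relax, happiness > stress | zygomaticus EMG, frontal alpha asymmetry, corrugator EMG (inv.), startle/orbicularis EMG (inv.) |
| life satisfaction | happiness > relax **and** > stress | NN50, RMSSD, HF power, LF/HF (inv.), LF power (inv.) |

Because the arousal profile of happiness is indistinguishable from stress by
construction, arousal alone must never be used to claim happiness — the
classifier enforces this guard explicitly.

## What the package does

* **`felicity.cohort`** — synthesizes three-epoch multi-channel cohorts with
  controllable ground truth: NN-interval series with 0.10/0.30 Hz spectral
  modulation, tonic+phasic skin conductance, burst-modulated facial EMG,
  sinusoidal respiration, band-limited bilateral EEG, pupil traces with blink
  dropouts. Scenarios: `happiness_true`, `stress_only`, `null`.
* **`felicity.features`** — extracts all 14 indexes per (subject, epoch):
  time- and frequency-domain HRV (NN50, RMSSD, VLF/LF/HF powers, LF/HF
  sympathovagal ratio from a 4 Hz cubic-resampled tachogram), SC mean with
  artifact masking, EMG RMS envelopes, respiration depth, EEG band powers,
  ln(R)−ln(L) frontal alpha asymmetry, blink-corrected pupil mean, plus
  Pan–Tompkins-style R-peak detection for waveform ECG.
* **`felicity.stats`** — one-way within-subjects ANOVA with Mauchly's test,
  Greenhouse–Geisser / Huynh–Feldt ε corrections (Girden's 0.75 rule),
  Bonferroni paired comparisons, orthonormal linear/quadratic trend
  contrasts, partial η² → Cohen's *f* = √(η²/(1−η²)), and noncentral-*F*
  power analysis with λ = f²·N·k/(1−ρ).
* **`felicity.decision`** — evaluates each index against its expected
  pairwise/trend pattern, aggregates per dimension by strict majority, and
  emits `happiness` / `not_happiness` / `inconclusive` with guard notes and
  power diagnostics.
* **`felicity.scfit`** — least-squares fit of a sum of eight sinusoids
  `f(t) = Σ aᵢ sin(bᵢ t + cᵢ)` to a skin-conductance trace, for compact
  real-time-style tracking.

## Worked example

Sample-size planning for the three-epoch within-subjects design at a medium
effect (*f* = 0.25), α = .05, target power 0.8, repeated-measures correlation
0.5 and sphericity satisfied:

```bash
$ felicity power --f 0.25 --alpha 0.05 --power 0.8 --k 3 --rho 0.5 --epsilon 1.0
{
  "N": 28,
  "lambda": 10.5,
  "F_crit": 3.168245967251338,
  "df1": 2.0,
  "df2": 54.0,
  "achieved_power": 0.8124546105447642
}
```

i.e. 28 subjects give a noncentrality of 10.5 and actual power ≈ 0.812 for
the main epoch effect.

Simulate a small cohort in which the candidate epoch really is a happiness
experience, then run the full pipeline (extract → analyze → decide):

```bash
$ felicity simulate --n 6 --scenario happiness_true --seed 11 \
      --epoch-duration 150 --out demo/cohort
wrote 6 recordings to demo/cohort
$ felicity run --in demo/cohort --out demo/out
classification: happiness
```

`demo/out/report.txt` lists, per measure, the epoch means, F with corrected
df, raw/corrected p, ε, the Bonferroni-adjusted pairwise p's, the contrast
p's and the trend class; for example:

```
[arousal]  supported=True  support=0.80
  SC          relax=4.34  happiness=6.58  stress=7.07
    F(2.00,10.00)=40.193  p_raw=1.658e-05 p_corr=1.658e-05 (none) eps_gg=0.813 eta_p2=0.889
    pairwise: R-H p_adj=0.002507*  H-S p_adj=0.189   contrasts: lin p=0.0007828 quad p=0.012 [both]  pattern_met=True
...
guard: arousal indexes are expected to resemble stress during a happiness
experience; never classify happiness from physiological arousal alone
```

Skin conductance rises from 4.3 µS (relax) to 6.6 µS in the candidate epoch,
is significantly different from relax but not from stress after Bonferroni
adjustment, and carries the expected concave quadratic trend — the arousal
pattern of a genuine happiness experience.

The same stages are available programmatically
(`synthesize_cohort`, `extract_index_table`, `run_battery`, `classify`) and
as separate subcommands (`simulate`, `extract`, `analyze`, `decide`,
`power`, `scfit`).

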