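# Methods

This note documents the models, algorithms, and numerical choices behind
`cdsvoice`, and what the synthetic-data validation does and does not show.

## The scientific question

Mothers address young children in a distinctive register ("motherese"):
raised pitch, widened pitch range, altered timbre. `cdsvoice` implements an
analysis of whether those acoustics still track the child's age in late
childhood and adolescence. Each mother contributes nine short utterance
recordings (three nonsense words, `teebudishawlt` / `keebudishawlt` /
`peebudishawlt`, three takes each). Five acoustical features are extracted
per utterance, averaged per mother, and related to the child's age with a
battery of inferential procedures.

## Feature extraction

**Pitch (F0) tracking.** Frames are taken every 10 ms. Each frame uses a
Hann-tapered, mean-removed window of length `3/floor` seconds (40 ms at the
default 75 Hz floor) centred on the frame. The frame's normalized
autocorrelation is computed by FFT and divided by the Hann window's own
normalized autocorrelation, which undoes the taper's attenuation of long
lags (without this correction, peak heights at lags near a third of the
window drop below any sensible voicing threshold). Candidate lags span
`[1/ceiling, 1/floor]` (defaults 75–300 Hz). Local maxima are scored with a
mild penalty of 0.01 per octave of lag above the minimum lag, which breaks
the near-exact ties between a period and its integer multiples in favour of
the shorter lag; the best peak is refined by parabolic interpolation of the
three surrounding autocorrelation values. A frame is voiced when the
corrected, interpolated peak height reaches the voicing threshold
(default 0.45 — the value rejects white noise outright and accepts all
synthetic harmonic voices in the test suite; it is configurable). Frames
whose window would overrun a signal edge are unvoiced. Voiced F0 is
hard-limited to `[floor, ceiling]`.

This is a single-candidate-per-frame tracker: there is no cross-frame
Viterbi path search or octave-cost dynamic programming as in full-featured
speech analysis software. On the additive-harmonic signals used for
validation it recovers constant F0s within 0.1% and a 70 Hz/s glide within
3 Hz per frame; on natural speech it should be considered an approximation,
not a drop-in replacement for a production pitch tracker.

**Pitch summaries.** Pitch height is the arithmetic mean of voiced-frame
F0; pitch range is max − min; the 90th percentile uses linear interpolation
between order statistics (definitions of percentiles differ across
software, so this is stated explicitly); the first-500-ms mean uses voiced
frames with centre time < 0.5 s (half-open). An utterance with zero voiced
frames is an error, never silently zero — mirroring the manual exclusion of
defective takes in human-curated corpora. Two drop-off controls (the 90th
percentile and the first-500-ms mean) exist because natural utterances show
F0 declination toward the end; both summaries are insensitive to the tail
of the contour.

**Duration** is sample count over rate. **Amplitude** is root-mean-square
in full-scale units. **Brightness** is the spectral centroid
`sum(f * |S(f)|^p) / sum(|S(f)|^p)` of the whole utterance with `p = 2`
(power weighting, the conventional "centre of gravity") and the DC bin
excluded.

## Cohort inference

**Pearson inference.** `r` by the product-moment formula;
`t = r * sqrt(n-2) / sqrt(1-r^2)` against a t distribution with `n-2` df;
95% CI by Fisher z: `tanh(atanh(r) ± 1.96 / sqrt(n-3))`.

**Partial correlation** (pitch height vs child age controlling mother's
age): both variables are residualized on the covariate by OLS with
intercept and the residuals correlated; the t test uses `n-3` df and the
Fisher CI uses `1/sqrt(n-4)` (one covariate).

**Family-wise error correction** is Bonferroni, `min(1, m*p)` across the
five-feature family — with five features, a per-feature p of 0.007 adjusts
to exactly 0.035.

**Cross-validated prediction.** Mothers are assigned to 4 folds of
near-equal size under a balance constraint: a one-way ANOVA of the
predictor across folds and of the outcome across folds must both give
p > 0.50, and the random assignment is repeated until this holds (the
constraint check compares the ANOVA F against the precomputed F-median, a
cheap equivalent). Per repetition, a simple linear model fit on three folds
predicts the held-out fold; predictions are pooled across the four folds
and correlated with the observed outcomes, giving one r per repetition;
`r_obs_pred` is the arithmetic mean over 100 repetitions (a median
alternative is one line away; the mean is the default and is what the
acceptance checks use). Significance comes from a permutation null: each
of 1000 surrogates permutes the outcome and reruns the complete repeated
cross-validation, including fresh balanced fold assignments; the p-value is
the add-one estimator `(1 + #{r_surr >= r_obs}) / (1 + B)`, which can never
return 0. Monte-Carlo calibration at 99 surrogates, 20 repetitions and 100
replicates gives a type-I error of 0.05 at alpha = 0.05.

**Mixed models.** Because nine utterances per mother are dependent, each
feature is also modelled on the long table with a random intercept per
mother (REML). Standardized slopes come from refitting on z-scored outcome
and predictor (z across all rows). Slope inference uses the large-sample
Wald/normal approximation — a Satterthwaite-style denominator-df correction
is not available in the fitting backend; the approximation is recorded as
`df_method="wald-normal"` in every result, and at 50 mothers the difference
from a t reference is small. Singular or non-converged fits are flagged via
the `converged` field, not hidden. For brightness the model adds a
nonsense-word main effect and a word × age interaction (treatment coding):
the words' initial stop consonants /t/, /k/, /p/ differ in high-frequency
burst energy, which moves the spectral centroid directly.

**Regressions.** The simultaneous model regresses child age on all five
features at once (all variables z-scored, so coefficients are standardized
betas). The stepwise comparison fits child age ~ pitch height as the base
model (its F against the intercept-only model and adjusted R² are
reported), then adds one other feature at a time and reports the nested
F test and the change in adjusted R². Exactly collinear predictors raise an
error naming the pair.

**Subgroups and extrapolation.** Pearson inference is repeated within
child-sex groups and within the primary-English subgroup; groups under
n = 4 are reported as skipped. The adult-pitch extrapolation solves the
fitted line `pitch = a + b*age` for the age at which it reaches a reference
adult-directed pitch height (175 Hz); it requires a negative, non-trivial
slope and errors otherwise.

## Synthetic cohort generator

The generator is the package's test bed: it produces cohorts whose
statistical structure matches the regime the analysis targets, with exact
ground truth at every level.

**Cohort level.** Child ages are uniform on [7.72, 16.47] years. Mother age
and true per-mother pitch height are affine-plus-Gaussian responses to
child age, calibrated in closed form: for target correlation `r` and
marginal `(m, s)`, slope `= r*s/sd_age` and noise SD `= s*sqrt(1-r^2)` give
population correlation exactly `r` and marginal moments exactly `(m, s)`
regardless of the age distribution. Defaults: 50 mothers; pitch marginal
188.11 ± 18.20 Hz with pitch–age correlation −0.38; mother-age marginal
46.46 ± 7.35 y with mother–child age correlation 0.38; a brightness latent
correlated 0.34 with pitch height, mapped linearly to a spectral tilt of
9 ∓ 2 dB/octave (clipped to [2, 16]); 18/50 girls and 2/50 Spanish-speaking
mothers, matching the cohort composition the analysis assumes. Declination
(25 ± 5 Hz), duration (0.9 ± 0.08 s) and RMS (0.10 ± 0.02) are drawn
independently of age — they are the designed null features. The
take-to-take F0 scatter within a mother defaults to 8 Hz; no published
estimate of this quantity exists, so it is an explicitly free parameter.

**Utterance level.** Additive-harmonic synthesis: ten harmonics of a
time-varying F0 contour (flat for 70% of the utterance, then a linear
declination emulating the terminal pitch drop-off of natural utterances),
harmonic k attenuated by the tilt in dB per octave, per-10-ms-frame
Gaussian F0 jitter (2 Hz) interpolated to sample rate, 10 ms cosine fades,
exact scaling to the target RMS. The base F0 is offset by +0.15 ×
declination so the contour's time average equals the mother's true pitch.

**What the generator does not emulate.** No formants, no consonant
acoustics, no amplitude modulation, no recording-channel effects — the
three "words" differ only by label (an optional word-indexed tilt offset
exists for interaction power checks). Consequences worth knowing: the
spectral centroid of a harmonic comb scales with F0 for fixed tilt, so the
*extracted* brightness–pitch correlation in synthetic cohorts (~0.6) is
stronger than the configured latent coupling (0.34); and passing end-to-end
tests demonstrate that the pipeline recovers the statistical structure it
is pointed at, not that the feature extractor matches any particular
speech-analysis software on natural voices.

## Validation problem sizes

The heavy validation studies run at sizes chosen to make their Monte-Carlo
error small relative to the bands being checked while keeping the suite
fast to iterate on:

* CV/permutation calibration: 100 Monte-Carlo replicates × 99 surrogates ×
  20 repetitions, n = 50 (both a null regime and a true-correlation −0.38
  regime).
* End-to-end parameter recovery: 50 replicate cohorts of 50 mothers × 9
  utterances at the default cohort calibration, with audio rendered at
  22.05 kHz (the synthesis rate only affects audio fidelity, which the
  tracker's accuracy margin dwarfs; cohort statistics are unchanged). At
  the cohort's −0.38 effect size and n = 50 the design has roughly 80%
  power, and the pitch–age association is recovered as negative and
  significant in 88% of replicates; the three null features are
  non-significant in ≥ 92% each.
* `scripts/acceptance.py` synthesizes 20 replicate default cohorts and
  averages the recovered cohort statistics (one cohort's correlation has a
  sampling SD near 0.12, so the replicate mean — not any single draw — is
  the meaningful point estimate of the generative regime). The
  cross-validated prediction r is additionally computed on cohorts
  constructed to realize a sample correlation of exactly −0.38, with the
  permutation test at the standard 1000-surrogate setting. Note that the
  repeated-CV estimator is conservative by construction: even conditioned
  on a sample correlation of 0.38, out-of-fold prediction noise shrinks the
  expected observed–predicted correlation to about 0.30.

## Numerical and degenerate-input policy

* Numerically perfect correlations (|r| within 1e-15 of 1) return a
  degenerate CI at r and p = 0 rather than overflowing the Fisher
  transform.
* Zero-variance inputs, silent signals, unvoiced utterances, empty tables
  and clipping audio raise descriptive errors; nothing is silently clamped
  or imputed.
* Fold balancing gives up after a configurable number of tries (default
  10 000) and reports the best balance achieved.
* A mother missing a feature value simply drops out of the affected
  analysis when rows are incomplete; the aggregation warns whenever a
  mother has other than nine utterances.
* 16-bit WAV round-trips are exact to one quantization step (2^-15) for
  samples of magnitude ≤ 1 − 2^-15; writing samples above full scale is an
  error.

## Known limitations

* The pitch tracker has no octave-error recovery across frames; extreme
  jitter or strong subharmonics could produce halving/doubling that a
  path-search tracker would fix.
* Mixed-model p-values are asymptotic (see above); with few mothers they
  are mildly anti-conservative.
* The permutation test reruns the fold-balance constraint on permuted
  outcomes (the surrogate distribution is therefore exchangeable with the
  observed statistic); this is the assumed-correct design but makes 1000
  surrogates the dominant cost of a full run.
* The brightness model's treatment coding makes individual word
  coefficients reference-dependent; fitted values and the age effect are
  not.
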