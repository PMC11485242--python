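# Methods notes

This note documents the models, estimators and numerical choices behind
`chronolfp`, and what the synthetic cohort generator does and does not
emulate.

## Data model and conditioning

The unit of analysis is a chronic stream of band-amplitude values (µVp) in
a 5-Hz-wide band centred at 8.79 Hz, logged every 10 minutes by an
implanted sensing DBS device — 144 samples per local calendar day.
Timestamps arrive in UTC and are shifted to local clock time by a fixed
per-patient offset (no daylight-saving unfolding; devices in the emulated
export format timestamp in UTC).

Conditioning operates per *chunk* — a maximal run of consecutive
non-missing samples at nominal spacing:

* **Outliers.** A sample is an outlier when its value exceeds
  `median + 30·SD` of its own chunk.  The rule is one-sided: amplitudes
  are non-negative and the artefacts being targeted are large positive
  transients; a `two_sided` flag enables the symmetric rule.  Outliers are
  replaced by PCHIP (shape-preserving piecewise-cubic) interpolation
  through the neighbouring non-outlier samples.  Because the chunk SD is
  computed with the spike included, a spike can only trip the rule if the
  chunk is long enough that one sample cannot dominate the SD — a property
  the tests construct for explicitly.
* **Gaps.** Missing runs of at most six samples (1 h) are filled with the
  same interpolant; longer runs and edge gaps stay NaN.  Chunks shorter
  than four samples are left untouched (a cubic needs support).

Days are binned on the 144-bin local-clock grid (bin `b` covers
`[10·b, 10·(b+1))` minutes; day indices are relative to the local calendar
date of DBS activation, activation day = day 0) and z-scored per day with
the day's own mean and SD.  A day needs at least 72 non-missing bins
(half a day) to be usable — the daily z-score is unstable below that — and
constant days become all-missing.  This per-day normalisation removes slow
baseline drift and stimulation-amplitude steps by construction.

The Welch PSD helper (1-s Hamming window, 600-ms overlap, 256-point FFT at
250 Hz, output in dB) exists to verify band selection on raw time-domain
snippets and for tests; the chronic stream itself is already band power.

## The four daily measures

All four are computed within clinical states (pre-DBS severe symptoms,
post-DBS clinical response, post-DBS persistent symptoms), using the same
cross-validation scheme: the state's 10-min timepoints in chronological
order are split into five **contiguous, unshuffled** folds.  Contiguity
matters — the stream is strongly autocorrelated, and shuffled folds would
leak neighbouring samples between train and test.  Held-out predictions
from the five fits are pooled; per-fold R² values average into the state
mean, and held-out predictions grouped by day give one R² per day
(Eq. `R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²`; a day needs ≥ 36 held-out points).
In-sample OLS R² is non-negative by construction; held-out R² has no floor
and is legitimately negative for unpredictable data.

**Cosinor.**  OLS on the design `[1, sin(2πjt/24), cos(2πjt/24)]` for
harmonics `j = 1..N`, with the period fixed at exactly 24 h.  Default
`N = 2`; an optional heuristic sets N per patient as the count of peaks
with prominence > 0.25 z in the mean daily profile (capped at 3).  The
reported amplitude and acrophase belong to the primary (largest-amplitude)
harmonic; its significance is an F-test dropping that harmonic's
sine/cosine pair.  Rotated ("circularized") days shift the acrophase bin
to angular position 3π/2 (bin 108) and apply a circular Gaussian blur
(SD 3 bins = 30 min — small enough to keep ultradian spikes, large enough
to suppress bin noise); only days with a significant acrophase (p < 0.05)
are rotated and averaged.

**Linear autoregression.**  Candidate lags 1..144 (one day).  Selection
runs on the patient's *entire* z-scored series, before any per-state
fitting: one OLS per disjoint contiguous fold identifies lags with
coefficient p < 0.05; lags significant in ≥ 4 of 5 folds are kept; the
surviving set is refitted on the full series and all non-significant lags
are dropped simultaneously, repeating until every remaining lag is
significant (possibly leaving an empty set, in which case the metric
degrades to the intercept-only held-out R², ≤ 0, and says so loudly).
Fitting each fold on its own disjoint block is deliberate: the five
p-values are then nearly independent, so the 4-of-5 consensus suppresses
chance significances almost completely (white-noise false-discovery is
~0 per 144 candidates in simulation), while a shared-training-data variant
leaves the fold decisions correlated and lets false positives through.
A HAC-covariance refit is available behind a flag; it changes standard
errors only — predictions are identical to the OLS fit.

**Nonlinear autoregression.**  A single-hidden-layer network
(144 lagged inputs → 32 ReLU units → 1), trained for 50 epochs with Adam
(lr 0.001), mean-absolute-error loss and an L1 penalty of 1e-5 on weights
(not biases).  Training uses mini-batches of 128 rows with a
deterministic per-epoch shuffle: with full-batch steps, 50 Adam updates at
lr 0.001 move each weight by at most ~0.05 from a ±0.08 initialisation and
the network cannot reach the data; mini-batching provides the needed
update count at the stated epoch budget.  Initialisation is uniform
fan-in (U(±1/√fan_in)) from a fixed seed; per fold, the epoch with the
best held-out R² supplies that fold's predictions.  Everything is
bit-reproducible for a given seed.

**Sample entropy.**  `−ln(A/B)` with `B` the number of unique pairs of
distinct length-m windows at Manhattan distance strictly below r, and `A`
the same for length-(m+1); defaults m = 2, r = 3.6 z-units, τ = 1,
computed on single z-scored days.  All length-m windows (N−m+1 of them)
enter B; the common alternative restricts both counts to N−m templates —
the difference is one window and immaterial at r = 3.6, but the convention
is fixed and the exhaustive-enumeration oracle in the tests uses the same
one.  Days with internal missing bins are compacted (windows may span a
dropped bin); `A = 0` returns +∞ with a warning and the daily series
records it as missing.  The measure is translation-invariant but *not*
scale-invariant (r is fixed) — both properties are asserted by tests.

## Effective sample size and state comparisons

Daily metric series are autocorrelated, so comparisons use the effective
sample size `N_eff = N / (1 + 2 Σ_{k=1..m} ρ_k)` with m = min(10, N−1)
days.  Two standard refinements to the plain biased-ACF plug-in are on by
default, both disableable:

* the lag sum stops at the first non-positive sample autocorrelation
  (the initial-positive-sequence rule familiar from Markov-chain ESS
  estimation), which removes the noise contributed by high-lag terms of
  weakly correlated series; and
* the first-order downward bias of the sample ACF caused by mean
  estimation, `E[ρ̂_k] ≈ ρ_k − (1 + 2Σρ)/N`, is removed in closed form:
  `Σ_c = (Σ̂ + K/N) / (1 − 2K/N)` for K summed lags.

Without them the estimator overshoots the true-autocorrelation plug-in by
~25% for an AR(1) daily series with φ = 0.7 at N = 200; with them it is
within ~3% there and within 10% for i.i.d. data (measured over hundreds of
seeds).  `N_eff` is rounded to the nearest integer and clamped to [2, N]:
it may not exceed the raw count, and a floor of 2 keeps the downstream
tests defined.

Welch's t and Hedges' g then use `N_eff` in the standard-error,
Welch–Satterthwaite df, pooled-SD and small-sample-correction formulas,
while means and variances always come from the full samples.  All
comparisons are reported as the change from the first state to the second
(post − pre), matching the delta convention (daily value minus pre-DBS
state mean).  Cross-patient pooled comparisons concatenate daily values by
the burdened/unburdened dichotomy and sum the per-patient `N_eff` per
group.  Hedges-g confidence intervals use the normal approximation with
variance `(n1+n2)/(n1·n2) + g²/(2(n1+n2−2))`.  No multiple-comparison
correction is applied — comparisons are reported per hemisphere and per
metric as individual tests.

## Classifier

One feature (a metric's daily or delta value), logistic regression with
intercept, no penalty, fitted by Newton/IRLS to tolerance 1e-8.  Row
weights balance the two classes within every patient —
`w = n_p / (2·n_{p,class})` — so long-recording patients' majority class
cannot dominate; duplicating one class's rows within a patient provably
leaves the fit unchanged.  On separable data the ML coefficients diverge;
they are capped (rankings and AUROC are unaffected).  Evaluation is
leave-one-patient-out with pooled held-out probabilities; AUROC gives half
credit to ties (equals the Mann–Whitney statistic), and balanced accuracy
uses a fixed probability threshold of 0.5.

Permutation nulls rerun the full LOPO pipeline per draw: `random`
shuffles labels globally; `circular` rotates each patient's day-ordered
label sequence by a uniform offset (0 allowed — conservative), preserving
label contiguity.  p = #(null > observed)/n_perm, so an exact 0 means
"below 1/n_perm".  DeLong's test compares two feature sets' AUROCs on
identical rows via the structural-components covariance.

A flip symmetry worth knowing: for *fixed* scores, inverting labels maps
AUROC to 1 − AUROC; for the *retrained* LOPO classifier, flipping the
labels exactly negates the ML logistic coefficients, so the pooled AUROC
is flip-invariant.  Tests assert both.

## Synthetic cohort generator

Each simulated patient-hemisphere stream is the sum of a multicomponent
circadian rhythm (`mesor + Σ_j amp_j·cos(2πjt/24 − φ_j)`), an
autoregressive noise process generated in z-units and scaled by
`noise_sd`, and a linear baseline drift — an additive decomposition
mirroring the cosinor model's residual structure.  Defaults: mesor 50 µVp,
amplitudes (20, 8) µVp, AR(2) coefficients (0.55, 0.2), noise SD 6 µVp,
drift 0.1 µVp/day, 30 pre-DBS + 90 post-DBS days.  These were chosen so
the pre-DBS state shows strong rhythmicity (cross-validated cosinor R²
≈ 0.75) and predictability (linear-AR R² ≈ 0.85), comparable to what the
severe-symptom state exhibits in chronic OCD recordings.  At DBS
activation — aligned to local midnight, since all metrics are daily — a
responder's circadian amplitudes shrink (×0.25) and noise grows (×1.5);
non-responders are unchanged.  Artefacts: Poisson-rate short gaps with
geometric lengths, one always-injected long gap (> 6 samples, exercising
the NaN path), and rare outliers at 35 SD above the global median (above
the 30-SD conditioning threshold by construction).  Y-BOCS trajectories
draw reductions of 45–75% (responders) or 0–20% (non-responders),
consistent with the ≥ 35% criterion after rounding.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: ultradian spectral structure beyond the
configured harmonics (real responder data shows "stellate" dispersion that
is only approximated here by increased noise SD), acute
stimulation-induced disinhibition episodes, daylight-saving clock shifts
(optional flag territory), device-specific artefact shapes, and any
hemispheric asymmetries beyond independent noise draws.  The classifier's
high AUROC on synthetic deltas reflects the configured effect sizes, not a
claim about clinical performance.

## Degenerate inputs and tie-breaking

Duplicate samples in a daily bin keep the later one (device re-exports
overwrite).  Duplicate session timestamps with equal values collapse;
conflicting values are an error.  Constant days z-score to all-missing.
A state with too few points for its model is skipped with a warning, never
silently.  Empty lag set → intercept-only metric.  Acrophase of a
multi-harmonic fit belongs to the primary harmonic and is reported in
[0, 24) hours; rotation maps its bin with round-half-away behaviour.

## Problem sizes

The default test and acceptance configurations use an 8-patient cohort
(4 responders) with 30 + 90 days per patient and analyse the left
hemisphere, with 1000-draw permutation nulls and Monte-Carlo loops of
20–500 seeds per property; these sizes give stable pass/fail behaviour for
every asserted contrast while keeping a full run in the low minutes on one
CPU.
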