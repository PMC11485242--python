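# chronolfp

Circadian periodicity and predictability analysis of chronic intracranial
LFP band-power streams from sensing deep-brain-stimulation (DBS) implants.

## The problem

Sensing DBS devices log the average local field potential (LFP) amplitude
in a configured frequency band — here the theta/alpha border, 8.79 ± 2.5 Hz
("9 Hz") in ventral striatum — every 10 minutes (144 samples per day), for
months at a time.  In obsessive-compulsive disorder (OCD) DBS cohorts,
these streams show a strong circadian pattern before stimulation begins;
in patients who go on to respond clinically (≥ 35% Y-BOCS reduction) that
pattern weakens and the signal becomes less predictable, while in
non-responders it persists.  `chronolfp` implements the full analysis
chain that quantifies this and turns it into a day-level classifier of
clinical state, plus a synthetic cohort generator so every stage is
testable without patient data.

## What it computes

For each patient-hemisphere stream, after conditioning (outliers above
30 SD over the chunk median replaced by PCHIP interpolation, gaps ≤ 1 h
filled, daily z-scoring on the 144-bin local-clock grid), four daily
measures:

* **Cosinor R²** — fit of the multicomponent cosinor model
  `y(t) = M + Σ_j [A_{j,1} sin(2πjt/P) + A_{j,2} cos(2πjt/P)] + e(t)`
  with P = 24 h, scored by held-out R² from five-fold cross-validation
  within each clinical state.
* **Linear autoregressive R²** — `X_t = c + Σ_k φ_k X_{t−k} + ε_t` with
  lags up to one day (144), selected by a cross-validated significance
  consensus with iterative pruning, same CV scheme.
* **Nonlinear autoregressive R²** — a 144→32→1 ReLU network trained with
  Adam (lr 0.001, MAE loss, L1 1e-5, 50 epochs, best epoch by test R²).
* **Sample entropy** — `−ln(A/B)` over single z-scored days with m = 2,
  r = 3.6, τ = 1 (Manhattan distance).

State comparisons use Welch's t and Hedges' g at the effective sample size
`N_eff = N / (1 + 2 Σ_{k≤10} ρ_k)`, which discounts the daily series'
autocorrelation.  A leave-one-patient-out logistic classifier predicts
symptom-burdened vs. unburdened days from each measure (daily values or
deltas from the pre-DBS mean), with chance levels from random-shuffle and
circular-shift permutation nulls and DeLong tests between feature sets.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from chronolfp import PatientSimParams, ArtifactSpec, simulate_patient, compare_states
from chronolfp.pipeline import analyze_hemisphere

params = PatientSimParams(patient_id="demo", responder=True)
bundle = simulate_patient(params, ArtifactSpec(), seed=42)
result = analyze_hemisphere(bundle.series["L"], bundle.trajectory,
                            include_nonlinear=False)

for metric, means in result.state_means.items():
    print(metric, {s: round(v, 3) for s, v in means.items()})

daily_ar = result.daily[result.daily["metric"] == "linear_ar_r2"]
cmp = compare_states(daily_ar, "severe_symptoms_preDBS", "clinical_response",
                     corrected=True)
print(f"linear AR change: g={cmp.hedges_g:.2f}, t={cmp.t:.2f}, "
      f"p={cmp.p:.2e}, Neff={cmp.neff1}+{cmp.neff2} (N={cmp.n1}+{cmp.n2})")
```

prints

```
cosinor_r2 {'severe_symptoms_preDBS': 0.75, 'clinical_response': 0.059}
linear_ar_r2 {'severe_symptoms_preDBS': 0.815, 'clinical_response': 0.454}
sample_entropy {'clinical_response': 0.295, 'severe_symptoms_preDBS': 0.264}
linear AR change: g=-1.99, t=-7.78, p=2.27e-09, Neff=30+90 (N=30+90)
```

Read: before DBS this simulated responder's 9-Hz stream is strongly
rhythmic (cross-validated cosinor R² 0.75) and predictable (linear-AR R²
0.82); after DBS activation both collapse (0.06 and 0.45), sample entropy
rises, and the drop in daily AR predictability is a large, significant
effect (Hedges g ≈ −2) even after the autocorrelation-aware sample-size
correction.

A command-line interface wraps the same pipeline:

```bash
chronolfp all --seed 0 --out run0 --n-perm 1000 --hemisphere L
```

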