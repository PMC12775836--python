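# gammarep

Repetition-related plasticity of visual gamma oscillations, as measured by
MEG, implemented as a tested end-to-end pipeline with a synthetic cohort
generator.

## The scientific problem

High-contrast moving gratings drive narrow-band gamma oscillations
(35–100 Hz) in early visual cortex.  When the same stimulus is repeated
hundreds of times, the induced gamma response (GR) follows a biphasic
course: a rapid decrease over the first ~10–15 trials (habituation,
time constant τ) followed by a slow, near-linear increase over the next
~100 trials that is thought to reflect Hebbian plasticity.  In visual
snow syndrome (VSS) — a disorder marked by persistent "TV-static"
visual disturbance — this late increase is steeper than in controls,
suggesting heightened activity-dependent plasticity, and the steepness
correlates with the parasympathetic contribution to autonomic balance
(HFnu from heart-rate variability).

The package implements the full measurement chain for users who want to
reproduce, stress-test or extend this analysis:

* **`gammarep.synthetic`** — cohort generator: multi-sensor trial epochs
  (1/f noise + evoked transient + calibrated narrow-band gamma bursts) or
  single-trial relative spectra, plus ECG with controlled HF/LF balance.
  The trial law is the generative inverse of the fitted model:
  `P(n,c) = base · tuning(c) · gain · (1 + A·e^(−n/τ) + β·n/100)`.
* **`gammarep.spectral`** — evoked subtraction, multitaper TFR (10 Hz
  bandwidth, 2.5 Hz grid, 2 ms step), baseline normalization
  `(stim−base)/base·100%`, 80%-of-max posterior sensor selection (1–4
  sensors), and the 2/3-peak GR power / centre-of-gravity frequency.
* **`gammarep.dynamics`** — single-trial GR in ±15 Hz around the
  condition peak, IQR exclusion (k = 2), z-scoring per
  subject × condition, grand-average trial course, the dual-process model
  `y = A·exp(−n/τ) + B·n + C`, the broken-line (segmented) model for the
  inflection point ψ, and per-subject plasticity slopes (trials 15–137).
* **`gammarep.hrv`** — R-peak detection (moving-average envelope), R-R
  artifact correction, BPM/SDNN/RMSSD, Welch LF/HF powers and
  `HFnu = HF/(HF+LF)·100`.
* **`gammarep.stats`** — trial-level mixed models
  `GR_power ~ trialN*group + (1+trialN|subject) + (1+trialN|condition)`
  with Satterthwaite dfs (lme4/lmerTest via Rscript), mixed ANOVA with
  Greenhouse–Geisser correction and ηp², Mann–Whitney Z with r = Z/√N,
  Spearman correlations, summary-statistic t-tests, and noncentral-t/F
  power and sensitivity calculators.
* **`gammarep.pipeline` / `gammarep` CLI** — reproducible, seeded,
  manifest-logged end-to-end runs.

## Worked example

Simulate a 53-subject cohort under the study conditions and run the whole
chain:

```bash
gammarep all --seed 1 --out run1
```

prints (abridged):

```json
{
  "stages": {"simulate": "ok", "spectral": "ok", "dynamics": "ok",
             "hrv": "ok", "stats": "ok"},
  "headline": {
    "tau": 8.13,
    "psi": 15.46,
    "r2_adj": 0.93,
    "vss_slope_per100": 0.368,
    "control_slope_per100": 0.225
  }
}
```

Reading this: the grand-average z-scored GR power course decays with a
time constant of ≈8 trials before rising linearly (generator truth
τ = 7.8); the broken-line inflection sits at ≈15 trials; and the mixed
model estimates that relative GR power grows by ≈0.37 ratio units per
100 trials in the VSS group versus ≈0.23 in controls (generator truth
0.45 and 0.19 — the gap between fitted and generative slopes is the
exponential tail inside the 15–137 window, see `docs/methods.md`).
`run1/` now holds the truth table, GR table, single-trial table, fits,
HRV table, a statistics report and a manifest; re-running with the same
seed reproduces every table byte for byte.

The library surface mirrors the CLI:

```python
from gammarep import (GeneratorConfig, simulate_cohort, single_trial_table,
                      grand_average_course, fit_dual_process)
cohort = simulate_cohort(GeneratorConfig(), mode="spectra", seed=1)
table = single_trial_table(cohort)
course = grand_average_course(table)
fit = fit_dual_process(course["trialN"], course["z_mean"])
print(fit.tau, fit.r2_adj)      # 8.13... 0.93...
```

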