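# phqtraj

Temporal correlation and subtype discovery for sparse longitudinal
depression questionnaire records.

Depression severity and suicidal ideation are tracked in routine care with
the PHQ-9: items 1–8 sum to the **PHQ-8** severity score (0–24), while
**Item 9** (0–3) asks about thoughts of self-harm.  A long-standing clinical
concern is that ideation may *rise* while overall severity improves.
`phqtraj` implements a trajectory pipeline for that question on irregular,
sparse longitudinal records, for biostatisticians and mental-health services
researchers:

1. **Continuization** — each patient's irregular PHQ-8 and Item-9 series is
   turned into a continuous curve by Gaussian-process regression
   (squared-exponential kernel + white noise, hyperparameters by grid search
   on the mean marginal likelihood) and sampled on a biweekly grid of
   M = 20 points;
2. **Lead/lag analysis** — the sample cross-correlation function
   ρ̂_xy(k) = γ̂_xy(k)/(σ̂_x σ̂_y), with
   γ̂_xy(k) = (1/(N−k)) Σ_{t=1}^{N−k} (x_{t+k} − x̄)(y_t − ȳ) for k ≥ 0,
   over lags k ∈ [−5, 5] biweeks; the lag at maximum CCF summarises whether
   ideation and severity move in synchrony (k = 0) or one leads the other;
3. **Raw-score change patterns** — Spearman/OLS association of short-term
   (≤ 1 month) and anchor-based (3/6/9-month) changes, and the partition of
   patients by opposite-direction patterns: (a) severity up ≥ d while
   ideation down, (b) severity down ≥ d while ideation up, d ∈ {2, 3, 4};
4. **Subtype discovery** — a tied-weight autoencoder
   (h = u(Wm + b), m̂ = Wᵀh + b′, H = 25 latent basis trajectories) trained
   by SGD on normalised curves, followed by t-SNE embedding of the
   activations and k-means clustering with the cluster count chosen at the
   inertia knee.

Because EHR extracts of this kind are access restricted, the package
includes a first-class synthetic-cohort generator (`phqtraj.cohort`) with
five latent trajectory classes, irregular visits, ordinal observation
noise, zero-inflated Item 9 and a *plantable* Item-9 lead/lag — every
analysis stage can be validated against known ground truth.  See
`docs/methods.md` for the full model and design rationale.

## Worked example

```python
from phqtraj import (SimConfig, generate_cohort, sample_ccf,
                     population_lag_summary)
from phqtraj.cohort import LAG_STUDY_CLASS_MIX
from phqtraj.gpr import (default_settings, fit_cohort,
                         grid_search_hyperparams, patient_series)

# 100 patients; Item 9 planted to lead PHQ-8 by 2 biweeks
cfg = SimConfig(n_patients=100, lag_biweeks=2, noise_sd=0.2,
                item9_zero_prob=0.2, class_mix=LAG_STUDY_CLASS_MIX, seed=3)
visits, demographics, truth = generate_cohort(cfg)

fitted = {}
for measure in ("phq8", "item9"):
    series = patient_series(visits, measure)
    hp = grid_search_hyperparams(series, default_settings(measure))
    fitted[measure] = {t.patient_id: t for t in fit_cohort(visits, measure, hp)}

profiles = [sample_ccf(fitted["phq8"][p].mean, fitted["item9"][p].mean,
                       patient_id=p) for p in fitted["phq8"]]
s = population_lag_summary(profiles)
print(s["n_total"], s["n_degenerate"], max(s["histogram"], key=s["histogram"].get))
```

prints

```
100 16 2
```

— of 100 patients, 16 are ideation non-reporters whose flat Item-9 curves
give an identically-zero CCF (degenerate, excluded), and the modal lag at
maximum CCF among the rest is +2 biweeks: the analysis recovers the planted
four-week ideation lead.

The same flow is available from the shell:

```bash
phqtraj run-all --seed 11 --out run/        # simulate -> ... -> subtypes
phqtraj simulate --seed 3 --out run/        # or stage by stage
```

`run-all` writes per-stage CSV tables plus `manifest.json`; the same
configuration and seed reproduce the manifest hash bit-for-bit.

The repository's own study is the numbered scripts under `analysis/`
(simulate → fit → lag analysis → change patterns → subtype discovery); each
prints what it finds and writes its tables under `results/pipeline/`.  On
the default 300-patient cohort they report, among other things, 44% of
non-degenerate patients in synchrony (lag 0), strongly positive long-term
change associations (Spearman ≈ 0.36–0.62), a mutually exclusive
four-subgroup pattern partition, and five recovered trajectory subtypes
(adjusted Rand 0.99 against the generating classes, K = 5 chosen by the
inertia knee).

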