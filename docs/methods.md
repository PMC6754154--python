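# Methods

`phqtraj` analyses the temporal relationship between overall depression
severity (PHQ-8: the sum of the first eight PHQ-9 items, 0–24) and suicidal
ideation (Item 9, 0–3) in sparse, irregular longitudinal questionnaire
records, and discovers trajectory subtypes.  Real EHR extracts of this kind
are access restricted, so the pipeline ships with a synthetic-cohort
generator that reproduces the statistical structure every stage assumes and
provides a ground truth against which recovery can be scored exactly.  This
note records the models, the parameter choices that matter, and the places
where design was genuinely open.

## Synthetic cohort model

Each patient carries a latent PHQ-8 severity curve `f(t)` (total scale,
weeks), drawn from one of five trajectory classes:

| class | form | parameters (uniform draws) |
|---|---|---|
| increasing | `base + amp · σ((t−t0)/s)` | base 2–6, amp 8–14, t0 16–24 w, s 2–4 w |
| decreasing | mirrored logistic | same |
| peak-then-decline | `base + amp · exp(−(t−t0)²/2w²)` | width 4–7 w |
| periodic | `level + amp · sin(2π(t−φ)/P)` | level 8–14, amp 4–7, P 22–30 w, φ 0–6 w |
| stable | `level − amp · cos(2π(t−φ)/80)` | level 6–16, amp 1.5–2.5, φ 16–24 w |

Curves are defined on all of ℝ (no edge handling when time-shifted) and stay
inside 0–24 by construction.  Within-class parameter jitter is moderate
relative to between-class shape differences: that is what makes the classes
*subtypes* a clustering stage can be scored against.  The stable class is a
shallow mid-window sag (≈2 points over 40 weeks — clinically "relatively
stable"); it is oriented as a dip so that, after per-patient normalisation,
it is not a broadened copy of the peak class.

**Item-9 latent and the planted lead/lag.**  The ideation curve is
`g(t) = clip(f(t + 14·L days)/8, 0, 3)` for a planted lag of `L` biweeks.
With the cross-correlation convention below (x = PHQ-8, y = Item 9),
positive `L` means ideation *leads* severity.  With probability
`item9_zero_prob` (default 0.3) a patient is an *ideation non-reporter*:
their whole Item-9 curve is masked to zero and their answers are structural
zeros.  This is the dominant form of zero inflation in this kind of data —
a large minority of patients never endorse the ideation item — and it is
what surfaces downstream as degenerate (identically flat) CCF profiles that
lag summaries exclude.  We deliberately do not mask individual time points:
pointwise masking at rate 0.2 destroys the lag information of the latent
curves themselves (recovery within ±1 biweek falls to ~79% before any noise
or fitting), whereas whole-patient masking leaves unmasked patients intact
and masked patients cleanly excluded.

**Visits and observation noise.**  Inter-visit gaps are discretised gamma
(mean 2.5 weeks, dispersion 0.5 — the questionnaire's own two-week
reporting window in a frequently monitored treatment population, which is
also the cadence a biweekly continuization grid presumes); schedules with
fewer than `min_visits` (default 6) draws inside the 40-week horizon are
redrawn.  Observed scores add Gaussian noise (sd `noise_sd`, default 0.5, in
the units of the reported scale) and are rounded and clipped to the legal
ordinal range; the PHQ-8 total is spread deterministically over items 1–8.
Demographics (age band, sex, race/ethnicity, Charlson band) are drawn
independently of trajectory class, so partition-homogeneity tests have a
true null.

What the generator does *not* emulate: informative visit timing (sicker
patients visiting more often), treatment effects, item-level response
patterns, and measurement error that depends on severity.  Passing tests
therefore demonstrate that the estimators recover known structure under
realistic sparsity, ordinal coarseness and zero inflation — not that any
particular clinical finding generalises.

## Gaussian-process continuization

Each patient × measure series is fitted with GP regression (squared
-exponential kernel plus i.i.d. Gaussian noise) and read off on the 20-point
biweekly grid (weeks 0–38, anchored at the patient's first visit).  The
prior mean is the patient's own observation mean: data are centered before
fitting and the mean added back.  Two consequences we rely on: a constant
observation series returns an *exactly* constant posterior (so flat-Item-9
patients become exactly degenerate CCF profiles, no numeric tolerance
needed), and posterior means revert to the patient mean, not to zero, in
gaps.  Posterior means are clipped to the legal score range.

Hyperparameters are chosen per measure by grid search maximising the mean
per-patient marginal log-likelihood.  Grids: length-scale {2, 4, 8, 16, 32}
weeks for both measures; signal variance {4, 9, 16, 36} (PHQ-8, total²) or
{0.25, 0.5, 1, 2} (Item 9); noise variance {0.25, 1, 4} or {0.05, 0.1,
0.25, 0.5}.  Constant series are excluded from the search (their likelihood
is maximised by the smallest total variance regardless of smoothness, so
all-zero Item-9 series would drag the selection to the grid floor), and the
search may be capped at the first 40 patients in sorted order: the
hyperparameters are population-level and the mean log-likelihood stabilises
with a few dozen series.

## Cross-correlation and lag-at-maximum

The sample cross-covariance at lag `k ≥ 0` is
`γ̂(k) = (1/(N−k)) Σ_{t=1}^{N−k} (x_{t+k}−x̄)(y_t−ȳ)` (mirrored for
`k < 0`), with full-series means; the CCF is `ρ̂(k) = γ̂(k)/(σ̂_x σ̂_y)`
with 1/N-convention deviations, so `ρ̂(0) = 1` for identical series.
Because γ̂ divides by `N−|k|` while σ̂ divides by `N`, `|ρ̂(k)|` is bounded
by `N/(N−|k|)` (4/3 at N=20, |k|=5), not by 1, and trending series do
exceed 1 at large lags — this is a property of the estimator as defined,
kept deliberately.  The lag window is −5..+5 biweeks; argmax ties break to
the smallest |k|, then to the negative lag (ties essentially never occur on
real-valued fits; the rule exists for reproducibility).  A profile is
degenerate when either fitted series has zero sample deviation (then
`ρ̂ ≡ 0` and the lag is undefined); population summaries count lags over
non-degenerate profiles only.

**A known identifiability limit.**  On a 20-point window this estimator
cannot locate the displacement of a monotone trend: a shifted ramp is nearly
the same ramp, the informative extremes sit at the window edges that the
truncated sums cut, and the argmax shrinks toward zero (planted ±3 recovered
as ∓1…0; `analysis/03_lag_analysis.py` prints the demonstration).  Lag-
planting experiments therefore draw from the peak-then-decline and periodic
classes (`LAG_STUDY_CLASS_MIX`), whose localized/oscillatory features make
the lag exactly identifiable in the noiseless limit; monotone classes remain
in the default mix for subtype analyses, where only shape matters.  This is
also a substantive caveat for interpreting lag histograms on real data.

## Raw-score change analyses

Short-term pairs are per-week rates of change between consecutive
observations at most one month (30.44 days) apart; long-term pairs are the
change of the windowed mean around month t ∈ {3, 6, 9} (± 0.5 months)
relative to the first observation.  Association = Spearman rank correlation
(average ranks, large-sample p) plus OLS of the Item-9 change on the PHQ-8
change, pooled across patients; PHQ-8 enters association analyses as the
per-item average (total/8) so both measures share the 0–3 scale.  In the
generator, short-term rates are dominated by ordinal rounding (latent curves
move little within a month), so the short-term coefficient is small though
reliably positive; anchor-based coefficients are substantially larger.

Pattern rules use the 0–24 total: on any consecutive pair, pattern (a) fires
when ΔPHQ-8 ≥ d and ΔItem-9 ≤ −1, pattern (b) when ΔPHQ-8 ≤ −d and
ΔItem-9 ≥ +1, for d ∈ {2, 3, 4}; a patient's subgroup (a-only / b-only /
both / none) is determined by which patterns fired anywhere in their series.
No gap cap is applied to pattern pairs by default (configurable).  The
partition is computed over patients whose raw Item-9 series is not all
zeros.  Homogeneity across demographic strata uses the Pearson chi-square
statistic with expected counts from the marginals; empty subgroup rows or
unused categories are dropped before testing (a zero marginal makes the
statistic undefined) and a flag marks tables with any expected cell < 5.

## Autoencoder and subtype clustering

Fitted curves are normalised per patient across the 20 time points (zero
mean, unit variance): clustering is shape-focused, level and amplitude are
removed.  The alternative axis (per time point across patients) is
implemented but not default.  Constant fitted curves are excluded (no shape
to normalise).

The autoencoder is tied-weight by construction: only `W` (H×M) is stored,
the encoder is `h = u(Wm + b)` with logistic-sigmoid `u` (tanh and identity
available) and the decoder is `m̂ = Wᵀh + b′`, so the tie cannot drift.
Rows of `W` are the learned basis trajectories; `h` is the patient's
activation vector.  Training minimises reconstruction MSE plus L2 weight
decay (1e-4) by minibatch SGD (rate 0.01, batch 32, 500 epochs, seeded
shuffling; weights initialised N(0, √(2/(H+M)))).  Latent size defaults to
H = 25; 5-fold cross-validation (equal-size folds, each used once for
validation) reports the capacity curve.

Activations are embedded with t-SNE (2-D, perplexity 30 — reduced to
(n−1)/3 for small cohorts — PCA initialisation, 1000 iterations, fixed
seed) and clustered with k-means (10 restarts) in the embedding.  When K is
not fixed it is chosen from the inertia curve over K = 2..10 by the knee:
both axes rescaled to [0, 1], K at maximum perpendicular distance from the
line joining the endpoints (a reproducible stand-in for eyeballing the
elbow).  The inertia curve is made non-increasing constructively: if the
restarts at K+1 land above the K solution, one extra Lloyd run is seeded
with the K centers plus the worst-fit point, which can only lower the
objective.  Validation summaries are the cluster-reordered activation
matrix (stable within cluster) and per-cluster pointwise mean trajectories
of both measures (PHQ-8 as per-item average).

## Reproducibility and problem sizes

A single global seed deterministically derives per-stage seeds
(`numpy` SeedSequence); identical configuration and seed reproduce every
output table and the manifest hash bit-for-bit (t-SNE, k-means, GP fits and
SGD are all explicitly seeded).  The bundled analyses and the acceptance
script run at desk scale by choice: 200–300-patient cohorts (the scale of
the emulated study), 100–200 patients per planted-lag cell, 50 seeded
replicates for GP recovery, 5 seeds for subtype recovery.  All validation
quantities are recomputed from scratch on each run.

## Known limitations

* The CCF lag is unidentifiable for monotone trajectories on short windows
  (above); lag histograms should be read as conditional on temporally
  structured trajectories.
* Item 9 is ordinal with four levels; GP regression treats it as Gaussian.
  For near-flat ideation series the fitted curve is driven by rounding
  noise — such patients are excluded via degeneracy, but patients with a
  single nonzero report remain and their lags are unreliable.
* The generator's Item-9 curve is a deterministic transform of the PHQ-8
  curve; real ideation has independent dynamics.  Recovery results bound
  what the estimators can do under the model, not what real data will show.
* The autoencoder is a single hidden layer with a fixed nonlinearity;
  training is plain SGD and converges to different (equally good) bases per
  seed — downstream clustering, not the bases themselves, is the stable
  output.
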