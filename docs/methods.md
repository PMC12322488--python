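# Methods

This note documents the models, numerical choices and known limitations of
`titplayback`. It is the authoritative description of what the package
computes; no number quoted here is asserted anywhere the tests or the
acceptance script do not themselves recompute.

## Ethogram reduction and the aggression index

A trial is a 60 s pre-playback window plus a 480 s response window (4 min of
broadcast, 4 min of post-broadcast observation) sampled every second. The
pre-window only records whether the male was already singing; all four
aggression variables are computed on the response window:

* `min_distance` — minimum observed distance to the speaker (m);
* `mean_distance_singing` — mean distance over singing seconds (m);
* `total_singing` — count of singing seconds (s);
* `latency` — 1-based index of the first singing second (a bird singing in
  second 1 has latency 1).

Censoring keeps the ordering semantics of each variable at the
weakest-response bound: a bird that never sings gets latency 480 s and
`mean_distance_singing` equal to the maximum visible distance (default
50 m, configurable); a bird never localized gets `min_distance` at the same
bound. Missing single seconds (observer lost the bird) are skipped in
minima and means; a trial with more than 20% missing response seconds is
flagged, not dropped.

Scaling maps every variable to [0, 1] with 1 = strongest response. Singing
time has a natural denominator (480 s, so 120 s scales to 0.25). Latency is
scaled over its theoretical span [1, 480] as `(480 − latency) / 479`, which
assigns exactly 1 to a bird singing in the first second and exactly 0 to
the censored value — chosen so that the four components at their strongest
values attain the composite score's upper bound of 4 exactly. Distances
have no theoretical bound and are min-max scaled over the dataset; the
basis is configurable (`global` default, `per_species`, or `fixed` bounds)
because a data-driven choice is the only defensible one when no bound is
recorded. If all distances are identical the component is uninformative and
is set to 0.5 with a warning.

The raw score is the sum of the four components (0–4); the aggression index
is the raw score centered within each territorial male over the trials
actually analysed. A male with a single trial centers to 0 (with a
warning). The four raw variables are also centered within male for the
per-variable analyses. No re-standardization is applied after centering.

## Mixed models

All models are Gaussian LMMs with random intercepts. The engine
(`titplayback.lmm`) profiles the fixed effects and residual variance out of
the (restricted) likelihood and optimizes the variance ratios
`gamma_k = sigma_k^2 / sigma^2` by bounded L-BFGS-B from three starts
(0.05, 0.5, 2.0), handling the marginal covariance densely via Cholesky
factorizations — exact and fast for designs up to a few hundred rows. A
variance ratio at the zero boundary is reported as a singular fit
(warning), not an error. The engine agrees with a brute-force maximizer of
the unprofiled restricted likelihood and with statsmodels' `MixedLM` on
crossed-intercept fixtures (tested to 1e-4 and ~1e-4 respectively).

Model battery (fit by REML for estimates, refit by ML for LRTs):

* **global** — `treatment * habitat_group + already_singing + z(trial_seq)
  + z(minutes)`, random intercepts for species, male and playback species.
  Male labels are globally unique, so the male intercept is nested in
  species by labelling; species is fitted as its own variance component
  (switchable).
* **per-species** — same fixed structure without the habitat factor, random
  intercepts for male and playback species.
* **per-variable** — each within-male-centered raw variable as response,
  `treatment + already_singing + z(minutes)`, same random structure.

Continuous covariates are standardized (mean 0, SD 1) before fitting.
Likelihood-ratio tests compare ML refits of nested fixed structures; the
interaction LRT has 2 df, main effects are tested from the additive model
(type-II style). Post hoc treatment contrasts are estimated-marginal-means
differences on a reference grid with standardized covariates at 0 and the
already-singing factor averaged over {0, 1}; SEs come from the fixed-effect
covariance, t tests use residual degrees of freedom (n − rank(X); the
containment/Satterthwaite alternatives are deliberately not guessed), and
p-values are Benjamini–Hochberg adjusted within each model's three-contrast
family (per habitat group in the global model).

### Centering-aware degrees of freedom

Within-male centering estimates one mean per male *outside* the model.
Fitted on centered data, the male variance component collapses to ~0 and
the residual variance estimate is deflated by roughly `(1 − 1/n̄)` with `n̄`
the mean trials per male (~3.3 here), while the sampling variance of
treatment contrasts — driven by within-male differences in which the male
mean cancels — stays at the full residual scale. A naive fit on centered
data therefore understates every contrast SE by ~16%. The battery fixes
this by charging the M − 1 centered-out male means against the residual
degrees of freedom (`ModelSpec.centered_within`, on by default in the
battery, off in the raw engine): the residual variance then estimates the
pre-centering error scale and 2-SE intervals achieve near-nominal coverage
(verified by the parameter-recovery study). Setting
`centered_within=None` reproduces the naive fit.

The ML likelihood itself is left untouched, so LRT statistics computed on
centered responses still inherit the deflation and are anticonservative
(~15% type-I at alpha = 0.05 for the 2-df interaction in simulations).
This mirrors what any off-the-shelf mixed-model fit on pre-centered data
reports. The calibration study in the acceptance suite therefore evaluates
the LRT machinery on the generator's latent (uncentered) response, where
the model is correctly specified; at 50 males / 150 trials the empirical
type-I error is at the nominal 5%. Treat LRT p-values on centered
responses as approximate.

## Synthetic-data generator

The generator defines the study conditions; its defaults are frozen design
choices, not tuning knobs.

**Design.** The default schedule reproduces the experiment's printed
focal x playback allocation grid exactly (101 territories: 21/21/21/20/18
per species; 333 trials: 103 conspecific, 97 intra-habitat, 133
extra-habitat), assigning each male 1 conspecific stimulus (2 for the two
extra conspecific trials of one species), 2–3 heterospecific stimuli under
a 4-stimulus cap, randomized order, one trial per male per day with a
minimum 2-day gap in a 31-day horizon, and at least 8 experiment-wide
repetitions of every heterospecific focal x playback pair. Heterospecific
selection prefers giving each male both treatment classes
(`balance_treatments_within_male`, default on): the study describes
treatments as balanced across playbacks, and an unbalanced per-male mix
interacts with within-male centering to bias the intra-vs-extra contrast
downward by ~15–20%.

**Latent layer.** Trial aggression on the 0–4 score scale:
`a = grand_mean + effect(group, treatment) + 0.4·already_singing
− 0.05·z(trial_seq) + 0.02·z(minutes) + u_male + v_playback + eps`.
Defaults: `grand_mean = 1.0`; effects broadleaf (conspecific 1.9, intra
0.7, extra 0.0) and conifer (2.0, 0.0, 0.0) — the qualitative field
pattern with conspecific−intra = 1.2 and intra−extra = 0.7 in the
broadleaf group and no heterospecific discrimination in the conifer group;
`sd_male = 0.4`, `sd_playback_species = 0.05`, `sd_residual = 0.75`. The
residual scale was chosen so that simulated per-species contrast SEs land
near 0.3 index units, matching the reported precision of comparable field
analyses at n ≈ 70 trials per species; the small playback-species SD
reflects volume-normalized, multi-exemplar stimuli (a large value would be
visible as much wider conspecific contrast SEs than those analyses show);
the grand mean centers the occupied range inside the score's support so the
bounded scale truncates as little as possible.

**Renderer.** A normalized logistic link
`g(a) = (expit((a−2)/2) − expit(−1)) / (expit(1) − expit(−1))`, clipped to
[0, 1], maps the latent score to a behaviour fraction; the same link (with
independent small Gaussian perturbations, SD 0.04) drives singing time
(`round(480·g)` contiguous seconds), onset (`480 − round(479·g)`), and mean
approach distance (`(1−g)·50 m` with AR(1) jitter, coefficient 0.8, SD
1.5 m, clipped to [0, 50] and rounded to the meter as in field estimation).
The link family is logistic for smoothness and boundedness; its width (2
score units) keeps the map near-linear over the occupied range so that the
recomputed composite score tracks the latent score approximately one-to-one
(empirical slope ~0.95) and generating contrasts survive the
render→summarize→scale round trip. With all noise constants at zero the
renderer is a deterministic monotone function of the latent score.

**Songs and territories.** Syllable feature vectors are drawn i.i.d. around
per-species profile means. The placeholder profiles sit on a regular
simplex (each species offset along one feature axis), making every
species-pair profile distance equal — song similarity is orthogonal to the
habitat grouping by construction, so the generator's null carries no
built-in song–aggression association. Body masses are placeholders ordered
great > coal ≈ blue > marsh > crested; because the heaviest species is also
a broadleaf member, the mass-difference matrix retains a small structural
alignment with the treatment pattern (r ≈ 0.2 in the directed-cell
correlation), which the exact permutation test correctly treats as
non-significant; null behaviour is therefore assessed through p-values,
not through the raw correlation. Territory points scatter isotropically
(SD 35 m) around jittered grid centers 150 m apart.

**What the generator does not emulate.** Behavioural autocorrelation beyond
AR(1) distance jitter, within-trial escalation dynamics, observer error in
singing detection, non-Gaussian residuals, day/weather effects, and any
coupling between song structure and aggression. Passing tests show the
*analysis chain* is correct and calibrated under the stated generative
model; they do not validate the behavioural realism of that model.

## Matrix tests

The response matrix is directed (focal row, playback column, diagonal
excluded by default); predictors are symmetric. The statistic is the
Pearson (optionally Spearman) correlation over matched off-diagonal cells;
the null jointly permutes the predictor's row/column labels. For K = 5
species all 119 non-identity permutations are enumerated, so p-values are
exact multiples of 1/120, the identity predictor attains the minimal
achievable p = 1/120, and the rejection rate at alpha = 0.05 is exactly
6/120 under exchangeability. When K! − 1 exceeds `n_perm` (default 10,000)
the test falls back to sampled permutations with the add-one estimator. A
configuration option averages cells (i, j) and (j, i) first; signed mass
differences are available for larger-versus-smaller aggression hypotheses.

DTW uses Euclidean local cost on dataset-z-scored features, the symmetric
step pattern with diagonal weight 2, boundary-to-boundary paths, and
normalization by the path-independent constant n + m. This makes the
distance symmetric, zero for identical sequences, invariant to syllable
repetition, and exactly reproducible by exhaustive path enumeration (the
test oracle). The acoustic feature set is a contract, not a commitment:
any fixed-k syllable feature table is accepted.

## Territories

Minimum convex polygons via exact convex hulls; percentile trimming (e.g.
95%) removes the farthest points from the centroid before hulling, as in
the home-range literature, but the default is 100% since no percentile is
part of the study design. Areas use the shoelace formula; overlap is
intersection area over the smaller territory's area. Coordinates are
planar meters; tables with lon/lat-named columns are rejected with a
pointer to pre-projection rather than guessed at from coordinate ranges.

## Problem sizes and reproducibility

All randomness flows from one seed; per-stage and per-trial sub-seeds are
derived by SHA-256 of the seed and a tag path, so any stage or single trial
can be regenerated in isolation. The Monte-Carlo studies in the acceptance
suite use 100 replicates of the full 333-trial experiment for parameter
recovery, 1,000 replicates at 150 trials for LRT calibration, and 1,000
seeded runs of the exact permutation test; these sizes give binomial
standard errors of ~1–3% on the rates being checked while keeping the whole
suite under ten minutes on one core.

## Known limitations

* LRT p-values on pre-centered responses are anticonservative (see above);
  contrast inference is the calibrated route.
* Residual degrees of freedom for contrast t-tests are a deliberate,
  simple choice; they do not reproduce any particular emmeans adjustment.
* The permutation test conditions on the observed matrices; with five
  species its resolution is limited to multiples of 1/120.
* The generator's renderer is monotone and near-linear by design; analyses
  of data from a strongly nonlinear behavioural readout would attenuate
  contrasts relative to the latent scale.
* No geodesic support in territory mapping; project first.
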