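# Methods

`stackenc` implements a stacked ridge encoding-model analysis for
naturalistic movie fMRI, from feature design matrices and grayordinate time
series through per-grayordinate model metrics, permutation-based
significance, parcel summaries, and parcel-wise mixed-effects group
statistics, together with a synthetic-data generator that provides
ground-truth cohorts for validation.

## The encoding model

For one subject, the response of grayordinate *g* is a time series
**y**_g of length *T* at TR = 0.8 s. Stimulus features are organised into
feature spaces *k* (by default audio-low, audio-high, visual-low,
visual-high), each a design matrix **X**_k built by convolving the raw
feature series with the canonical double-gamma haemodynamic response
function (response peak 6 s, undershoot peak 16 s, dispersions 1 s,
peak-to-undershoot ratio 6; all six parameters exposed), bin-averaging down
to the TR, dropping the first 10 volumes (matching the BOLD discard), and
z-scoring each column.

Each space gets its own ridge regression per grayordinate, evaluated with
5-fold cross-validation over contiguous time blocks (train on 80% of the
movie, test on the held-out 20%). The ridge penalty is selected per
grayordinate and space by an inner 4-fold cross-validation on the training
block only, over a log-spaced grid of 20 values from 1e-2 to 1e5. Ridge
solutions are computed on a shared SVD of the design so all grayordinates
and penalties reduce to dense matrix products; design-side factors are
cached per fold so repeated refits (permutations) cost only products.

The stacking stage solves, per grayordinate, the convex quadratic program

    min_alpha || y - sum_k alpha_k yhat_k ||^2
    s.t. alpha_k >= 0, sum_k alpha_k = 1,

where yhat_k are the base models' out-of-fold predictions inside the
training block; the solved weights are then evaluated on the outer held-out
block, so the stacking stage never sees its own evaluation data. The QP is
solved exactly by enumerating support sets of the KKT system (at most
2^K - 1 faces; K = 4 here). Singular faces are solved in the minimum-norm
sense, which makes the tie-break on flat objectives — identical predictors
receive uniform weights — automatic rather than a special case.

**Standardised base predictions.** Base-model predictions are z-scored
(within block, per grayordinate and space) before the stacking solve and
the stacked prediction, and the stacked prediction carries the training
mean as an intercept. Without this, a space whose prediction is attenuated
by ridge shrinkage would be under-weighted in proportion to its amplitude
rather than its information; with it, a space whose standardised prediction
carries a fraction *w* of the response signal receives weight *w*, which is
what makes the weights comparable across grayordinates and against the
generator's ground-truth mixing weights.

**Derived metrics.** Held-out R² = 1 − SS_res/SS_tot is computed on the
concatenated out-of-fold predictions, SS_tot about the evaluated segment's
mean; it can be negative. Unique R² uses clipped subtraction: the competing
component's R² is clipped to zero from below and to the stacked R² from
above, so unique + clipped component = stacked in every branch. Preference
indices are stacking-weight differences: W_H − W_L per modality and
W_V − W_A for the audio-visual model, positive meaning high-level (or
visual) preference. The source literature states the subtraction order
inconsistently in one place; this package follows the results-level
convention (W_H − W_L, positive = high-level) throughout.

## Inference

Grayordinate significance uses a temporal-permutation null: the response
order is permuted, the full fit is rerun, and p = (1 + #{null ≥ obs}) /
(1 + B) with B = 1000 by default. The default scheme is a full random
reordering; a block scheme (configurable block length) is available for
autocorrelation-aware nulls, and the docs note that full shuffles are
anticonservative under autocorrelated noise. Null refits reuse the ridge
penalties selected on the observed data by default (`reuse_penalties`),
which makes each iteration a set of matrix products; setting it to False
re-selects penalties inside every iteration, making null and observed fits
fully exchangeable. The uniformity of p-values under a true null is
verified in the test suite with the exchangeable variant.

Benjamini–Hochberg FDR correction is applied across grayordinates within a
subject and model (q ≤ 0.05); parcel summaries are unweighted means of each
metric over the surviving grayordinates, with parcels lacking significant
grayordinates reported as missing. Split-half noise ceilings split subjects
into random halves (50 splits), correlate the half-average parcel time
series, average r over splits, apply the Spearman–Brown correction
r_sb = 2r/(1+r), and report r_sb² as the ceiling on attainable R² — the
standard reliability-to-variance conversion, since reliability bounds the
correlation between any prediction and the measured signal.

## Group statistics

Each parcel-level metric is modelled across subjects with a linear mixed
model: the focal predictor (group, SRS, SSS, age, or an age interaction,
interactions always with their main effects) plus age (years), sex
(M = 1, F = 0), and socioeconomic status (Barratt total, unstandardised) as
fixed effects, and acquisition site as a random intercept. Group is coded
ASD = 1, nonASD = 0, so a negative focal-group coefficient means the metric
is lower in the autistic group. P-values for the focal coefficient are BH
corrected across parcels within one (metric, focal, FD-threshold) family.

The identity link is the default. A logit-link option first squeezes the
metric into (1e-3, 1 − 1e-3) — R²-type metrics clipped to [0, 1], signed
preference indices mapped through (x+1)/2 — then fits the mixed model on
the logit scale; both links are exposed because the appropriate transform
for metrics that can be negative is genuinely underdetermined, and the link
used is recorded in every output row.

Numerical details: fits use statsmodels MixedLM (REML); when the default
optimizer stalls or returns non-finite p-values the model is refit with
Powell's method, which is slower but far more robust at these sample sizes.
When the random-intercept variance estimate collapses to the boundary
(< 1e-8) the model degenerates to an ordinary regression and is refit by
OLS for exact coefficients. Single-site data drop the random term with a
warning; parcels with fewer than 10 subjects, or non-converging fits, are
excluded from the FDR family with a logged count. Wald p-values that
underflow to exactly zero on degenerate (noiseless) fits are floored at
1e-300 before BH.

Demographic comparisons follow a test-selection cascade: within-group
normality (Shapiro–Wilk for n < 50, else D'Agostino's K²) and Levene's
variance test route each continuous measure to Student's t (normal, equal
variance), Welch's t (normal, unequal variance), or a two-sided
Mann–Whitney U (non-normal). The sex comparison uses a continuity-corrected
2×2 chi-square, with Fisher's exact test substituted when any observed cell
count falls below five. P-values are BH adjusted over the comparison
family. ADHD-stratified contrasts reuse the same machinery after relabeling
(ASD−ADHD vs nonASD, ASD+ADHD vs nonASD, ASD−ADHD vs ASD+ADHD).

## Quality control and phenotype

Framewise displacement follows the Power convention: the sum of absolute
backward differences of the three translations (mm) plus the three
rotations (radians) converted to arc length at a 50 mm radius; the first
volume's FD is 0. A run fails a threshold iff the fraction of volumes with
FD strictly above 0.2 mm strictly exceeds it; the thresholds swept are 40%,
60%, and 80%, and pass sets are nested by construction. QC is evaluated per
run, a subject being retained only if all analysed runs pass.

The Sensory Subset Score is the sum of SRS-2 items 20, 42, 58 (coded 0–3)
and SCQ item 14 (Yes → 3, No → 0), ranging 0–12; a missing item makes the
score missing rather than pro-rating, which would silently change the
scale. Group assignment maps the consensus label 'Autism Spectrum
Disorder' to ASD and 'No Diagnosis Given' to nonASD; incomplete or
unrecognised labels are excluded with a logged reason, and co-occurring
ADHD never excludes a subject from the ASD group.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the physiology behind it. A shared "movie" drives all subjects: low-level
feature spaces are stationary AR(1) Gaussian processes (lag-1 coefficient
0.3 by default, unit variance); high-level spaces are blockwise binary
indicators (mean block length 8 TRs, activation probability 0.2). Feature
dimensionalities default to 6 (audio-low), 8 (audio-high), 2 (visual-low),
2 (visual-high), mirroring the compact feature sets the analysis was
designed around. Grayordinate responses are known convex mixtures of
z-scored per-space predictions plus a per-site offset (site SD 0.1 response
units, three sites assigned round-robin) and AR(1) noise scaled so that
sd(signal)/sd(noise) equals the configured SNR (default 1, giving an
explainable-variance ceiling of snr²/(1+snr²) = 0.5 — an identity the test
suite verifies by simulation).

The cohort has two groups (default 30 subjects each) with demographics
loosely matched to the study population: the simulated-ASD group is older,
more male, lower-SES, and higher-severity. In designated "pSTS-like"
parcels (the last 2 of 16 by default), whose baseline mixing prototype is
high-level-visual dominant (0.10, 0.10, 0.30, 0.50), simulated-ASD subjects
have their visual high-level weight shifted toward the low-level space by
∓shift/2 on the two weights, so the group difference in the W_H − W_L index
equals `group_pref_shift` (default 0.3) on average; per-subject shifts are
proportional to severity, so the severity association is built in. Weights
pushed off the simplex are re-projected (clip negatives, renormalise) with
a warning. Motion traces are gamma-distributed FD series whose subject-level
mean decays exponentially with age (default slope −0.04 log-mm/year with
0.3 SD log-normal subject noise, calibrated so the fraction-over-0.2 mm vs
age Spearman correlation lands near −0.4).

What the generator does not emulate: cortical geometry and spatial
autocorrelation, haemodynamic nonlinearity, scanner drift and physiological
confounds, gaze-dependent input, or any real movie content. Passing tests
therefore demonstrate that the estimators recover the structure they are
designed for under the assumed noise model — not that the assumptions hold
in real data. The temporal-permutation default, in particular, is exactly
as anticonservative on real autocorrelated noise as it is in the AR(1)
simulation with the full-shuffle scheme.

## Validation problem sizes

The test suite validates the pipeline at sizes chosen to keep the full run
in minutes on one CPU: stacking-weight recovery uses one subject at
T = 2000, 80 grayordinates, SNR 1 (mean absolute error ≤ 0.05);
group-effect detection uses five replicate cohorts of 30 subjects per
group, T = 400, 48 grayordinates over 12 parcels, 39 permutations per
subject, requiring the injected 0.3 preference shift to be flagged
(q < 0.05, correct sign) in ≥ 90% of designated parcel-replicates and in
≤ 5% of non-designated ones; permutation-p uniformity uses 500 white-noise
grayordinates at 99 exchangeable permutations (Kolmogorov–Smirnov at
α = 0.01); BH FDR control uses 500 replicates of 200 tests with 20%
non-null.

## Known limitations

- The permutation default (full shuffle) ignores temporal autocorrelation;
  use the block scheme when the noise is autocorrelated.
- statsmodels MixedLM provides Wald inference only; small-site-count
  designs (three sites here) estimate the random-intercept variance
  noisily, and the boundary-refit rule makes the identity-link results
  insensitive to that, but logit-link variance components should be read
  with care.
- The logit link is applied to a squeezed transform of the metric, not a
  true conditional-binomial model; it is provided for comparability, with
  the identity link as the default.
- The unique-R² clipping rules guarantee a consistent partition but bias
  unique variance toward zero when component fits are noisy.
- CIFTI-2 reading is a thin optional layer (nibabel); the canonical
  containers are plain .npy/TSV matrices.
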