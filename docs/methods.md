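# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the known limitations of `motorchart`.

## From label streams to analysable playtime

The pipeline assumes frame-level classifier outputs at a fixed hop of
1.15 s: the wearable's raw 52 Hz signal is segmented into 2.3 s frames with
50% overlap (120 samples, 60-sample hop), and each frame carries a posture
label, a movement label, a carried flag and a quality flag.  One hour is
3,130 frames; hour↔frame conversions round down.  Ages are real-valued
months (30.4375 days/month).

Only frames that are simultaneously good-quality, not carried, and free
play enter feature computation.  The three masks are set intersections, so
their application order is irrelevant.  Free play is detected by a
regularized binary logistic regression on 10-minute (520-frame,
50%-overlap) super-segment features — the concatenated posture and movement
category distributions of the window.  Window decisions map back to frames
by majority vote over the covering windows, ties counting as playtime, and
trailing frames beyond the last complete window inherit its decision; the
combination rule is a design choice, as overlapping-window aggregation has
no single canonical form.  Recordings retaining under 20 minutes of
playtime are excluded from feature computation and listed in the retention
report; the separate >2 h threshold of the noise analysis (below) is
deliberately stricter.

## Motor features

A recording's feature vector concatenates its posture distribution (6
fractions summing to 1) with the row-major posture-conditioned movement
matrix (6×7; each observed posture's row sums to 1).  Conditional rows of
unobserved postures are zeros rather than NaN so the feature space stays
fixed at 48 dimensions; deleting rows instead would make the regression
dimension depend on the recording, which we rejected.  Monthly category
curves average recordings within [m, m+1)-month bins; movement categories
are reported by default on the common whole-recording scale (conditional
rows weighted by posture prevalence) so posture and movement curves share
units, with the unweighted conditional mode available.

## Developmental age prediction

DAP is the posterior mean of a Gaussian-process regression of age on the
feature vector — a forward features→age regression, which is the standard
GPR reading of "the expected age that generated this measurement"; an
inverse-model formulation (fit features as a function of age, invert)
would be an alternative reading and is not implemented.  The kernel is an
isotropic RBF times a constant plus a white-noise term; hyperparameters
maximize the marginal likelihood with 5 seeded restarts (configurable).
Features are standardized internally; structurally-zero columns (category
cells that never occur) are kept at unit scale, since a column constant in
both training and test data contributes nothing to RBF distances.  A
feature constant at a nonzero value indicates a broken input and raises,
naming the offending dimensions.  The age target is centred and scaled by
the GP and predictions are re-expressed in months with a predictive SD.

Evaluation is always subject-wise: full leave-one-subject-out for motor
cohorts (tens of subjects), grouped 5-fold subject-wise CV for physical
cohorts (hundreds to thousands of subjects, where full LOSO buys nothing
but compute).  No subject ever appears in both train and test; the fold
loop asserts this.  Physical DAP uses the same machinery on 1-D or 3-D
feature vectors of length (cm), weight (kg) and head circumference (cm).

## Growth-chart model

The mean model is the four-parameter logistic

    f(x) = L + (U − L) / (1 + exp(−k(x − x0)))

with asymptotes L, U and midpoint x0 in months and slope k in 1/months,
fitted by least squares with data-driven multi-start (L = min, U = max,
x0 = median age, k ∈ {0.2, 0.5, 1} signed by the data trend) and
Levenberg–Marquardt refinement; the solution is normalized to U ≥ L.  Any
4PL reparameterization gives the same fitted curve, so goodness-of-fit
metrics are parameterization-invariant.  Constant values produce the
degenerate flat fit without error; R² is then reported as 0 with a flag.

Goodness-of-fit is R² = 1 − SS_res/SS_tot and σ = RMS residual in months
(not a ddof-corrected SD — σ is the ±1SD band half-width, and the RMS
definition keeps raw and grouped metrics consistent).  Three groupings:

* **raw** — every measurement against the curve;
* **monthly means** — bin-mean values against the model at bin-mean ages.
  Note a small Jensen gap: bin means of a nonlinear curve differ from the
  curve at the bin-mean age, so even noiseless data give R² ≈ 0.99999
  rather than exactly 1 under this definition;
* **ID-controlled** — raw residuals after removing per-subject random
  intercepts, estimated in two stages: sigmoid first, then the
  random-intercept model r_ij = b_i + e_ij by REML (statsmodels MixedLM).
  A joint nonlinear mixed model would be the alternative; the two-stage
  form matches the serial-measurement-correction reading of the procedure
  and keeps the mean model identical across groupings.  R² for this
  grouping uses the raw total sum of squares, so removing offsets can only
  tighten it.  If every subject has a single measurement the intercepts
  are undefined and raw residuals are returned with a warning; numerically
  degenerate covariance (e.g. zero residuals) falls back to unshrunken
  per-subject means.

Because REML intercepts absorb roughly 1/k of each subject's noise (k =
measurements per subject), the RMS of corrected residuals sits slightly
below the true noise SD (≈ √(1−1/k) of it); recovery of the generating
variances is therefore assessed on the REML variance components, which are
unbiased.

Confidence intervals are 95% bootstrap percentile intervals (default
N = 10,000 in the primitive; chart construction defaults to 1,000 with 200
for the LME-refitting ID-controlled metrics, as variance there is dominated
by subjects, not resamples).  The resampling unit is the recording for raw
and grouped metrics and the subject for ID-controlled metrics.  Resamples
on which a metric is undefined are redrawn and counted.  Chart-quality
intervals are additionally recentred by the bootstrap bias (mean of
resamples minus point estimate): row resampling biases grouped metrics
upward, and a plain percentile interval can otherwise exclude its own point
estimate.

## Measurement noise and longitudinal tracking

Recordings with strictly more than 2 h of retained playtime are split into
consecutive non-overlapping 1-h playtime epochs (trailing partial epoch
discarded), each scored with its own DAP.  With two independent
equal-variance epochs, Var(difference) = 2σ², so the per-epoch noise SD is
the SD of all within-recording epoch differences divided by √2 — e.g. a
difference SD of 1.2 months implies σ = 0.85 months.  Normality of the
differences is tested with a one-sample K–S test after standardizing by the
sample mean and SD; this standardization makes the test conservative under
the null (the Lilliefors effect), which we accept — the check guards
against gross non-normality, not calibrated inference.  Age dependence of
the noise level is the Pearson correlation of |difference| with age (a
signed-difference variant is available by flag).

Longitudinal tracking enumerates all within-subject ordered recording pairs
(t1 > t0), records (Δage, ΔDAP), and summarizes monthly Δage bins from 1 to
10 months by mean and SD; bins with fewer than 3 pairs are flagged and
excluded from the monotonicity assessment.

## Cohort comparison

Monthly category curves of two cohorts are compared per category by Pearson
r (two-sided p) and MAE in percentage points over bins populated in both
cohorts; categories with fewer than 3 shared bins are skipped with a flag,
and zero-variance categories report MAE but a flagged, undefined r by
default (computing r anyway is available, mirroring how near-degenerate
low-prevalence categories are sometimes still reported).  Group summaries
(mean and range) are given separately for posture and movement categories,
unweighted by bin occupancy.  Chart agreement reports the Pearson r of
monthly DAP means, per-parameter bootstrap-CI overlap of the 4PL fits, and
the fraction of an age grid where the two ±1SD bands intersect.

## The synthetic cohort generator

The generator is the package's test bed and defines the conditions under
which all validation claims hold.  For each recording of subject i at age
t, labels are drawn at developmental stage d = t + δ_i + η_r with
δ_i ~ N(0, σ_dev²) (a stable per-infant pace offset, default 0.6 months)
and η_r ~ N(0, σ_sess²) (a per-session situational offset, default 0.85
months, matching the measured epoch-noise scale).  Posture probabilities
are softmax of per-posture quadratic logits in d, parameterized (see
`defaults.yaml`) to reproduce the canonical sequence — supine declining
first, prone next, a transient crawl-posture peak near 10 months, then
rising and persisting sitting and standing.  Movement given posture follows
a cumulative-logit ordinal model (still → proto → elementary → fluent, with
thresholds at 5/9/13 months shifted per posture) plus small fixed
probabilities for pivot/roll/transition where applicable; the fluent
fraction is strictly increasing in d in every posture.  Consecutive frames
repeat with probability p_stay = 0.9, giving realistic label runs
(persistence never crosses block boundaries).

Sessions run 1.4–16.9 h (truncated normal, mean 7.8 h), of which 30% is
free play, 10% carried and 20% low-quality by default; playtime and
non-playtime come in long blocks (mean 30 min), carried and low-quality
interruptions in short ones (mean 5 min).  Non-playtime frames draw from an
age-independent resting distribution (supine/sitting-heavy, predominantly
still), which is what makes super-segments separable for the playtime
classifier.  Physical growth uses strictly monotone median curves (length
and HC logarithmic, weight square-root; parameters chosen to span realistic
4–18-month values) with per-subject intercepts and per-visit measurement
error; the noise-to-slope ratios make length the tightest age predictor and
weight/HC the loosest, reproducing the modality ordering seen in real
growth data.  Visit ages follow the routine child-health-clinic schedule
within range, jittered.

What the generator does **not** emulate: within-session drift of the
situational offset (η_r is constant across a session, so epoch-to-epoch DAP
differences reflect feature-sampling noise only and sit below σ_sess);
classifier confusion structure (labels are draws from the true model, not
noisy classifications); Bluetooth-dropout patterns; skipped or regressed
milestones; preterm-corrected age.  Passing tests therefore demonstrate
that the analysis machinery recovers what it claims under the stated
statistical structure — not that any particular real cohort satisfies that
structure.

## Problem sizes and reproducibility

Validation runs use desk-scale cohorts chosen as the package's own test
conditions: a 200-recording default cohort (~60 subjects) for
leave-one-subject-out recovery, 150-recording pairs for replicate-cohort
chart agreement, a 70-subject repeat-recording cohort (~650 pairs) for
longitudinal tracking, and 500×4 panels for variance-component recovery.
Under these conditions LOSO DAP recovers age with slope ≈ 0.9 and RMSE ≈
1.1 months against an injected noise floor of √(0.6² + 0.85²) ≈ 1.04
months.  Every random draw — generator, GP restarts, bootstrap, CV folds —
flows from explicit integer seeds, and rerunning any stage with the same
config and seed reproduces its outputs exactly.

## Known limitations

* The motor scale saturates once fluent standing/walking dominates;
  charts are meaningful for roughly 4–18 months and the 4PL asymptotes are
  weakly identified when the observed range covers only the near-linear
  mid-section.
* The playtime classifier is a linear model on window label distributions;
  with real classifier outputs (rather than generator draws) a richer
  feature set or kernel may be needed.
* Epoch-noise estimation assumes equal-variance independent epochs within
  a recording; pairs from recordings with many epochs are correlated
  through shared epochs, which the SD-of-differences estimator ignores.
* Centile estimation (LMS/GAMLSS) is out of scope; the charts report a
  mean curve with a ±1σ band, not full reference centiles.
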