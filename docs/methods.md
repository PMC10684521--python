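# Methods

`valuectx` implements a complete analysis chain for context-dependent
subjective-value coding in human intracranial band-power recordings,
together with a synthetic-data generator that reproduces the statistical
structure the chain assumes. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
data can and cannot establish.

## Behavioral task model

The behavioral substrate is a Becker-DeGroot-Marschak (BDM) auction:
on each trial the subject bids x ∈ {0, 10, …, 200} TWD for a food item;
at realization a price y ~ Uniform{10, …, 200} is drawn and the subject
buys at y iff x ≥ y. Truthful bidding is optimal, so the bid is used as
the trial's subjective value (SV).

Per-subject behavioral regressions are simple OLS fits with intercept:

* current bid on the previous trial's bid (lag 1 or 2). A (t, t−lag)
  pair is used only when both trials are valid and adjacent at exactly
  that lag in presentation order; pairs spanning an excluded trial are
  dropped. Block boundaries do not break adjacency.
* response time on the bid (the expected null relation). The transposed
  regression (bid on RT) is available behind `bid_as_response=True`;
  the default direction follows the convention of reporting RT as the
  response.

Subject coefficients are combined with a two-tailed one-sample t test.
RT outliers are excluded per subject at |RT − mean| > 3·SD (sample SD
over all of the subject's trials); zero-variance subjects produce no
exclusions and a logged warning.

## Spectral pipeline

Raw shaft-ordered LFP is re-referenced to the mean of the two
neighboring contacts (shaft ends use their single neighbor). Epochs are
cut from −1.5 to +2.0 s around stimulus onset — deliberately longer
than the analysis window so the wavelet transform never sees zero
padding inside it. Morlet wavelet power is estimated at 60 log-spaced
frequencies from 4 to 200 Hz with cycle counts scaling linearly from 3
(4 Hz) to 12 (200 Hz); neither number is critical, they are the usual
trade-off between temporal and spectral resolution over this range.

Baseline correction is two-step and single-trial: each
(frequency, contact, trial) power timeseries is divided by its own
full-epoch mean (a dB variant of this step is available behind
`mode="db"`), then the mean over the pre-stimulus second (−1…0 s) is
subtracted per frequency bin. Band power is the unweighted mean across
the frequency bins inside a band (theta 4–7, alpha 8–12, beta 13–30,
gamma 30–80, high-gamma 80–150 Hz), averaged within non-overlapping
10-ms windows and trimmed to the canonical grid: −1.0 to +1.5 s at
10 ms, 251 points, both endpoints included.

## Encoding models

For each contact and each grid timepoint independently, band power
across trials is regressed on a constant, the current trial's SV, and
the previous trial's SV (the main model). Variants: exclude zero-bid
trials; add RT; add the SV two trials back; add the previous trial's
power at the matched timepoint (an autocorrelation control, refit per
timepoint); restrict to trials with a given preceding inter-trial
interval (1, 1.5, or 2 s). A sequential two-step fit (one value
regressor, then the residuals on the other, in either order) probes
whether the two value signals are separable.

Previous-trial definitions at boundaries are not derivable from the
task, so the package fixes them: the previous trial is the immediately
preceding *presented* trial; session-initial trials, and trials whose
previous (or two-back, where used) trial is invalid, are dropped from
designs that need them. Regressors are left in raw TWD units (no
standardization; a per-subject z-scoring flag exists), so coefficients
are directly comparable across model variants.

t statistics are mapped to z scores by matching the Student-t CDF to
the standard-normal quantile. The transform is evaluated through the
log survival function of |t| so that far tails survive; |z| is capped
at 38, the quantile of the smallest positive double.

## TFCE permutation inference

Threshold-free cluster enhancement scores each point of a z series
(or 2D time-frequency map) as Σ_h e_h^E · h^H · dh over height levels
h = dh, 2dh, …, where e_h is the extent of the connected
supra-threshold component containing the point at level h. Time series
use E = 2, H = 2; time-frequency maps use E = 1, H = 2 with 4-neighbor
connectivity. Signed statistics are enhanced per direction (positive
part from max(z, 0), negative part as −TFCE of max(−z, 0)).

The level step defaults to max|z|/100 per input, making the sum a
quadrature of the underlying level integral; the max/min statistics the
inference consumes move by under ~2% of their scale across 50–200
levels, and the significance masks are unchanged. A fixed `dh` can be
supplied instead.

Familywise error across timepoints is controlled with
maximum-statistic nulls:

* **Group level** (contacts × time coefficients): the observed
  statistic is the across-contact one-sample t per timepoint → z →
  TFCE. Each permutation assigns +1 to ⌊N/2⌋ randomly chosen contacts
  and −1 to the rest (one labelling applied to all timepoints),
  regresses the coefficients on the label per timepoint, and records
  the max and min TFCE of the resulting series. A timepoint is
  significant when its TFCE exceeds the 95th percentile of the max
  null or falls below the 5th percentile of the min null — two
  one-tailed decisions, each at α = 0.05, with no additional
  cross-direction correction. Discrete-null quantiles use the
  conservative `higher`/`lower` methods with strict inequalities, and
  p = (1 + #more extreme)/(1 + n_perm).

  A consequence worth stating plainly: each *directional* family is
  controlled at 5%, so the probability that a null dataset shows any
  significant timepoint in *either* direction is close to 2α (~9%),
  not α. The calibration target reported by `scripts/acceptance.py`
  measures exactly this union and lands at 0.07–0.10 across seeds.

* **Individual contact level**: permutations shuffle the design rows
  jointly (the same row order at every timepoint), preserving the
  within-trial coupling of the regressors. The observed ordering is a
  member of the permutation orbit, so each directional test is exactly
  calibrated. The most extreme TFCE timepoint per regressor (ties
  broken toward the earliest) is reported with its t statistic, and
  contacts are classified current-only / previous-only / both /
  neither from the per-regressor FWE masks.

* **Time-frequency**: the group scheme with 2D connected components.

Default permutation counts are 10,000 (1D) and 1,000 (2D), matching
the analysis the package reproduces; tests and the acceptance script
use 150–300, which is ample for 5%-level decisions.

The sign-flip null assumes the cross-contact coefficient distribution
is symmetric. A bootstrap check resamples contacts with replacement
(the same resample at every timepoint), computes the Pearson median
skewness 3·(mean − median)/SD per timepoint, and flags a timepoint as
compatible with symmetry when the percentile 95% CI contains zero.

## State-space analyses

Trials are sorted into four conditions by subject-specific median
splits of the current and previous bid ([current, previous] =
[high, low], [high, high], [low, low], [low, high]); a bid exactly at
the median goes to "low" (configurable). Per contact, each trial's
high-gamma timeseries is smoothed with a Gaussian kernel — the window
parameter is interpreted as FWHM in ms (default 400, also 0–300),
truncated at ±3σ with renormalized edge kernels — and the mean
timeseries over all valid trials is subtracted before condition
averaging. The four condition matrices X_c (contacts × 251) are
stacked into X (contacts × 1004).

Two complementary projections:

* **PCA**: contacts are features, stacked timepoints are observations;
  each condition is projected onto the first two PCs. Centering on the
  feature mean is applied by default and toggleable (the per-contact
  mean subtraction already nearly centers the data).
* **Regression subspace**: D = Σ_{i≤N_pc} PC_i PC_iᵀ (N_pc = 12 by
  default) is the projector onto the top principal components. Each
  timepoint's coefficient vector across contacts is denoised with D;
  per variable the timepoint with the largest denoised L2 norm is
  selected (ties → earliest); the two selected vectors, ordered
  (current, previous), are orthogonalized by QR. Each axis is
  sign-flipped if needed so its inner product with its raw selected
  vector is positive, making directions reproducible. Condition
  matrices are projected onto the two axes, giving four trajectories
  in a value × context plane.

## Synthetic data

The generator's defaults are the emulated study's conditions: 20
subjects × 200 trials (8 blocks of 25, 100 items shown twice), 166
orbitofrontal contacts, ITIs drawn from {1, 1.5, 2} s, median RT near
1.5 s, ~23% zero bids, positive lag-1 bid carryover (default slope
0.3, within the range implied by the subject-level spread of the
emulated data), ~30% of contacts encoding value.

Bids: a latent stationary Gaussian AR(1) (mean 60 TWD, SD 35, lag-1
coefficient = configured carryover) is rounded to the nearest 10 and
clipped to [0, 200]; clipping at zero supplies the positive skew. Zero
inflation is an independent Bernoulli mask whose probability is
adjusted for the clipped process's small natural zero rate so the
marginal zero fraction matches the configuration. The skewness level
itself is a free parameter of the emulation, not a fitted quantity.

RTs are Gaussian (1.5 ± 0.4 s), independent of the bids, with a 1%
rate of gross outliers injected 5–9 SDs high (scaled by the SD, so the
degenerate SD = 0 case stays exact) to exercise the exclusion rule.

Neural power on the canonical grid is Gaussian noise (SD 1, in
baseline-corrected power units) plus, on encoding contacts,
w(t)·(b_cur·SV_t + b_prev·SV_{t−1}) where w is a boxcar over 0.3–1.2 s
with 50-ms half-cosine ramps (so enhancement sees clusters of
realistic extent). Default effect sizes are ±0.015 power units per TWD
in high-gamma/gamma (+current, −previous) and ∓0.009 in
theta/alpha/beta (reversed signs), giving per-contact t statistics
around 8–12 at 200 trials — clearly detectable but far from
degenerate. Encoding contacts are split current-only / previous-only /
both at 52/31/17% — the mix observed in the emulated study — which is
what makes the two coefficient patterns separable in contact space;
injected coefficients and latency windows are stored in a truth table
alongside the data.

What the synthetic data does *not* emulate: 1/f background spectra,
line noise, epileptiform artifacts, heterogeneous per-contact effect
sizes, spatial correlation between neighboring contacts, and any
nonlinearity in the value code. Passing recovery tests therefore shows
the estimators and their calibration are correct under the assumed
model, not that real recordings satisfy the model.

## Problem sizes used in tests and the acceptance script

Calibration of the group test uses 1,000 null datasets of 20 contacts
× 30 timepoints with 300 permutations each; parameter recovery uses
100 contacts (10 subjects × 200 trials, 30% encoding) with 200
permutations per contact for classification; the subspace checks use
40 contacts × 120 trials across smoothing windows of 100–400 ms.
These sizes give binomial/Monte-Carlo error well inside the asserted
bands while keeping a full run in minutes on one core.

## Known limitations

* The two one-tailed FWE families are not jointly corrected (by
  design, matching the described procedure); see the calibration note
  above.
* The t→z transform treats the per-timepoint OLS fits as exact; no
  small-sample correction beyond the Student-t CDF is applied.
* The regression-subspace axes are estimated in-sample; no
  cross-validation of axis selection is attempted.
* ROI membership is consumed from the contact table; no atlas lookup
  is performed, and the anterior/posterior orbitofrontal split is a
  strict y > 35 mm MNI threshold on the medial and central labels.
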