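# Methods

This note documents the models implemented in `igradient`, the defaults
and why they were chosen, the synthetic-data generator's assumptions, and
the numerical conventions that affect results.

## Time model and wear

Epoch series are regular vectors of per-epoch summaries (integer activity
counts, or ENMO in mg) indexed by epoch *start* time; the default epoch is
15 s. Wear intervals are half-open `[on, off)` and an epoch is wear iff
its start time lies inside an interval. This start-time rule is a
convention: log sheets do not resolve partially covered boundary epochs,
and any consistent rule changes wear time by at most one epoch per
interval edge. Missing epochs inside a recording are an error, never
imputed. All downstream statistics use wear-true epochs only.

## ENMO

Per sample, `ENMO = max(0, sqrt(ax^2 + ay^2 + az^2) - 1) * 1000` mg;
epoch values are the mean over consecutive non-overlapping windows, with
the trailing partial epoch discarded (mirroring epoch-mode devices).
Truncation happens at the *sample* level before averaging by default,
matching the documented behaviour of the standard raw-processing
pipelines; `EnmoParams.truncate_after_average` flips the order, which
changes results whenever sub-gravity samples occur, so the choice is
explicit rather than silent.

The optional recalibration finds non-overlapping windows (default 10 s)
whose per-axis SD is below 0.013 g, and fits per-axis gain and offset
minimising `sum((||gain*a + offset|| - 1)^2)` over window means by
nonlinear least squares. It requires at least three stationary windows
with orientations separated by ≥ 10°; otherwise it is a no-op with a
warning, and it never applies a fit that worsens the stationary residual.
This is a deliberate simplification of full ellipsoid autocalibration
(no temperature term, no per-axis weighting) and is labelled as such.

## Cutpoints

Evenson thresholds for 15 s epochs: SED ≤ 24, LPA 25–573, MPA 574–1002,
VPA ≥ 1003 counts. As usually printed, the bands skip count 25; the
boundary count is assigned upward to LPA so the categories partition the
non-negative integers, which is also the conservative choice for
sedentary time. Category minutes sum exactly to wear minutes; days are
cut at local midnight; MVPA = MPA + VPA is provided for convenience.

## Lag alignment

Device pairs can disagree by an integer number of epochs. `detect_lag`
maximises the Pearson correlation between one series and integer shifts
of the other over a ±`max_lag` window (default 300 epochs = 75 min,
comfortably beyond worst observed offsets of ~229 epochs), using jointly
wear-true epochs only; ties break to the smallest |shift|, then the
negative one. `rest_anchored_reference` picks the device with the larger
fraction of zero-count epochs inside logged rest periods as the alignment
reference — an automated, reproducible version of the manual log-sheet
check it replaces. `apply_lag` shifts in place of the time grid and marks
exposed epochs non-wear so they drop out of paired analyses. Sub-epoch
(fractional) lag and clock drift are out of scope.

## Intensity gradient

Bins are half-open `[lower, upper)` with equal width; the closed bins
tile `[0, 4000)` exactly and an open terminal bin takes all values
≥ 4000 (the value 4000 itself included — the usual "> 4000" phrasing
would orphan it). The regression coordinate is the bin midpoint
(`lower + width/2`; terminal `4000 + width/2`), so the lowest bin's
coordinate is 12.5 (or 50), never 0. Natural logarithms are used
throughout; the slope is invariant to the log base, the intercept is not.
Empty bins are excluded from the OLS fit rather than given pseudo-time;
`compute_ig(..., pseudo_minutes=eps)` exists behind a flag for
sensitivity analyses, default off. Plain unweighted OLS is used — no
robust fitting, no bin weighting.

Two diagnostics address the count-vs-acceleration comparison:
`bin_occupancy_ratio` (occupied count bins per occupied acceleration
bin; values well above 1 motivate coarsening the count bins) and
`first_bin_composition` (the light-activity share of the coarse scheme's
first bin, which mixes counts 25–99 with sedentary epochs).

## Agreement statistics

Differences are always `d = second-listed − first-listed`; pass the
reference device first to fix the sign convention. With repeated
observations per subject, Bland–Altman limits use
`sd_total = sqrt(sigma2_between + sigma2_within)` from a one-way
random-effects ANOVA of `d` with subject as the factor (unbalanced
designs use the usual `n0` coefficient; a negative between-subject
component is clamped to zero), so the limits describe a difference for a
new observation on a new subject. The headline outputs are the pooled
bias and `bias ± 1.96 sd_total`; optional confidence intervals use a
t-interval on the bias and MOVER-style combination of the bias and
chi-square variance limits for each limit of agreement (approximate under
clustering, and labelled so). Single-subject or one-pair-per-subject
input reduces exactly to the classic formula.

ICC(A,1) — single measurement, absolute agreement — comes from the
two-way ANOVA mean squares,
`(MSR − MSE) / (MSR + (k−1) MSE + k/n (MSC − MSE))`, with F-based 95%
confidence bounds (the McGraw–Wong closed forms). "Two-way random" vs
"two-way mixed" is an interpretation label: estimate and interval are
computed identically, as in the standard implementations.

The repeated-measures correlation is the common-slope ANCOVA: after
centring x and y within subjects, `r_rm` is their correlation with
`df = N − n_subjects − 1` and an F-test p-value; it is invariant to
per-subject shifts of either variable, and subjects with fewer than two
observations are dropped with a record. `r_squared_rm = r_rm^2`. Paired
t-tests (two-sided; zero-variance differences reported as infinite t
with a flag), Shapiro–Wilk, and the two-sided variance-ratio F-test
round out the distributional gates; these delegate to scipy where scipy
provides the statistic.

## Synthetic generator

The generator emulates the study design the validation chain targets:
two hip-worn monitors observing the same latent movement.

* **Day structure.** A wear day (default 732 min, with a 30-min midday
  nonwear gap) alternates sedentary runs and activity bouts with
  geometric lengths (mean bout 14 epochs; sedentary fraction 0.7, so
  ~220 active min/day). Sedentary epochs carry incidental movement —
  exponential counts with mean 13 — so roughly 14% of epochs in the
  coarse scheme's first bin land above the sedentary cutpoint, as
  observed for real hip data.
* **Intensity.** Bout epochs draw intensity i.i.d. from a truncated power
  law `p(m) ∝ m^beta` on [100, 4000] counts (default β = −2). The i.i.d.
  choice is deliberate: holding intensity constant within a bout
  quantises bin occupancy (one bout → one bin), which biases any
  log-binned OLS slope shallow regardless of sample size; with i.i.d.
  draws the realized time-at-intensity follows the target law exactly.
  Real bouts are autocorrelated — a known mismatch with free-living data.
  The support edges keep the midpoint approximation accurate (the
  deterministic curvature bias of the fit is ≤ 0.025 for every scheme at
  β ∈ [−2.5, −1.5]).
* **Devices.** `counts = round(clip(gain * I * (1 + cv * eps)))` with
  gain 1.0 (reference device) and 0.95 (test device), multiplicative
  noise cv = 0.10, saturation at 6000. Multiplicative noise reproduces
  the widening of limits of agreement at vigorous intensities seen in
  paired-device studies, and yields an in-lab regression slope of ~0.94.
  An integer epoch lag (fixed or drawn per session: mostly 0 or ≤ 10
  epochs, occasionally 229) delays the test device's stream.
* **Raw signal.** Per epoch the test device's raw 30 Hz stream is gravity
  plus a vertical sinusoid at 1.6 Hz whose amplitude is chosen by
  inverting the closed-form truncated-ENMO response so that the expected
  epoch ENMO equals `0.3 mg/count × counts`. The 0.3 scale makes counts
  occupy ~2.5× more fine bins than ENMO — inside the 2.3–5.2 band
  reported for real paired data — and drives the fine-binned count IG
  shallower than the acceleration IG, the central phenomenon the
  adjusted scheme corrects.
* **Count emulation.** The approximate counts-from-raw chain (2nd-order
  Butterworth band-pass 0.25–2.5 Hz applied forward–backward, rectify,
  0.05 g dead-band, 2.5 g clip, scaled per-epoch accumulation) mimics the
  documented behaviour of uniaxial count devices. It makes no claim of
  matching any vendor's proprietary algorithm. The dead-band censors
  counts below ~53; rank order is preserved essentially perfectly above
  it (Spearman ρ > 0.99 over a simulated day).
* **Determinism.** Every output is a pure function of
  `(seed, participant, day)` via per-purpose seed-sequence substreams.

What the generator does **not** emulate: physiologically validated
activity profiles, energy expenditure, idle-sleep-mode artefacts,
temperature effects, clock drift, or autocorrelated bout intensity.
Passing end-to-end tests therefore demonstrates correctness of the
processing chain under a controlled data-generating model, not
device-level fidelity to any real cohort.

## Parameter-recovery protocol

`ig_recovery_slopes` fits the IG on bout epochs only (the sedentary
background is not part of the power law) and restricts the regression to
bins that are (a) fully inside the generating support — with a margin of
three noise SDs when device noise applies — and (b) expected to contain
at least 10 epochs under the configured law. Both limits are computed
analytically from the configuration, never from the realized sample.
The occupancy floor is the standard guard against the sparse-tail bias
of log-binned power-law fits: a tail bin that happens to be occupied
contributes one epoch's time however small its expectation, sitting
systematically above the log-log line. Recovery experiments use 10 days
per participant (~8800 active epochs), which makes the mean recovered
slope accurate to within ~0.05 of the generating exponent for every
scheme across β ∈ {−1.5, −2, −2.5}.

Full-day IGs (sedentary mass included) are deliberately *not* expected to
equal β: the sedentary lump in the first bin steepens every variant, and
coarser schemes concentrate it more — which is precisely the behaviour
the three-scheme comparison exists to study.

## Degenerate inputs and numerical conventions

Fewer than 2 occupied bins: IG undefined (error). Constant series: lag
correlation undefined (error). Zero-variance differences: BA limits
collapse to the bias; paired t reported as infinite with a flag. ICC
denominators ≤ 0 are clamped to 0 with a warning; estimates are clipped
to [−1, 1]. The lag tie-break (smallest |k|, then negative) cannot be
antisymmetric on exact ±k correlation ties; such ties occur with
probability zero for continuous-noise series.

## Limitations

The agreement module handles exactly two raters/methods (the paired
design it serves). The BA confidence intervals are approximate under
clustering. The emulated counts are order-faithful but not
magnitude-calibrated to any commercial device. Wear detection is
log-based only; no algorithmic nonwear detection is included.
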