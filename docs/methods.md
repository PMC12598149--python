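# Methods

## Scope and data model

The package operates on ROI × frame fluorescence matrices (ΔF/F or raw
units) with an optional matched neuropil matrix, sampled at a stated frame
rate (default 10 Hz, recordings up to tens of minutes).  Image-plane work —
motion correction, segmentation, pixel-level background subtraction — is
assumed done upstream; every stage here is the trace-level analog of the
corresponding image-level operation.

## Synthetic recordings

The generator realizes the statistical structure the analysis assumes, so
that ground truth exists for every downstream quantity.

**Spike trains.** Each active ROI emits an alternating renewal process:
exponential interburst gaps (mean `interburst_mean_s`), bursts of
`events_per_burst_min` (≥ 3) plus a geometric excess of events, Gaussian
within-burst intervals (mean `intraburst_mu_s` = 2.0 s, SD
`intraburst_sigma_s` = 0.5 s) left-truncated at `interval_floor_s` = 0.2 s
(two frames at 10 Hz — shorter intervals are unresolvable).  Interburst
gaps share the floor so every interpeak interval respects it.  A burst
truncated by the end of the recording keeps its realized events; its
window is recorded only if at least the minimum number of events landed
inside the recording, so every recorded burst satisfies the ≥ 3 rule.

**Rendering.** Spikes are convolved with a peak-normalized difference of
exponentials (rise 0.08 s, decay 0.6 s — a fast-indicator stand-in; both
configurable because real indicator kinetics vary) evaluated at the exact
continuous spike offsets, in the linear regime (no saturation).  Added
nuisance terms: white sensor noise; a slow per-ROI sinusoidal drift; and
one low-frequency background trace shared by all ROIs, scaled into each
fluorescence trace by a true contamination coefficient (default 0.7) and
observed (plus independent noise) as the neuropil channel.  This is the
minimal structure that makes neuropil subtraction testable; it does not
emulate photobleaching, movement artifacts, spatially varying
contamination, or indicator nonlinearity, so passing tests say nothing
about those failure modes in real data.

**Presets.** Four named presets pair a stimulus (TI = TASK-inhibitor
cocktail, AngII = angiotensin II) with an osmolarity (280 mOsm permissive,
310 mOsm suppressive).  280-presets have higher active-cell probability
(0.65–0.70 vs 0.35), shorter interburst means (20–22 s vs 45–50 s) and
heavier burst-length tails (geometric p 0.25–0.30 vs 0.60); the
within-burst interval distribution is identical across presets.  These
values are chosen to produce the qualitative contrast the experimental
conditions show — an order-of-magnitude difference in time spent bursting —
at 20 ROIs × 600 s per dataset.

**Seeding.** One master seed; ROI *i* draws from a stream keyed by
`(seed, i)`, so enlarging `n_roi` leaves earlier ROIs bit-identical, and a
separate dataset-level stream drives the shared background.

## Trace conditioning

Fixed stage order: neuropil subtraction → rolling baseline → QC →
deconvolution.

- **Neuropil subtraction** `F − c·Fneu`, c ∈ [0, 1], default 0.7
  (config-exposed; no universal value exists).
- **Rolling baseline**: centered running 10th percentile over a 60 s
  window (edges clamped), subtracted.  Because a low percentile of a noisy
  trace sits ~1.28 SD below the noise center, the detrended trace is then
  re-centered at its median (`condition_trace`); downstream noise-relative
  thresholds assume a zero baseline.
- **SD-ratio QC**: SDs in 60 s windows at half-window stride; an ROI fails
  if max SD / min SD exceeds 6 (floored denominator, so a flat-then-noisy
  trace fails rather than dividing by zero).  The ratio is scale-invariant.

## Deconvolution

Event amplitudes are recovered by the nonnegative sparse AR(1) program

    minimize ½‖y − c‖² + λ Σ s,   s_t = c_t − γ c_{t−1} ≥ 0,  c ≥ 0,

with γ = exp(−1/(f_s τ_decay)), solved exactly by a single forward pass
with pool-adjacent-violators-style merging (pool heights clamped at zero).
The ℓ1 penalty enters as a constant shift λ(1−γ) on the working data, so a
noise-proportional default λ = 2·σ̂/(1−γ) is used when none is given
(σ̂ = robust noise SD of the input trace).  The solution is verified
against a generic constrained quadratic solver on small instances in the
tests (objective agreement to 1e−6; observed ~1e−12).

## Transient detection

Staged rules on the deconvolved sequence `s` and the conditioned
fluorescence `f`:

(i) keep frames with `s` above 5% of its maximum; (ii) one candidate per
contiguous run, at the run's largest `s`; (iii) move each candidate to the
fluorescence maximum within ± 5 frames (± 0.5 s), collapsing duplicates to
the larger amplitude, ties to the earlier frame; (iv) drop events whose
fluorescence amplitude is below 3 noise SDs; (v) a moving filter removes
events smaller than 15% of the largest deconvolved amplitude within
± 10 frames (minor fluctuations riding on large transients).

Two numerical choices matter at realistic SNR.  Alignment and amplitude
readout use a 3-frame boxcar-smoothed copy of the fluorescence (the
amplitude threshold is scaled by 1/√3 to match the smoothed noise level):
the argmax of a raw noisy trace jitters by several frames around a
flat-topped indicator peak, and the smoothing removes most of that jitter
without moving the true peak.  Noise is estimated as
`MAD(diff(f)) / (√2 · 0.6745)`, insensitive to sparse transients.

**Validation** correlates each event's local fluorescence segment with the
indicator template (kernel from onset, its maximum aligned to the event
peak, window ending ~3 decay constants past the peak) and additionally
bounds the residual SD after least-squares template scaling at 2 noise
SDs.  The window is clipped at the next detected event's onset — inside
bursts the following transient would otherwise count against the current
one.  The correlation floor is 0.45: calibrated so that an event planted
on pure noise is rejected ≥ 95% of the time while true in-burst events
(short clipped windows, overlapping tails) survive.  Unvalidated events
are kept in the event table, flagged, and excluded from metrics.

All thresholds are per-run configuration with optional per-ROI overrides
(real recordings were tuned per ROI; the synthetic benchmark uses the
global defaults throughout).

## Burst analysis

**Mixture fit.** Pooled interpeak intervals (validated events, per
recording by default) are fitted with a Gaussian + exponential mixture by
EM: responsibilities from the weighted densities; closed-form M-steps for
the weights and the exponential rate; convergence at log-likelihood gain
< 1e−8 or 500 iterations; best of 5 restarts (median-split initialization,
multiplicative perturbations).  The Gaussian component is modeled as
*left-truncated* at the 0.2 s interval floor: with within-burst parameters
in the regime of interest (μ ≈ 2σ above zero is not guaranteed) the
sub-floor Gaussian mass is ~10%, and ignoring it biases μ and σ upward
enough to shift the derived threshold by ~0.5 s.  The truncated M-step
maximizes the expected complete-data likelihood through its three weighted
sufficient statistics (a cheap 2-parameter inner optimization); setting
the floor to 0 restores the plain closed-form EM.

**Threshold.** The burst ceiling is the root of
`w_g N(x) = (1−w_g) λ e^{−λx}` bracketed in [μ, μ + 10σ] (grid scan for
the sign change, then Brent's method, |f| < 1e−10).  A left-tail crossing
is deliberately ignored — it would cap bursts below the typical
within-burst interval.  If the densities do not cross (e.g. w_g → 1), the
pipeline falls back to a configured fixed threshold; the fixed values
5.6 s (TI) and 5.3 s (AngII) are also the recommended setting when a
recording yields too few intervals for a stable fit (< 50 by default).

**Segmentation and metrics.** Bursts are maximal runs of ≥ 3 consecutive
events with all adjacent intervals strictly below the threshold.  Burst
duration is onset-to-offset of event peaks (decay tails excluded); the
fraction of time bursting is Σ durations / analyzed duration; the
intraburst period averages all adjacent-event intervals inside bursts; an
ROI is "active" with ≥ 3 transients, and active-cell density divides the
active count by the zG area (µm²).  Binned rates use 1-minute bins.
Quantities undefined without bursts are reported as missing, never zero.

## Secretion

Fold change = post / baseline per slice; each animal's mean vehicle fold
then normalizes all of that animal's conditions (vehicle mean ≡ 1 exactly;
animals without vehicle slices are excluded with a warning).  Replicate
slices are averaged per animal × condition before group summaries; raw
slice values are retained.  Dose-response curves use a four-parameter
logistic in linear x, `bottom + (top − bottom)/(1 + e^{−slope(x − mid)})`,
least-squares with quartile self-start, midpoint bounded within the data
range ± one span, restarts, and R² = 1 − SSres/SStot; fits are
canonicalized to top ≥ bottom and flagged when degenerate
(constant y → R² = 0).  The same family serves secretion-vs-osmolarity
and secretion-vs-fractional-active-time; a saturating relationship with a
different parametric form would need only a drop-in model function.

## Pipeline and windowing

A single config (YAML or `Config`) governs a run; runs write their
resolved config and a manifest (seed, config hash, stage funnel counts,
output files).  The analysis window supports a start/end and excluded
spans (e.g. a 5-minute equilibration after a solution switch): events
inside excluded spans are dropped and the excluded time is subtracted from
the duration used for time-normalized metrics.  Identical config + seed
reproduces outputs byte-for-byte.

## Problem sizes in tests

The test suite and drivers use 10–20 ROIs × 600 s recordings, 20 seeds for
condition contrasts, 50,000 intervals for mixture-recovery checks, 10⁴
random event trains against the segmentation oracle, and ≤ 40-frame
instances against the quadratic-program oracle — sizes at which every
check is exact or has comfortable Monte-Carlo margin.

## Known limitations

- Validation and detection assume a roughly stationary noise floor; slow
  noise-level changes are only caught by the QC stage.
- The AR(1) deconvolution ignores the indicator rise time (~1 frame at
  10 Hz); event amplitude therefore splits over 1–2 frames of `s`, which
  the run-merging stage absorbs.
- The interval mixture pools intervals across ROIs by default; per-ROI
  rate heterogeneity broadens the exponential component and can shift the
  fitted threshold slightly.
- Fraction-active time uses peak-to-peak burst duration; including decay
  tails would scale it by a roughly constant factor.
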