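# caburst

Trace-level analysis of oscillatory Ca²⁺ signaling in adrenal zona
glomerulosa (zG) cells, for experiments that relate bursting activity to
aldosterone secretion under different stimulation and osmolarity
conditions.

zG cells assembled in rosettes fire Ca²⁺ transients in *bursts*: runs of
regularly spaced fluorescence peaks separated by long silent gaps.  Given
per-ROI GCaMP fluorescence traces (extracted upstream by a segmentation
tool), the package

1. conditions each trace (neuropil subtraction, rolling-percentile
   baseline removal, windowed-SD quality control),
2. recovers event amplitudes by sparse nonnegative AR(1) deconvolution,
3. detects and validates Ca²⁺ transients with a dual-threshold /
   peak-alignment / moving-filter rule set,
4. derives the burst-defining interval threshold from a Gaussian +
   exponential interpeak-interval mixture, segments bursts, and computes
   activity metrics (active-cell density, burst counts and durations,
   fraction of time bursting, intraburst period, binned rates), and
5. normalizes per-slice aldosterone measurements (fold over baseline,
   vehicle-normalized per animal) and fits 4-parameter-logistic
   dose-response curves.

A synthetic-data module generates ground-truth bursting trains rendered as
noisy indicator traces under named condition presets, so the whole pipeline
is testable without the (non-public) recordings.

## The burst threshold

Interpeak intervals pooled over bursting cells follow a two-component
mixture: within-burst intervals are approximately Gaussian, between-burst
gaps approximately exponential,

    p(x) = w_g · N(x; μ, σ²) + (1 − w_g) · λ e^{−λx}.

The maximum interval that still counts as "within a burst" is the crossing
point of the two weighted component densities above the Gaussian mean,

    w_g · N(x*; μ, σ²) = (1 − w_g) · λ e^{−λx*},   x* > μ.

With μ = 2.0 s, σ = 1.5 s, λ = 1/15 s⁻¹ this gives x* = 5.60 s at
w_g = 0.7545 (TASK-inhibitor stimulation) and x* = 5.30 s at w_g = 0.6644
(angiotensin II).  A burst is ≥ 3 consecutive transients whose adjacent
intervals all fall below x*.

## Worked example

```sh
python analysis/01_simulate.py        # four condition presets -> results/sim/
python analysis/02_analyze_traces.py  # full pipeline on each preset
python analysis/03_burst_threshold.py # mixture intersection + EM refit
python analysis/04_secretion.py       # secretion normalization + 4PL fit
```

`02_analyze_traces.py` prints the per-condition summary (20 ROIs, 600 s at
10 Hz per condition):

```
   preset  rois_passed_qc  events  validated  bursts  mean_fraction_active  mean_burst_duration_s  mean_intraburst_period_s
   TI-280              20    2063       1992     250                 0.308                 14.886                     2.136
   TI-310              20     273        264      63                 0.035                  6.869                     2.179
AngII-280              20    1439       1388     195                 0.211                 13.148                     2.135
AngII-310              20     264        249      59                 0.031                  6.396                     2.166
```

Reading it: the permissive 280 mOsm conditions produce many more validated
transients, more and longer bursts, and an order of magnitude more time
spent bursting than the suppressive 310 mOsm conditions — while the
intraburst period stays at ~2.1 s everywhere, the invariant the analysis is
designed to expose.  `03_burst_threshold.py` prints the two crossing points
(5.5998 s and 5.3000 s) and an EM refit of 50,000 sampled intervals whose
recomputed threshold lands at 5.578 s.

The same stages are scriptable through the CLI (`caburst simulate`,
`caburst analyze`, `caburst secretion`, `caburst report`) with a YAML
config; every run writes its resolved config and a manifest with stage
counts.

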