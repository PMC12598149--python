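"""Run the full trace analysis on each simulated condition.

Pipeline per ROI: neuropil subtraction -> rolling-baseline detrend ->
SD-ratio QC -> sparse nonnegative deconvolution -> dual-threshold transient
detection -> template validation -> burst segmentation (threshold fixed at
the condition's mixture-intersection value) -> activity metrics.

Writes events/bursts/metrics tables under results/analysis/<preset>/ and
prints the per-condition activity summary (the osmolarity contrast).
"""

from pathlib import Path

import pandas as pd

from caburst.pipeline import Config, run_analyze

THRESHOLDS = {"TI": 5.6, "AngII": 5.3}  # seconds, per stimulation condition

rows = []
for preset in ["TI-280", "TI-310", "AngII-280", "AngII-310"]:
    stim = preset.split("-")[0]
    cfg = Config(
        traces_csv=f"results/sim/{preset}/traces.csv",
        out_dir=f"results/analysis/{preset}",
        seed=1,
        burst_threshold_mode="fixed",
        burst_fixed_threshold_s=THRESHOLDS[stim],
    )
    manifest = run_analyze(cfg)
    per_roi = pd.read_csv(Path(cfg.out_dir) / "metrics_roi.csv")
    rows.append(
        {
            "preset": preset,
            "rois_passed_qc": manifest.counts["rois_passed_qc"],
            "events": manifest.counts["events"],
            "validated": manifest.counts["validated"],
            "bursts": manifest.counts["bursts"],
            "mean_fraction_active": per_roi["fraction_active"].mean(),
            "mean_burst_duration_s": per_roi["mean_burst_duration_s"].mean(),
            "mean_intraburst_period_s": per_roi["intraburst_period_s"].mean(),
        }
    )

summary = pd.DataFrame(rows)
out = Path("results/analysis/summary.csv")
summary.to_csv(out, index=False)
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nwrote {out}")
print(
    "\nExpected contrast: the 280 mOsm presets show more validated events, "
    "more and longer bursts and higher fraction-active than their 310 mOsm "
    "counterparts, with the intraburst period essentially unchanged."
)
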