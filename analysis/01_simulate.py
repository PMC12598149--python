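"""Generate synthetic adrenal-slice recordings under the four condition presets.

Each preset pairs a stimulus (TASK-inhibitor cocktail or angiotensin II)
with an extracellular osmolarity (280 mOsm permissive, 310 mOsm
suppressive).  Presets share the within-burst interval distribution and
differ only in active-cell fraction, burst rate and burst length — the
structure the downstream analysis is supposed to recover.

Writes per-preset trace CSVs, ground-truth manifests and a run manifest
under results/sim/.
"""

import json

from caburst.pipeline import Config, run_simulate

cfg = Config(out_dir="results/sim", n_roi=20, seed=1)
manifest = run_simulate(cfg)

print("simulated presets (20 ROIs x 600 s at 10 Hz):")
for preset, counts in manifest.counts.items():
    print(
        f"  {preset:10s} active {counts['n_active_true']:2d}/20  "
        f"spikes {counts['n_spikes_true']:5d}  bursts {counts['n_bursts_true']:4d}"
    )
print(json.dumps(manifest.files, indent=1))
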