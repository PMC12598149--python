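"""End-to-end orchestration: configuration, windowing, manifests, file I/O.

A run is governed by a single config (YAML on disk or a ``Config`` object);
every run writes its resolved config and a manifest (seed, stage counts,
output files) next to its outputs so results are traceable.  The analysis
stage applies the fixed order neuropil subtraction -> rolling baseline ->
SD-ratio QC -> deconvolution -> detection -> validation -> burst
segmentation -> metrics, restricted to a configurable analysis window with
optional excluded spans (e.g. an equilibration period after a solution
switch).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bursts as bursts_mod
from . import preprocess as pre
from . import synthetic as syn
from . import transients as tr

__all__ = ["Config", "RunManifest", "load_config", "run_simulate", "run_analyze"]

log = logging.getLogger("caburst")


@dataclass
class Config:
    out_dir: str = "results/run"
    traces_csv: str | None = None
    seed: int = 0
    fs_hz: float = 10.0
    zg_area_um2: float = 4000.0
    # simulate
    presets: list[str] = field(default_factory=lambda: list(syn.PRESETS))
    n_roi: int = 20
    # analyze
    neuropil_coeff: float = 0.7
    qc: pre.QCParams = field(default_factory=pre.QCParams)
    deconv: pre.DeconvParams = field(default_factory=pre.DeconvParams)
    detection: tr.DetectionParams = field(default_factory=tr.DetectionParams)
    per_roi_overrides: dict = field(default_factory=dict)
    burst_threshold_mode: str = "fit"  # "fit" | "fixed"
    burst_fixed_threshold_s: float = 5.6
    burst_min_events: int = 3
    min_intervals_for_fit: int = 50
    window_start_s: float = 0.0
    window_end_s: float | None = None
    excluded_spans_s: list[tuple[float, float]] = field(default_factory=list)

    def resolved(self) -> dict:
        d = asdict(self)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> Config:
    """Load a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, val in raw.items():
        if key == "qc":
            kwargs["qc"] = pre.QCParams(**val)
        elif key == "deconv":
            kwargs["deconv"] = pre.DeconvParams(**val)
        elif key == "detection":
            kwargs["detection"] = tr.DetectionParams(**val)
        elif key == "excluded_spans_s":
            kwargs["excluded_spans_s"] = [tuple(map(float, s)) for s in val]
        elif key in Config.__dataclass_fields__:
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config key: {key}")
    return Config(**kwargs)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = "0.1.0"
    files: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1))


def _write_resolved_config(config: Config, out: Path) -> None:
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True)
    )


def run_simulate(config: Config) -> RunManifest:
    """Generate one dataset per configured preset; write traces and truth."""
    if not config.presets:
        raise ValueError("nothing to simulate: preset list is empty")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_resolved_config(config, out)
    manifest = RunManifest(config_hash=config.content_hash(), seed=config.seed)
    for preset in config.presets:
        ds = syn.generate_dataset(
            preset,
            n_roi=config.n_roi,
            seed=config.seed,
            fs_hz=config.fs_hz,
            zg_area_um2=config.zg_area_um2,
        )
        paths = ds.write(out / preset)
        manifest.files[preset] = paths
        manifest.counts[preset] = {
            "n_roi": ds.n_roi,
            "n_active_true": ds.ground_truth.n_active(),
            "n_spikes_true": int(
                sum(r.spike_times_s.size for r in ds.ground_truth.rois)
            ),
            "n_bursts_true": int(
                sum(len(r.bursts) for r in ds.ground_truth.rois)
            ),
        }
        log.info("simulated %s: %s", preset, manifest.counts[preset])
    manifest.write(out / "manifest.json")
    return manifest


def read_traces_csv(path: str | Path, fs_hz: float) -> pre.TraceSet:
    """Read a long-format trace table (roi_id, frame, F[, Fneu])."""
    df = pd.read_csv(path)
    needed = {"roi_id", "frame", "F"}
    if not needed.issubset(df.columns):
        raise ValueError(f"trace CSV must have columns {sorted(needed)}")
    wide_f = df.pivot(index="roi_id", columns="frame", values="F").sort_index()
    if wide_f.isna().any().any():
        raise ValueError("missing frames in trace CSV")
    Fneu = None
    if "Fneu" in df.columns:
        Fneu = (
            df.pivot(index="roi_id", columns="frame", values="Fneu")
            .sort_index()
            .to_numpy()
        )
    return pre.TraceSet(
        F=wide_f.to_numpy(), fs_hz=fs_hz, Fneu=Fneu, roi_ids=list(wide_f.index)
    )


def _window_mask_times(
    times: np.ndarray, config: Config, duration_s: float
) -> np.ndarray:
    keep = times >= config.window_start_s
    end = config.window_end_s if config.window_end_s is not None else duration_s
    keep &= times <= end
    for a, b in config.excluded_spans_s:
        keep &= ~((times >= a) & (times <= b))
    return keep


def _effective_duration(config: Config, duration_s: float) -> float:
    end = min(
        config.window_end_s if config.window_end_s is not None else duration_s,
        duration_s,
    )
    dur = max(end - config.window_start_s, 0.0)
    for a, b in config.excluded_spans_s:
        lo = max(a, config.window_start_s)
        hi = min(b, end)
        dur -= max(hi - lo, 0.0)
    return dur


def analyze_traceset(
    traces: pre.TraceSet, config: Config
) -> dict:
    """Library entry point for the analysis stage; returns all artifacts.

    Returns a dict with keys: qc (DataFrame), events (TransientSet),
    bursts_by_roi, mixture (IntervalMixture | None), threshold_s, metrics
    (ActivityMetrics), counts (stage funnel).
    """
    n_roi, n_frames = traces.F.shape
    duration_s = n_frames / traces.fs_hz
    kernel = syn.indicator_kernel(
        syn.IndicatorParams(decay_tau_s=config.deconv.decay_tau_s),
        traces.fs_hz,
    )
    # validation window: kernel rise to ~3 decay constants past the peak
    kernel = kernel[
        : int(np.argmax(kernel))
        + int(np.ceil(3 * config.deconv.decay_tau_s * traces.fs_hz))
        + 1
    ]
    qc_rows = []
    events_by_roi: dict = {}
    validated_times: dict = {}
    counts = {"rois_in": n_roi, "rois_passed_qc": 0, "events": 0, "validated": 0}
    for i, roi_id in enumerate(traces.roi_ids):
        f = pre.condition_trace(
            traces.F[i],
            None if traces.Fneu is None else traces.Fneu[i],
            config.neuropil_coeff,
            config.deconv.baseline_window_frames,
            config.deconv.baseline_percentile,
        )
        qc = pre.sd_ratio_qc(f, config.qc)
        qc_rows.append(
            {
                "roi_id": roi_id,
                "min_sd": qc.min_sd,
                "max_sd": qc.max_sd,
                "ratio": qc.ratio,
                "passed": qc.passed,
            }
        )
        if not qc.passed:
            log.warning("ROI %s excluded by SD-ratio QC (ratio %.2f)", roi_id, qc.ratio)
            continue
        counts["rois_passed_qc"] += 1
        det_params = config.detection
        if roi_id in config.per_roi_overrides:
            det_params = tr.DetectionParams(
                **{**asdict(det_params), **config.per_roi_overrides[roi_id]}
            )
        dec = pre.deconvolve(f, config.deconv, traces.fs_hz)
        noise = tr.estimate_noise(f)
        evs = tr.detect_transients(
            dec, f, det_params, noise, roi_id=roi_id, fs_hz=traces.fs_hz
        )
        evs = tr.validate_transients(evs, f, kernel, det_params, noise)
        # analysis window: drop events outside / in excluded spans
        times = np.array([e.peak_time_s for e in evs])
        if times.size:
            keep = _window_mask_times(times, config, duration_s)
            evs = [e for e, k in zip(evs, keep) if k]
        counts["events"] += len(evs)
        counts["validated"] += sum(e.validated for e in evs)
        events_by_roi[roi_id] = evs
        validated_times[roi_id] = np.array(
            [e.peak_time_s for e in evs if e.validated]
        )
        if len(evs) and np.mean([not e.validated for e in evs]) > 0.5:
            log.warning("ROI %s: >50%% of events unvalidated", roi_id)

    # burst threshold: pooled mixture fit, or the configured fixed value
    mixture = None
    threshold = config.burst_fixed_threshold_s
    if config.burst_threshold_mode == "fit":
        pooled = np.concatenate(
            [np.diff(t) for t in validated_times.values() if t.size >= 2]
        ) if validated_times else np.empty(0)
        pooled = pooled[pooled > 0]
        if pooled.size >= config.min_intervals_for_fit:
            try:
                mixture = bursts_mod.fit_interval_mixture(pooled)
                threshold = bursts_mod.mixture_intersection(mixture)
            except (bursts_mod.NoIntersectionError, bursts_mod.DegenerateFitError):
                log.warning(
                    "mixture intersection unavailable; falling back to fixed "
                    "threshold %.2f s", threshold,
                )
        else:
            log.warning(
                "only %d intervals (< %d); using fixed threshold %.2f s",
                pooled.size, config.min_intervals_for_fit, threshold,
            )
    defn = bursts_mod.BurstDefinition(
        max_interval_s=threshold, min_events=config.burst_min_events
    )
    bursts_by_roi = {
        roi_id: bursts_mod.segment_bursts(t, defn, roi_id=roi_id)
        for roi_id, t in validated_times.items()
    }
    eff_dur = _effective_duration(config, duration_s)
    metrics = bursts_mod.compute_metrics(
        validated_times,
        bursts_by_roi,
        duration_s=eff_dur if eff_dur > 0 else duration_s,
        zg_area_um2=config.zg_area_um2,
        fs_hz=traces.fs_hz,
    )
    tset = tr.TransientSet(
        events_by_roi=events_by_roi, duration_s=duration_s, fs_hz=traces.fs_hz
    )
    return {
        "qc": pd.DataFrame(qc_rows),
        "events": tset,
        "bursts_by_roi": bursts_by_roi,
        "mixture": mixture,
        "threshold_s": threshold,
        "metrics": metrics,
        "counts": counts,
    }


def run_analyze(config: Config) -> RunManifest:
    """File-level analysis run: read traces CSV, write all output tables."""
    if config.traces_csv is None:
        raise FileNotFoundError("config.traces_csv is not set")
    path = Path(config.traces_csv)
    if not path.exists():
        raise FileNotFoundError(f"input traces not found: {path}")
    traces = read_traces_csv(path, config.fs_hz)
    res = analyze_traceset(traces, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_resolved_config(config, out)
    manifest = RunManifest(config_hash=config.content_hash(), seed=config.seed)

    res["qc"].to_csv(out / "qc.csv", index=False)
    res["events"].to_frame().to_csv(out / "events.csv", index=False)
    burst_rows = [
        {
            "roi_id": b.roi_id,
            "onset_s": b.onset_s,
            "offset_s": b.offset_s,
            "duration_s": b.duration_s,
            "n_events": b.n_events,
        }
        for bl in res["bursts_by_roi"].values()
        for b in bl
    ]
    pd.DataFrame(
        burst_rows, columns=["roi_id", "onset_s", "offset_s", "duration_s", "n_events"]
    ).to_csv(out / "bursts.csv", index=False)
    res["metrics"].per_roi.to_csv(out / "metrics_roi.csv", index=False)
    slice_report = {
        "n_active_rois": res["metrics"].n_active_rois,
        "active_cell_density_per_um2": res["metrics"].active_cell_density_per_um2,
        "binned_rate_hz": [float(v) for v in res["metrics"].binned_rate_hz],
        "threshold_s": float(res["threshold_s"]),
    }
    (out / "metrics_slice.json").write_text(json.dumps(slice_report, indent=1))
    mix_report = {
        "threshold_s": float(res["threshold_s"]),
        "mode": config.burst_threshold_mode,
        "mixture": res["mixture"].to_dict() if res["mixture"] else None,
    }
    (out / "mixture.json").write_text(json.dumps(mix_report, indent=1))
    manifest.files = {
        name: str(out / name)
        for name in [
            "qc.csv", "events.csv", "bursts.csv",
            "metrics_roi.csv", "metrics_slice.json", "mixture.json",
        ]
    }
    manifest.counts = dict(res["counts"])
    manifest.counts["bursts"] = len(burst_rows)
    manifest.write(out / "manifest.json")
    if manifest.counts["rois_passed_qc"] == 0:
        log.warning("all ROIs failed QC; metrics are empty")
    return manifest
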