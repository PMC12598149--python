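"""Synthetic GCaMP6f-like fluorescence traces with known burst structure.

Zona glomerulosa cells in intact rosettes fire calcium transients in bursts:
within a burst, interpeak intervals are tightly clustered (approximately
Gaussian), while the gaps between bursts are long and irregular
(approximately exponential).  The generator realizes exactly this alternating
renewal structure, renders the resulting spike trains through a fast
calcium-indicator kernel, and adds the nuisance terms the preprocessing
stages are built to remove: white sensor noise, slow per-cell drift, and a
low-frequency background shared across all ROIs (the "neuropil"
contamination of widefield slice imaging).

Condition presets mimic the experimental contrasts of interest (stimulus x
osmolarity): they differ in the fraction of active cells, the burst rate and
the burst-length distribution, but never in the within-burst period — the
invariant the downstream metrics are supposed to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BurstTrainParams",
    "IndicatorParams",
    "NoiseParams",
    "GroundTruth",
    "SyntheticDataset",
    "PRESETS",
    "sample_burst_train",
    "indicator_kernel",
    "render_trace",
    "generate_dataset",
    "sample_interval_mixture",
]


@dataclass(frozen=True)
class BurstTrainParams:
    """Parameters of the alternating burst/gap renewal process.

    ``interburst_mean_s`` is the mean of the exponential gap from the last
    event of one burst to the first event of the next; ``intraburst_mu_s``
    and ``intraburst_sigma_s`` give the Gaussian within-burst interpeak
    interval, truncated below at ``interval_floor_s`` so no two events fall
    closer than the detector's frame resolution.  Events per burst are
    ``events_per_burst_min`` plus a geometric excess with success
    probability ``events_per_burst_geom_p``.
    """

    interburst_mean_s: float = 30.0
    intraburst_mu_s: float = 2.0
    intraburst_sigma_s: float = 0.5
    events_per_burst_min: int = 3
    events_per_burst_geom_p: float = 0.35
    active_prob: float = 0.8
    duration_s: float = 600.0
    interval_floor_s: float = 0.2

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.interburst_mean_s <= 0 and not np.isinf(self.interburst_mean_s):
            raise ValueError("interburst_mean_s must be positive (or inf)")
        if not (self.intraburst_mu_s > self.interval_floor_s > 0):
            raise ValueError("need intraburst_mu_s > interval_floor_s > 0")
        if self.intraburst_sigma_s <= 0:
            raise ValueError("intraburst_sigma_s must be positive")
        if self.events_per_burst_min < 3:
            raise ValueError("events_per_burst_min must be >= 3")
        if not (0 < self.events_per_burst_geom_p <= 1):
            raise ValueError("events_per_burst_geom_p must be in (0, 1]")
        if not (0 <= self.active_prob <= 1):
            raise ValueError("active_prob must be in [0, 1]")


@dataclass(frozen=True)
class IndicatorParams:
    """Difference-of-exponentials indicator response, peak-normalized.

    Defaults approximate a fast GCaMP variant (rise ~80 ms, decay ~600 ms).
    """

    rise_tau_s: float = 0.08
    decay_tau_s: float = 0.6
    unit_amplitude_dff: float = 1.0

    def __post_init__(self) -> None:
        if not (self.decay_tau_s > self.rise_tau_s > 0):
            raise ValueError("need decay_tau_s > rise_tau_s > 0")
        if self.unit_amplitude_dff < 0:
            raise ValueError("unit_amplitude_dff must be nonnegative")


@dataclass(frozen=True)
class NoiseParams:
    """Additive nuisance terms: white noise, slow drift, shared background."""

    white_sd_dff: float = 0.1
    drift_amplitude_dff: float = 0.05
    drift_period_s: float = 300.0
    neuropil_coeff_true: float = 0.7
    background_amplitude_dff: float = 0.3
    background_period_s: float = 200.0

    def __post_init__(self) -> None:
        for name in (
            "white_sd_dff",
            "drift_amplitude_dff",
            "drift_period_s",
            "neuropil_coeff_true",
            "background_amplitude_dff",
            "background_period_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class RoiTruth:
    active: bool
    spike_times_s: np.ndarray
    bursts: list[tuple[float, float, int]]  # (start_s, end_s, n_events)


@dataclass
class GroundTruth:
    rois: list[RoiTruth] = field(default_factory=list)

    def n_active(self) -> int:
        return sum(r.active for r in self.rois)

    def to_jsonable(self) -> dict:
        return {
            "rois": [
                {
                    "active": bool(r.active),
                    "spike_times_s": [float(t) for t in r.spike_times_s],
                    "bursts": [
                        [float(a), float(b), int(n)] for a, b, n in r.bursts
                    ],
                }
                for r in self.rois
            ]
        }


@dataclass
class SyntheticDataset:
    F: np.ndarray
    Fneu: np.ndarray
    fs_hz: float
    zg_area_um2: float
    condition: str
    seed: int
    ground_truth: GroundTruth

    @property
    def n_roi(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs_hz

    def to_long_frame(self) -> pd.DataFrame:
        n_roi, n_frames = self.F.shape
        return pd.DataFrame(
            {
                "roi_id": np.repeat(np.arange(n_roi), n_frames),
                "frame": np.tile(np.arange(n_frames), n_roi),
                "F": self.F.ravel(),
                "Fneu": self.Fneu.ravel(),
            }
        )

    def write(self, out_dir: str | Path, wide: bool = False) -> dict[str, str]:
        """Write traces (long CSV), optional wide CSV and truth manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        traces = out / "traces.csv"
        self.to_long_frame().to_csv(traces, index=False)
        paths["traces"] = str(traces)
        if wide:
            wide_path = out / "traces_wide.csv"
            pd.DataFrame(self.F).to_csv(wide_path, index=False)
            paths["traces_wide"] = str(wide_path)
        truth = out / "ground_truth.json"
        manifest = {
            "condition": self.condition,
            "seed": int(self.seed),
            "fs_hz": float(self.fs_hz),
            "zg_area_um2": float(self.zg_area_um2),
            "n_roi": int(self.n_roi),
            "n_frames": int(self.n_frames),
            "ground_truth": self.ground_truth.to_jsonable(),
        }
        truth.write_text(json.dumps(manifest, indent=1))
        paths["ground_truth"] = str(truth)
        return paths


# Condition presets: stimulus x osmolarity.  Lower osmolarity (280 mOsm) is
# permissive — more active cells, more frequent and longer bursts; the
# within-burst period is identical everywhere.
_COMMON = dict(intraburst_mu_s=2.0, intraburst_sigma_s=0.5, duration_s=600.0)
PRESETS: dict[str, BurstTrainParams] = {
    "TI-280": BurstTrainParams(
        active_prob=0.70, interburst_mean_s=20.0, events_per_burst_geom_p=0.25, **_COMMON
    ),
    "TI-310": BurstTrainParams(
        active_prob=0.35, interburst_mean_s=45.0, events_per_burst_geom_p=0.60, **_COMMON
    ),
    "AngII-280": BurstTrainParams(
        active_prob=0.65, interburst_mean_s=22.0, events_per_burst_geom_p=0.30, **_COMMON
    ),
    "AngII-310": BurstTrainParams(
        active_prob=0.35, interburst_mean_s=50.0, events_per_burst_geom_p=0.60, **_COMMON
    ),
}


def _truncated_normal(mu: float, sigma: float, floor: float, n: int, rng) -> np.ndarray:
    """Sample N(mu, sigma^2) conditioned on x >= floor, by rejection."""
    out = np.empty(n)
    got = 0
    while got < n:
        draw = rng.normal(mu, sigma, size=max(n - got, 8))
        keep = draw[draw >= floor]
        take = min(len(keep), n - got)
        out[got : got + take] = keep[:take]
        got += take
    return out


def sample_burst_train(
    params: BurstTrainParams, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[float, float, int]]]:
    """Draw one ROI's spike train as an alternating burst/gap renewal process.

    Returns ``(spike_times_s, burst_windows)`` where each window is
    ``(start_s, end_s, n_events)``.  A burst begun near the end of the
    recording is truncated at ``duration_s``; its realized events are kept
    and its window recorded only if at least ``events_per_burst_min`` events
    landed inside the recording.
    """
    if params.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if params.active_prob == 0 or np.isinf(params.interburst_mean_s):
        return np.empty(0), []
    if rng.random() >= params.active_prob:
        return np.empty(0), []

    spikes: list[float] = []
    windows: list[tuple[float, float, int]] = []
    floor = params.interval_floor_s
    t = rng.exponential(params.interburst_mean_s)
    while t < params.duration_s:
        n_events = params.events_per_burst_min
        if params.events_per_burst_geom_p < 1.0:
            n_events += rng.geometric(params.events_per_burst_geom_p) - 1
        burst = [t]
        intervals = _truncated_normal(
            params.intraburst_mu_s,
            params.intraburst_sigma_s,
            params.interval_floor_s,
            n_events - 1,
            rng,
        )
        for dt in intervals:
            nxt = burst[-1] + dt
            if nxt >= params.duration_s:
                break
            burst.append(nxt)
        spikes.extend(burst)
        if len(burst) >= params.events_per_burst_min:
            windows.append((burst[0], burst[-1], len(burst)))
        # interburst gaps share the detector-resolution floor so that every
        # interpeak interval in the train respects it
        t = burst[-1] + max(rng.exponential(params.interburst_mean_s), floor)
    return np.asarray(spikes), windows


def indicator_kernel(
    indicator: IndicatorParams, fs_hz: float, n_frames: int | None = None
) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel on the frame grid."""
    if n_frames is None:
        n_frames = int(np.ceil(8 * indicator.decay_tau_s * fs_hz)) + 1
    t = np.arange(n_frames) / fs_hz
    k = np.exp(-t / indicator.decay_tau_s) - np.exp(-t / indicator.rise_tau_s)
    # analytic peak of the continuous kernel; normalize so max_t k(t) = 1
    tr, td = indicator.rise_tau_s, indicator.decay_tau_s
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return k / peak


def shared_background(
    noise: NoiseParams, fs_hz: float, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Low-frequency background common to every ROI of a dataset."""
    t = np.arange(n_frames) / fs_hz
    if noise.background_amplitude_dff == 0:
        return np.zeros(n_frames)
    phase = rng.uniform(0, 2 * np.pi)
    phase2 = rng.uniform(0, 2 * np.pi)
    return noise.background_amplitude_dff * (
        np.sin(2 * np.pi * t / noise.background_period_s + phase)
        + 0.5 * np.sin(2 * np.pi * t / (noise.background_period_s * 2.7) + phase2)
    )


def render_trace(
    spike_times: np.ndarray,
    indicator: IndicatorParams,
    noise: NoiseParams,
    fs_hz: float,
    duration_s: float,
    rng: np.random.Generator,
    background: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a spike train as (fluorescence, neuropil) frame rows.

    The fluorescence row is the linear superposition of one indicator kernel
    per spike (evaluated at the exact continuous spike offset) plus
    ``neuropil_coeff_true`` times the shared background, a slow sinusoidal
    drift, and white noise.  The neuropil row is the shared background plus
    independent white noise.  No saturation is modeled.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size and (
        spike_times.min() < 0 or spike_times.max() > duration_s
    ):
        raise ValueError("spike times must lie within [0, duration_s]")
    n_frames = int(round(duration_s * fs_hz))
    t = np.arange(n_frames) / fs_hz
    F = np.zeros(n_frames)
    tr, td = indicator.rise_tau_s, indicator.decay_tau_s
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    for ts in spike_times:
        dt = t - ts
        mask = dt >= 0
        F[mask] += (
            indicator.unit_amplitude_dff
            * (np.exp(-dt[mask] / td) - np.exp(-dt[mask] / tr))
            / peak
        )
    if background is None:
        background = shared_background(noise, fs_hz, n_frames, rng)
    F = F + noise.neuropil_coeff_true * background
    if noise.drift_amplitude_dff > 0:
        phase = rng.uniform(0, 2 * np.pi)
        F = F + noise.drift_amplitude_dff * np.sin(
            2 * np.pi * t / noise.drift_period_s + phase
        )
    if noise.white_sd_dff > 0:
        F = F + rng.normal(0, noise.white_sd_dff, n_frames)
    Fneu = background.copy()
    if noise.white_sd_dff > 0:
        Fneu = Fneu + rng.normal(0, noise.white_sd_dff, n_frames)
    return F, Fneu


def _roi_rng(seed: int, roi: int) -> np.random.Generator:
    # counter-keyed streams: ROI i's stream does not depend on n_roi
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(roi))))


def _dataset_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), 0x0BA5E)))


def generate_dataset(
    preset: str | BurstTrainParams,
    n_roi: int,
    seed: int,
    fs_hz: float = 10.0,
    zg_area_um2: float = 4000.0,
    indicator: IndicatorParams | None = None,
    noise: NoiseParams | None = None,
) -> SyntheticDataset:
    """Generate a full ROI x frame dataset under a named condition preset.

    Reproducible: the same ``(preset, n_roi, seed)`` gives identical arrays,
    and each ROI draws from its own counter-keyed stream, so extending
    ``n_roi`` leaves earlier ROIs unchanged.
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise KeyError(
                f"unknown preset {preset!r}; known: {sorted(PRESETS)}"
            )
        condition = preset
        params = PRESETS[preset]
    else:
        condition = "custom"
        params = preset
    if n_roi < 0:
        raise ValueError("n_roi must be >= 0")
    indicator = indicator or IndicatorParams()
    noise = noise or NoiseParams()

    n_frames = int(round(params.duration_s * fs_hz))
    F = np.zeros((n_roi, n_frames))
    Fneu = np.zeros((n_roi, n_frames))
    bg = shared_background(noise, fs_hz, n_frames, _dataset_rng(seed))
    truth = GroundTruth()
    for i in range(n_roi):
        rng = _roi_rng(seed, i)
        spikes, windows = sample_burst_train(params, rng)
        F[i], Fneu[i] = render_trace(
            spikes, indicator, noise, fs_hz, params.duration_s, rng, background=bg
        )
        truth.rois.append(
            RoiTruth(active=spikes.size > 0, spike_times_s=spikes, bursts=windows)
        )
    return SyntheticDataset(
        F=F,
        Fneu=Fneu,
        fs_hz=fs_hz,
        zg_area_um2=zg_area_um2,
        condition=condition,
        seed=seed,
        ground_truth=truth,
    )


def sample_interval_mixture(
    w_g: float,
    mu: float,
    sigma: float,
    rate: float,
    n: int,
    rng: np.random.Generator,
    interval_floor_s: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample interpeak intervals from the Gaussian+exponential mixture.

    The Gaussian component is truncated below at ``interval_floor_s``.
    Returns ``(intervals, labels)`` with label 0 for Gaussian draws and 1
    for exponential draws, so tests can condition on the true component.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not (0 <= w_g <= 1):
        raise ValueError("w_g must be in [0, 1]")
    if sigma <= 0 or rate <= 0:
        raise ValueError("sigma and rate must be positive")
    labels = (rng.random(n) >= w_g).astype(int)
    intervals = np.empty(n)
    n_g = int(np.sum(labels == 0))
    if n_g:
        intervals[labels == 0] = _truncated_normal(
            mu, sigma, interval_floor_s, n_g, rng
        )
    if n - n_g:
        intervals[labels == 1] = rng.exponential(1.0 / rate, size=n - n_g)
    return intervals, labels
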