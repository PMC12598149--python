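"""Calcium-transient detection, alignment, filtering and validation.

Detection is a staged rule set over the deconvolved event sequence ``s``
and the conditioned fluorescence trace:

(i)   threshold ``s`` at a fraction of its maximum (dual threshold, part 1);
(ii)  merge contiguous supra-threshold runs to a single candidate at the
      run's largest ``s`` value;
(iii) align each candidate to the fluorescence maximum within a +/- window
      (ties -> earlier frame), collapsing duplicates to the larger
      fluorescence amplitude;
(iv)  drop candidates whose fluorescence amplitude falls below a multiple
      of the baseline noise SD (dual threshold, part 2);
(v)   moving filter: drop events that are small relative to the largest
      event nearby, removing minor fluctuations riding on large transients.

Validation then checks each surviving event against the indicator template:
the local fluorescence segment must correlate with the template and leave a
modest residual, otherwise the event is flagged as unvalidated (kept in the
table, excluded from downstream metrics by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import DeconvResult

__all__ = [
    "DetectionParams",
    "NoiseEstimate",
    "TransientEvent",
    "TransientSet",
    "estimate_noise",
    "detect_transients",
    "validate_transients",
]


@dataclass(frozen=True)
class DetectionParams:
    deconv_frac: float = 0.05
    amp_n_sigma: float = 3.0
    align_halfwidth_frames: int = 5
    align_smooth_frames: int = 3
    movfilt_window_frames: int = 10
    movfilt_rel_amp: float = 0.15
    validate_corr_min: float = 0.45
    validate_noise_max_sigma: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.deconv_frac < 1):
            raise ValueError("deconv_frac must be in (0, 1)")
        if self.align_halfwidth_frames < 0:
            raise ValueError("align_halfwidth_frames must be >= 0")
        if self.align_smooth_frames < 1:
            raise ValueError("align_smooth_frames must be >= 1")
        if self.amp_n_sigma < 0:
            raise ValueError("amp_n_sigma must be >= 0")


@dataclass
class NoiseEstimate:
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class TransientEvent:
    roi_id: int | str
    peak_frame: int
    peak_time_s: float
    fluor_amplitude: float
    deconv_amplitude: float
    validated: bool = True


@dataclass
class TransientSet:
    events_by_roi: dict = field(default_factory=dict)
    duration_s: float = 0.0
    fs_hz: float = 10.0

    def events(self, roi_id) -> list[TransientEvent]:
        return self.events_by_roi.get(roi_id, [])

    def all_events(self) -> list[TransientEvent]:
        return [e for evs in self.events_by_roi.values() for e in evs]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "roi_id": e.roi_id,
                "peak_frame": e.peak_frame,
                "peak_time_s": e.peak_time_s,
                "fluor_amplitude": e.fluor_amplitude,
                "deconv_amplitude": e.deconv_amplitude,
                "validated": e.validated,
            }
            for e in self.all_events()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "roi_id",
                "peak_frame",
                "peak_time_s",
                "fluor_amplitude",
                "deconv_amplitude",
                "validated",
            ],
        )


def estimate_noise(trace: np.ndarray) -> NoiseEstimate:
    """Robust baseline-noise SD from first differences.

    ``sigma = MAD(diff(trace)) / (sqrt(2) * 0.6745)``: differencing removes
    slow structure and the median absolute deviation ignores the sparse
    large excursions that transients contribute.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 100:
        raise ValueError("need >= 100 frames for a noise estimate")
    d = np.diff(trace)
    mad = np.median(np.abs(d - np.median(d)))
    return NoiseEstimate(sigma=float(mad / (np.sqrt(2) * 0.6745)))


def detect_transients(
    deconv: DeconvResult,
    fluor_trace: np.ndarray,
    params: DetectionParams,
    noise: NoiseEstimate,
    roi_id: int | str = 0,
    fs_hz: float = 10.0,
) -> list[TransientEvent]:
    """Run stages (i)-(v) of the detection rule set; returns sorted events.

    Peak alignment and amplitude readout operate on a lightly boxcar-smoothed
    copy of the fluorescence (``align_smooth_frames``); ``noise`` is the
    raw-trace estimate and the amplitude threshold is scaled by
    ``1/sqrt(align_smooth_frames)`` to match the smoothed trace's noise
    level.  Smoothing stabilizes the argmax under noise without moving the
    true peak by more than a fraction of a frame.
    """
    s = np.asarray(deconv.s, dtype=float)
    f = np.asarray(fluor_trace, dtype=float)
    if s.size == 0 or f.size == 0:
        raise ValueError("empty traces")
    if s.size != f.size:
        raise ValueError("deconvolved and fluorescence traces differ in length")
    sm = params.align_smooth_frames
    if sm > 1:
        f = np.convolve(f, np.ones(sm) / sm, mode="same")
    sigma_eff = noise.sigma / np.sqrt(sm)
    smax = s.max()
    if smax <= 0:
        return []

    # (i) deconvolved threshold
    above = s > params.deconv_frac * smax
    if not above.any():
        return []
    # (ii) one candidate per contiguous run, at the run's max s (ties: earlier)
    idx = np.flatnonzero(above)
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([0], run_breaks + 1))
    run_ends = np.concatenate((run_breaks, [idx.size - 1]))
    candidates = []
    for a, b in zip(run_starts, run_ends):
        run = idx[a : b + 1]
        candidates.append((run[np.argmax(s[run])], float(s[run].max())))

    # (iii) align to fluorescence maximum within +/- halfwidth (ties: earlier)
    h = params.align_halfwidth_frames
    aligned: dict[int, tuple[float, float]] = {}
    for frame, damp in candidates:
        lo = max(frame - h, 0)
        hi = min(frame + h + 1, f.size)
        peak = lo + int(np.argmax(f[lo:hi]))
        famp = float(f[peak])
        if peak in aligned:
            old_f, old_d = aligned[peak]
            aligned[peak] = (max(old_f, famp), max(old_d, damp))
        else:
            aligned[peak] = (famp, damp)

    # (iv) fluorescence amplitude threshold
    events = [
        (peak, famp, damp)
        for peak, (famp, damp) in sorted(aligned.items())
        if famp >= params.amp_n_sigma * sigma_eff
    ]

    # (v) moving filter on deconvolved amplitude
    kept = []
    for peak, famp, damp in events:
        nearby = [
            d2
            for p2, _, d2 in events
            if abs(p2 - peak) <= params.movfilt_window_frames
        ]
        if damp >= params.movfilt_rel_amp * max(nearby):
            kept.append((peak, famp, damp))

    return [
        TransientEvent(
            roi_id=roi_id,
            peak_frame=int(p),
            peak_time_s=p / fs_hz,
            fluor_amplitude=fa,
            deconv_amplitude=da,
        )
        for p, fa, da in kept
    ]


def validate_transients(
    events: list[TransientEvent],
    fluor_trace: np.ndarray,
    template: np.ndarray,
    params: DetectionParams,
    noise: NoiseEstimate,
) -> list[TransientEvent]:
    """Flag events whose local waveform does not match the indicator template.

    The template (peak-normalized indicator kernel sampled from onset at the
    recording frame rate, typically truncated a few decay constants past its
    maximum) is aligned so its maximum sits on the event's peak frame; the
    covered fluorescence segment runs from the kernel's rise (about 2 frames
    before the peak for the defaults) to the template's end.  An event is
    validated iff the Pearson correlation with the template reaches
    ``validate_corr_min`` and the SD of the residual after least-squares
    template scaling stays below ``validate_noise_max_sigma`` times the
    baseline noise.
    """
    f = np.asarray(fluor_trace, dtype=float)
    template = np.asarray(template, dtype=float)
    k_peak = int(np.argmax(template))
    peaks = sorted(e.peak_frame for e in events)
    next_peak = {p: q for p, q in zip(peaks, peaks[1:])}
    out = []
    for e in events:
        if not (0 <= e.peak_frame < f.size):
            raise ValueError("event outside trace bounds")
        lo = e.peak_frame - k_peak
        hi = lo + template.size
        # overlapping transients are expected in bursts: stop the window
        # before the next event's rise so its shape does not count against
        # this event
        nxt = next_peak.get(e.peak_frame)
        if nxt is not None:
            hi = min(hi, nxt - k_peak)
        a = max(lo, 0)
        b = min(hi, f.size)
        seg = f[a:b] if b > a else np.empty(0)
        t = template[a - lo : a - lo + seg.size]
        if seg.size < 4:
            # window swallowed by a hard-overlapping neighbor: nothing to
            # assess, keep the event
            out.append(
                TransientEvent(
                    roi_id=e.roi_id, peak_frame=e.peak_frame,
                    peak_time_s=e.peak_time_s,
                    fluor_amplitude=e.fluor_amplitude,
                    deconv_amplitude=e.deconv_amplitude, validated=True,
                )
            )
            continue
        ok = False
        if np.std(seg) > 0 and np.std(t) > 0:
            r = float(np.corrcoef(seg, t)[0, 1])
            scale = float(np.dot(seg, t) / np.dot(t, t))
            resid_sd = float(np.std(seg - scale * t))
            ok = (
                r >= params.validate_corr_min
                and resid_sd <= params.validate_noise_max_sigma * max(noise.sigma, 1e-12)
            )
        out.append(
            TransientEvent(
                roi_id=e.roi_id,
                peak_frame=e.peak_frame,
                peak_time_s=e.peak_time_s,
                fluor_amplitude=e.fluor_amplitude,
                deconv_amplitude=e.deconv_amplitude,
                validated=ok,
            )
        )
    return out
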