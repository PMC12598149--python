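"""Trace conditioning and quality control ahead of transient detection.

The fixed stage order is: neuropil subtraction -> rolling-percentile
baseline removal -> SD-ratio QC -> nonnegative sparse deconvolution.
Neuropil subtraction removes the scalar-scaled shared background picked up
by widefield imaging; the running-percentile detrend removes remaining slow
background at the trace level; the SD-ratio test drops ROIs whose noise
level is grossly nonstationary (poor signal quality); deconvolution inverts
the indicator decay to expose event onsets.

Deconvolution solves, for an AR(1) indicator model with coefficient
``gamma = exp(-1 / (fs * decay_tau))``::

    minimize  1/2 ||y - c||^2 + lam * sum(s)
    s.t.      s[t] = c[t] - gamma * c[t-1] >= 0   (s[0] = c[0]),  c >= 0

by a single forward pass with pool-adjacent-violators-style merging
(the online active-set scheme standard for calcium indicators).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TraceSet",
    "QCParams",
    "QCResult",
    "DeconvParams",
    "DeconvResult",
    "subtract_neuropil",
    "rolling_baseline",
    "sd_ratio_qc",
    "deconvolve",
]


@dataclass
class TraceSet:
    """ROI x frame fluorescence matrix with optional matched neuropil."""

    F: np.ndarray
    fs_hz: float
    Fneu: np.ndarray | None = None
    roi_ids: list | None = None

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.Fneu is not None:
            self.Fneu = np.atleast_2d(np.asarray(self.Fneu, dtype=float))
            if self.Fneu.shape != self.F.shape:
                raise ValueError("F and Fneu shapes differ")
        if self.roi_ids is None:
            self.roi_ids = list(range(self.F.shape[0]))
        elif len(self.roi_ids) != self.F.shape[0]:
            raise ValueError("roi_ids length mismatch")


@dataclass(frozen=True)
class QCParams:
    window_frames: int = 600
    sd_ratio_max: float = 6.0
    sd_floor_rel: float = 1e-6  # floor = sd_floor_rel * global SD

    def __post_init__(self) -> None:
        if self.window_frames < 2:
            raise ValueError("window_frames must be >= 2")
        if self.sd_ratio_max <= 1:
            raise ValueError("sd_ratio_max must be > 1")


@dataclass
class QCResult:
    min_sd: float
    max_sd: float
    ratio: float
    passed: bool


@dataclass(frozen=True)
class DeconvParams:
    """AR(1) deconvolution settings.

    ``sparsity_penalty`` is the absolute l1 weight on event amplitudes;
    ``None`` selects it automatically as ``auto_lambda_n_sigma`` robust
    noise SDs scaled by ``1 / (1 - gamma)`` — the scaling under which the
    penalty shifts each event amplitude by a noise-proportional amount.
    """

    decay_tau_s: float = 0.6
    sparsity_penalty: float | None = None
    auto_lambda_n_sigma: float = 2.0
    baseline_window_frames: int = 600
    baseline_percentile: float = 10.0

    def __post_init__(self) -> None:
        if self.decay_tau_s <= 0:
            raise ValueError("decay_tau_s must be positive")
        if self.sparsity_penalty is not None and self.sparsity_penalty < 0:
            raise ValueError("sparsity_penalty must be >= 0")

    def gamma(self, fs_hz: float) -> float:
        g = float(np.exp(-1.0 / (fs_hz * self.decay_tau_s)))
        if not (0 < g < 1):
            raise ValueError("AR(1) coefficient outside (0, 1)")
        return g


@dataclass
class DeconvResult:
    C: np.ndarray  # denoised calcium (>= 0)
    s: np.ndarray  # event amplitudes (>= 0), s[t] = C[t] - gamma*C[t-1]
    gamma: float


def subtract_neuropil(
    F_row: np.ndarray, Fneu_row: np.ndarray, coeff: float
) -> np.ndarray:
    """Elementwise ``F - coeff * Fneu``; coeff in [0, 1]."""
    F_row = np.asarray(F_row, dtype=float)
    Fneu_row = np.asarray(Fneu_row, dtype=float)
    if F_row.shape != Fneu_row.shape:
        raise ValueError("F and Fneu lengths differ")
    if not (0 <= coeff <= 1):
        raise ValueError("coeff must be in [0, 1]")
    return F_row - coeff * Fneu_row


def rolling_baseline(
    trace: np.ndarray, window_frames: int, percentile: float
) -> np.ndarray:
    """Subtract a centered running percentile (edges clamped).

    The running percentile tracks slow background (periods much longer than
    the window) while leaving brief transients nearly untouched.
    """
    trace = np.asarray(trace, dtype=float)
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    if not (0 <= percentile <= 100):
        raise ValueError("percentile must be in [0, 100]")
    if window_frames >= trace.size:
        return trace - np.percentile(trace, percentile)
    baseline = (
        pd.Series(trace)
        .rolling(window_frames, center=True, min_periods=1)
        .quantile(percentile / 100.0)
        .to_numpy()
    )
    return trace - baseline


def condition_trace(
    F_row: np.ndarray,
    Fneu_row: np.ndarray | None,
    coeff: float,
    window_frames: int,
    percentile: float,
) -> np.ndarray:
    """Neuropil subtraction, rolling-percentile detrend, median centering.

    The running low-percentile baseline sits below the noise floor by a
    noise-dependent offset, so the detrended trace is re-centered at its
    median: downstream stages (deconvolution, amplitude thresholds) assume
    a zero baseline.
    """
    f = np.asarray(F_row, dtype=float)
    if Fneu_row is not None:
        f = subtract_neuropil(f, Fneu_row, coeff)
    f = rolling_baseline(f, window_frames, percentile)
    return f - np.median(f)


def _windowed_sds(trace: np.ndarray, window: int) -> np.ndarray:
    stride = max(window // 2, 1)
    n = trace.size
    starts = list(range(0, n - window + 1, stride))
    if starts and starts[-1] + window < n:
        starts.append(n - window)  # cover the tail
    return np.array([trace[a : a + window].std(ddof=0) for a in starts])


def sd_ratio_qc(trace: np.ndarray, params: QCParams) -> QCResult:
    """Windowed-SD stationarity check (stride = half window).

    The ratio of maximum to minimum windowed SD flags ROIs whose noise level
    changes grossly over the recording; ratios above ``sd_ratio_max`` fail.
    The denominator is floored at a tiny fraction of the global SD so an
    exactly-flat stretch yields a capped (failing) ratio instead of inf.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < params.window_frames:
        raise ValueError("trace shorter than QC window")
    sds = _windowed_sds(trace, params.window_frames)
    min_sd = float(sds.min())
    max_sd = float(sds.max())
    floor = params.sd_floor_rel * float(trace.std(ddof=0))
    if floor == 0:  # constant trace: ratio defined as 1
        ratio = 1.0
    else:
        ratio = max_sd / max(min_sd, floor)
    return QCResult(
        min_sd=min_sd,
        max_sd=max_sd,
        ratio=ratio,
        passed=bool(ratio <= params.sd_ratio_max),
    )


def deconvolve(
    trace: np.ndarray, params: DeconvParams, fs_hz: float = 10.0
) -> DeconvResult:
    """Nonnegative sparse AR(1) deconvolution by pool merging.

    Exact solution of the constrained quadratic program in the module
    docstring: a forward pass builds pools of frames forced to share one
    exponentially decaying segment; adjacent pools are merged while the
    constraint ``c[t] >= gamma * c[t-1]`` is violated at their boundary,
    and pool heights are clamped at zero for ``c >= 0``.
    """
    y = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")
    g = params.gamma(fs_hz)
    lam = params.sparsity_penalty
    if lam is None:
        d = np.diff(y)
        sig = float(np.median(np.abs(d - np.median(d))) / (np.sqrt(2) * 0.6745))
        lam = params.auto_lambda_n_sigma * sig / (1.0 - g)
    n = y.size
    if n == 0:
        return DeconvResult(C=np.empty(0), s=np.empty(0), gamma=g)

    # fold the l1 penalty on s into the data term:
    # sum(s) = (1-g) * sum_{t<n-1} c[t] + c[n-1]
    ytil = y - lam * (1 - g)
    ytil[-1] = y[-1] - lam

    # pools: value v (height at pool start, pre-clamp), weight w, start, length
    v = np.empty(n)
    w = np.empty(n)
    start = np.empty(n, dtype=int)
    length = np.empty(n, dtype=int)
    m = 0  # number of pools
    for t in range(n):
        v[m] = ytil[t]
        w[m] = 1.0
        start[m] = t
        length[m] = 1
        m += 1
        while m > 1 and max(v[m - 1], 0.0) < g ** length[m - 2] * max(v[m - 2], 0.0):
            # merge pool m-1 into m-2
            ln = length[m - 2]
            f = g**ln
            v[m - 2] = (w[m - 2] * v[m - 2] + f * w[m - 1] * v[m - 1]) / (
                w[m - 2] + f * f * w[m - 1]
            )
            w[m - 2] = w[m - 2] + f * f * w[m - 1]
            length[m - 2] = ln + length[m - 1]
            m -= 1

    C = np.empty(n)
    for i in range(m):
        h = max(v[i], 0.0)
        ln = length[i]
        C[start[i] : start[i] + ln] = h * g ** np.arange(ln)
    s = np.empty(n)
    s[0] = C[0]
    s[1:] = C[1:] - g * C[:-1]
    s[np.abs(s) < 1e-12] = 0.0
    s = np.maximum(s, 0.0)
    return DeconvResult(C=C, s=s, gamma=g)
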