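"""Aldosterone-secretion normalization and nonlinear dose-response fits.

Per-slice hormone output (pg/slice/h) is noisy because the number of
functional zona glomerulosa cells per slice varies; each slice therefore
serves as its own control.  The fold change divides the post-treatment
rate by the same slice's baseline rate, and each animal's mean fold change
across its vehicle-treated slices then normalizes every treatment
condition for that animal, so vehicle slices average to exactly 1.

Dose-response relationships (secretion vs osmolarity; secretion vs
fractional bursting time) are summarized with a four-parameter logistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "SigmoidFit",
    "normalize_secretion",
    "fit_sigmoid",
    "four_param_logistic",
]

REQUIRED_COLUMNS = [
    "slice_id",
    "animal_id",
    "treatment",
    "baseline_pg_per_slice_h",
    "post_pg_per_slice_h",
]


@dataclass
class SigmoidFit:
    top: float
    bottom: float
    midpoint: float
    slope: float
    r_squared: float
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        return four_param_logistic(
            np.asarray(x, dtype=float), self.top, self.bottom, self.midpoint, self.slope
        )


def four_param_logistic(
    x: np.ndarray, top: float, bottom: float, midpoint: float, slope: float
) -> np.ndarray:
    """4PL in linear x: bottom + (top - bottom) / (1 + exp(-slope (x - mid))).

    Negative ``slope`` gives a curve decreasing in x (top at low x).
    """
    z = np.clip(-slope * (x - midpoint), -500, 500)
    return bottom + (top - bottom) / (1.0 + np.exp(z))


def normalize_secretion(
    records: pd.DataFrame, vehicle_label: str = "vehicle"
) -> pd.DataFrame:
    """Within-slice fold change, normalized to each animal's vehicle mean.

    Adds ``fold_raw = post / baseline`` and
    ``fold_norm = fold_raw / mean(fold_raw of the animal's vehicle slices)``.
    Animals without any vehicle slice are excluded with a warning.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = records.copy()
    if (df["baseline_pg_per_slice_h"] <= 0).any():
        raise ValueError("baseline must be positive for fold computation")
    if (df["post_pg_per_slice_h"] < 0).any():
        raise ValueError("post-treatment values must be nonnegative")
    df["fold_raw"] = df["post_pg_per_slice_h"] / df["baseline_pg_per_slice_h"]
    vehicle_mean = (
        df[df["treatment"] == vehicle_label]
        .groupby("animal_id")["fold_raw"]
        .mean()
        .rename("vehicle_mean_fold")
    )
    df = df.join(vehicle_mean, on="animal_id")
    dropped = df["vehicle_mean_fold"].isna()
    if dropped.any():
        bad = sorted(df.loc[dropped, "animal_id"].unique())
        warnings.warn(
            f"animals without vehicle slices excluded from normalization: {bad}",
            stacklevel=2,
        )
        df = df[~dropped].copy()
    df["fold_norm"] = df["fold_raw"] / df["vehicle_mean_fold"]
    return df


def average_replicates(normalized: pd.DataFrame) -> pd.DataFrame:
    """Mean fold change per animal x treatment (replicate slices averaged)."""
    group_cols = ["animal_id", "treatment"]
    if "osmolarity_mOsm" in normalized.columns:
        group_cols.append("osmolarity_mOsm")
    return (
        normalized.groupby(group_cols, as_index=False)[["fold_raw", "fold_norm"]]
        .mean()
    )


def fit_sigmoid(
    x: np.ndarray,
    y: np.ndarray,
    init: tuple[float, float, float, float] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> SigmoidFit:
    """Least-squares 4PL fit with quartile-based self-start and restarts.

    The midpoint is bounded within the data range extended by one span.
    A constant-y input yields a flagged degenerate fit with R^2 = 0.  On
    non-convergence the best attempt is returned flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 5:
        raise ValueError("need >= 5 points for a 4PL fit")
    span = float(np.ptp(x))
    if span == 0:
        raise ValueError("x values must not all coincide")
    if np.ptp(y) == 0:
        return SigmoidFit(
            top=float(y[0]), bottom=float(y[0]), midpoint=float(np.median(x)),
            slope=0.0, r_squared=0.0, converged=False,
        )

    lo_y, hi_y = float(np.min(y)), float(np.max(y))
    mid0 = float(np.median(x))
    # sign of the trend decides the initial slope direction
    trend = np.polyfit(x, y, 1)[0]
    slope0 = (4.0 / span) * (1.0 if trend > 0 else -1.0)
    starts = [(hi_y, lo_y, mid0, slope0)]
    if init is not None:
        starts.insert(0, tuple(init))
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts - 1):
        starts.append(
            (
                hi_y * rng.uniform(0.8, 1.2),
                lo_y * rng.uniform(0.8, 1.2),
                float(rng.uniform(x.min(), x.max())),
                slope0 * rng.uniform(0.3, 3.0),
            )
        )
    bounds = (
        [-np.inf, -np.inf, x.min() - span, -np.inf],
        [np.inf, np.inf, x.max() + span, np.inf],
    )
    sstot = float(np.sum((y - y.mean()) ** 2))
    best = None
    converged = False
    for p0 in starts:
        p0 = (
            p0[0],
            p0[1],
            float(np.clip(p0[2], bounds[0][2], bounds[1][2])),
            p0[3],
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    four_param_logistic, x, y, p0=p0, bounds=bounds, maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        ssres = float(np.sum((y - four_param_logistic(x, *popt)) ** 2))
        if best is None or ssres < best[1]:
            best = (popt, ssres)
            converged = True
    if best is None:
        return SigmoidFit(
            top=hi_y, bottom=lo_y, midpoint=mid0, slope=slope0,
            r_squared=0.0, converged=False,
        )
    popt, ssres = best
    top, bottom, midpoint, slope = (float(v) for v in popt)
    if bottom > top:  # canonical orientation: top >= bottom, slope flips
        top, bottom, slope = bottom, top, -slope
    r2 = 1.0 - ssres / sstot if sstot > 0 else 0.0
    return SigmoidFit(
        top=top, bottom=bottom, midpoint=midpoint, slope=slope,
        r_squared=float(r2), converged=converged,
    )
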