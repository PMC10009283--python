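"""Behavioral statistics for urgent-choice trial tables.

The central readout is the *tachometric curve*: percent correct as a
function of processing time (PT = RT - gap), estimated in 50 ms sliding
bins stepped every 1 ms, with exact (Clopper-Pearson) binomial confidence
intervals.  Derived summaries are the capture-range accuracy (pooled
percent correct for 75 <= PT <= 125 ms, where exogenously captured
saccades concentrate), the rise point (PT at which the curve first
reaches 75% correct), and the chronometric curve (mean RT vs gap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "processing_time",
    "binomial_ci",
    "TachCurve",
    "tachometric_curve",
    "capture_range_accuracy",
    "rise_point",
    "rise_point_ci",
    "ChronCurve",
    "chronometric_curve",
]

PT_GRID_MIN = -100.0
PT_GRID_MAX = 400.0


def processing_time(rt_ms, gap_ms):
    """PT = RT - gap, element-wise; missing values propagate."""
    return np.asarray(rt_ms, dtype=float) - np.asarray(gap_ms, dtype=float)


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson confidence interval for a binomial proportion.

    Returns (low, high) as fractions in [0, 1]; ``(nan, nan)`` when n = 0.
    """
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        return (float("nan"), float("nan"))
    low, high = proportion_confint(k, n, alpha=1.0 - level, method="beta")
    return float(low), float(high)


def _pt_and_correct(table: pd.DataFrame, include_invalid: bool = False):
    """Extract finite (pt, correct) pairs, honoring the valid flag."""
    df = table
    if not include_invalid and "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    if "pt_ms" in df.columns:
        pt = df["pt_ms"].to_numpy(dtype=float)
    else:
        pt = processing_time(df["rt_ms"].to_numpy(), df["gap_ms"].to_numpy())
    correct = df["correct"].to_numpy(dtype=float)
    keep = np.isfinite(pt) & np.isfinite(correct)
    return pt[keep], correct[keep].astype(bool)


@dataclass
class TachCurve:
    """Sliding-bin tachometric curve.

    ``pct_correct`` and the CI bounds are NaN wherever ``n_per_bin`` is 0.
    """

    pt_grid: np.ndarray
    pct_correct: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_per_bin: np.ndarray
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pt_ms": self.pt_grid,
                "pct_correct": self.pct_correct,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n": self.n_per_bin,
            }
        )


def tachometric_curve(
    table: pd.DataFrame,
    bin_width: float = 50.0,
    step: float = 1.0,
    level: float = 0.95,
    include_invalid: bool = False,
    grid_limits: tuple[float, float] = (PT_GRID_MIN, PT_GRID_MAX),
) -> TachCurve:
    """Percent correct vs PT in sliding bins of ``bin_width`` ms.

    Each grid center ``c`` pools the valid trials with PT in the half-open
    bin ``[c - bin_width/2, c + bin_width/2)``.  The grid steps every
    ``step`` ms across the populated PT range clipped to ``grid_limits``.
    """
    pt, correct = _pt_and_correct(table, include_invalid)
    if len(pt) == 0:
        raise ValueError("no valid trials with finite PT")

    lo = max(np.floor(pt.min()), grid_limits[0])
    hi = min(np.ceil(pt.max()), grid_limits[1])
    grid = np.arange(lo, hi + 0.5 * step, step)

    order = np.argsort(pt, kind="stable")
    pt_sorted = pt[order]
    csum = np.concatenate([[0], np.cumsum(correct[order])])

    half = bin_width / 2.0
    left = np.searchsorted(pt_sorted, grid - half, side="left")
    right = np.searchsorted(pt_sorted, grid + half, side="left")
    n_bin = right - left
    k_bin = csum[right] - csum[left]

    pct = np.full(len(grid), np.nan)
    ci_lo = np.full(len(grid), np.nan)
    ci_hi = np.full(len(grid), np.nan)
    pop = n_bin > 0
    pct[pop] = 100.0 * k_bin[pop] / n_bin[pop]
    if pop.any():
        lo_f, hi_f = proportion_confint(
            k_bin[pop], n_bin[pop], alpha=1.0 - level, method="beta"
        )
        ci_lo[pop] = 100.0 * np.asarray(lo_f, dtype=float)
        ci_hi[pop] = 100.0 * np.asarray(hi_f, dtype=float)

    return TachCurve(grid, pct, ci_lo, ci_hi, n_bin, bin_width)


def capture_range_accuracy(
    table: pd.DataFrame,
    lo: float = 75.0,
    hi: float = 125.0,
    level: float = 0.95,
    include_invalid: bool = False,
):
    """Pooled percent correct for trials with ``lo <= PT <= hi`` (inclusive).

    Returns ``(pct, (ci_low, ci_high))`` in percent, or
    ``(nan, (nan, nan))`` when no trial falls in the range.
    """
    pt, correct = _pt_and_correct(table, include_invalid)
    sel = (pt >= lo) & (pt <= hi)
    n = int(sel.sum())
    if n == 0:
        return float("nan"), (float("nan"), float("nan"))
    k = int(correct[sel].sum())
    ci = binomial_ci(k, n, level)
    return 100.0 * k / n, (100.0 * ci[0], 100.0 * ci[1])


def rise_point(curve: TachCurve, criterion: float = 75.0,
               min_count: int = 25) -> float:
    """PT at which the curve first reaches ``criterion`` percent correct.

    Scans the populated grid left to right for the first point at or above
    the criterion and interpolates linearly from the preceding populated
    point.  Returns NaN if the curve never reaches the criterion.

    Grid points with fewer than ``min_count`` trials are ignored: at the
    sparse edges of the PT distribution a near-empty bin can spuriously
    read >= 75% correct and would otherwise masquerade as the rise.
    """
    pct = curve.pct_correct
    grid = curve.pt_grid
    pop = np.isfinite(pct) & (curve.n_per_bin >= min_count)
    idx = np.flatnonzero(pop & (pct >= criterion))
    if len(idx) == 0:
        return float("nan")
    i = idx[0]
    prev = np.flatnonzero(pop[:i])
    if len(prev) == 0 or pct[i] == criterion:
        return float(grid[i])
    j = prev[-1]
    # linear interpolation between the bracketing populated grid points
    frac = (criterion - pct[j]) / (pct[i] - pct[j])
    return float(grid[j] + frac * (grid[i] - grid[j]))


def rise_point_ci(
    table: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    criterion: float = 75.0,
    min_count: int = 25,
    rng: np.random.Generator | int | None = None,
    **curve_kwargs,
):
    """Bootstrap percentile CI of the rise point.

    Resamples trials (rows) with replacement ``n_boot`` times.  Returns
    ``(low, high, n_undefined)``; the interval is ``(nan, nan)`` — flagged
    — when the rise point is undefined in more than half the resamples.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(rng)
    n = len(table)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = table.iloc[idx]
        try:
            curve = tachometric_curve(resampled, **curve_kwargs)
            vals[b] = rise_point(curve, criterion, min_count=min_count)
        except ValueError:
            vals[b] = np.nan
    defined = vals[np.isfinite(vals)]
    n_undef = n_boot - len(defined)
    if n_undef > n_boot / 2:
        return float("nan"), float("nan"), n_undef
    alpha = 1.0 - level
    lo, hi = np.percentile(defined, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi), n_undef


@dataclass
class ChronCurve:
    """Mean RT +/- SD per gap value (trials pooled over sessions)."""

    gap: np.ndarray
    mean_rt: np.ndarray
    sd_rt: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gap_ms": self.gap, "mean_rt": self.mean_rt,
             "sd_rt": self.sd_rt, "n": self.n}
        )


def chronometric_curve(
    table: pd.DataFrame, include_invalid: bool = False
) -> ChronCurve:
    """Mean and SD of RT as a function of gap, pooled across sessions."""
    df = table
    if not include_invalid and "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    df = df[np.isfinite(df["rt_ms"])]
    if len(df) == 0:
        raise ValueError("no valid trials with finite RT")
    grp = df.groupby("gap_ms")["rt_ms"]
    agg = grp.agg(["mean", lambda s: s.std(ddof=0), "size"])
    agg.columns = ["mean_rt", "sd_rt", "n"]
    agg = agg.sort_index()
    return ChronCurve(
        gap=agg.index.to_numpy(dtype=float),
        mean_rt=agg["mean_rt"].to_numpy(dtype=float),
        sd_rt=agg["sd_rt"].to_numpy(dtype=float),
        n=agg["n"].to_numpy(dtype=int),
    )
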