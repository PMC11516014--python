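"""Cross-proxy time-series statistics.

All functions operate on plain arrays ordered forward in time (decreasing
BCE), the convention shared by every series container in the package.
Provided: linear detrending, block binning, windowed Pearson correlation
(full 2850-1700, MNB 2850-2350, LN 2350-1700 BCE windows), lagged cross-
and auto-correlation, and SD-threshold event detection.  Event detection
uses the standard deviation rather than e.g. percentiles because smoothed
proxies (KDE means) have compressed variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "WINDOWS",
    "detrend",
    "bin_series",
    "window_pearson",
    "cross_correlation",
    "autocorrelation",
    "Event",
    "EventSet",
    "detect_events",
]

#: analysis windows in years BCE (start, end)
WINDOWS = {
    "full": (2850, 1700),
    "MNB": (2850, 2350),
    "LN": (2350, 1700),
}


def detrend(values, method: str = "linear") -> np.ndarray:
    """Remove an ordinary-least-squares linear trend; residual mean ~ 0."""
    y = np.asarray(values, float)
    if method != "linear":
        raise ValueError(f"unsupported detrend method {method!r}")
    if len(y) < 3:
        raise ValueError("detrend needs at least 3 points")
    x = np.arange(len(y), dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return y - (slope * x + intercept)


def bin_series(years_bce, values, width: int = 25, stat: str = "mean"):
    """Non-overlapping block means, bins labelled by their midpoint year.

    A trailing partial block is dropped; returns (bin_years, bin_values,
    n_dropped_points).
    """
    if stat != "mean":
        raise ValueError("only stat='mean' is supported")
    years = np.asarray(years_bce, float)
    y = np.asarray(values, float)
    if len(years) != len(y):
        raise ValueError("years and values must align")
    step = abs(years[0] - years[1]) if len(years) > 1 else 1.0
    per_bin = int(round(width / step))
    if per_bin < 1:
        raise ValueError("bin width smaller than the series step")
    n_bins = len(y) // per_bin
    dropped = len(y) - n_bins * per_bin
    yy = y[: n_bins * per_bin].reshape(n_bins, per_bin)
    ty = years[: n_bins * per_bin].reshape(n_bins, per_bin)
    return ty.mean(axis=1), yy.mean(axis=1), dropped


def _window_mask(years_bce, window):
    if isinstance(window, str):
        window = WINDOWS[window]
    start, end = window
    years = np.asarray(years_bce, float)
    return (years <= start) & (years >= end)


def window_pearson(years_bce, a, b, window="full") -> float:
    """Pearson r between two aligned series over a BCE window."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("series must be aligned")
    m = _window_mask(years_bce, window)
    m &= ~np.isnan(a) & ~np.isnan(b)
    if m.sum() < 3:
        raise ValueError("fewer than 3 overlapping points in window")
    aa, bb = a[m], b[m]
    if np.std(aa) == 0 or np.std(bb) == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(stats.pearsonr(aa, bb)[0])


def cross_correlation(a, b, max_lag: int, step: float = 1.0):
    """Pearson r at integer lags -max_lag..+max_lag (in series steps).

    Positive lag means ``a`` leads ``b``: r(+L) correlates a(t) with
    b(t + L).  Returns (lags_in_years, r, best_lag_in_years) where best is
    the lag of maximum |r|; lags with < 3 overlapping points are NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("series must be equal length and aligned")
    n = len(a)
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(len(lags), np.nan)
    for i, L in enumerate(lags):
        if L >= 0:
            x, y = a[: n - L] if L else a, b[L:]
        else:
            x, y = a[-L:], b[: n + L]
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3:
            continue
        xs, ys = x[ok], y[ok]
        if np.std(xs) == 0 or np.std(ys) == 0:
            continue
        r[i] = stats.pearsonr(xs, ys)[0]
    if np.all(np.isnan(r)):
        raise ValueError("no lag with enough overlap")
    best = lags[int(np.nanargmax(np.abs(r)))]
    return lags * step, r, best * step


def autocorrelation(a, max_lag: int, step: float = 1.0):
    """Lagged self-similarity: cross_correlation(a, a) for lags 0..max_lag."""
    lags, r, _ = cross_correlation(a, a, max_lag, step=step)
    keep = lags >= 0
    return lags[keep], r[keep]


@dataclass(frozen=True)
class Event:
    start_bce: float
    end_bce: float
    sign: str  # "positive" | "negative"
    peak_z: float


@dataclass
class EventSet:
    """Threshold-exceedance intervals of a z-scored series."""

    events: list
    threshold: float
    source: str = ""

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"start_bce": e.start_bce, "end_bce": e.end_bce,
                 "sign": e.sign, "peak_z": e.peak_z}
                for e in self.events
            ]
        )


def detect_events(years_bce, values, k: float = 1.0, source: str = "") -> EventSet:
    """Flag maximal runs where |z| >= k standard deviations.

    z-scores use the mean and SD of the supplied window itself.  Each run
    becomes an interval carrying the sign and the peak z inside it.
    """
    years = np.asarray(years_bce, float)
    y = np.asarray(values, float)
    ok = ~np.isnan(y)
    mu = y[ok].mean()
    sd = y[ok].std()
    if sd == 0:
        raise ValueError("degenerate series: zero standard deviation")
    z = (y - mu) / sd
    events = []
    exceed = np.abs(z) >= k
    exceed &= ok
    # split runs where the sign flips inside a run
    sign = np.sign(z)
    i = 0
    n = len(z)
    while i < n:
        if not exceed[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and exceed[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        seg = z[i : j + 1]
        peak = seg[np.argmax(np.abs(seg))]
        events.append(
            Event(
                start_bce=float(years[i]),
                end_bce=float(years[j]),
                sign="positive" if peak > 0 else "negative",
                peak_z=float(peak),
            )
        )
        i = j + 1
    return EventSet(events=events, threshold=k, source=source)
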