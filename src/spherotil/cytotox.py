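"""Killing-rate kinetics from red-object (target-cell) area time series.

The killing rate is the most negative OLS slope over a sliding window of the
target-well area series, normalized against the growth of unpulsed control
wells over the same window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RedAreaSeries:
    """Total red-object area per well on a uniform time grid."""

    times_h: np.ndarray
    area_um2: np.ndarray
    condition: str = "target"   # "target" or "control"
    well: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.area_um2 = np.asarray(self.area_um2, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.area_um2.shape:
            raise ValueError("times and areas must be 1D arrays of equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.area_um2 < 0):
            raise ValueError("areas must be non-negative")


@dataclass
class KillingRate:
    raw_slope: float          # um^2/h, most negative target slope
    control_slope: float      # um^2/h over the same window
    normalized_rate: float    # um^2/h (difference) or unitless (ratio)
    window: tuple[float, float]


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    t = t - t.mean()
    denom = (t**2).sum()
    if denom == 0:
        raise ValueError("degenerate time window")
    return float((t * (y - y.mean())).sum() / denom)


def steepest_slope(series: RedAreaSeries, window_points: int = 8,
                   bounds_h: tuple[float, float] | None = None
                   ) -> tuple[float, tuple[float, float]]:
    """Most negative OLS slope over contiguous windows of ``window_points``.

    ``bounds_h`` restricts the search to windows fully inside
    ``[killing_onset, eradication]`` when supplied.  Returns the slope
    (um^2/h) and the (start_h, end_h) of the winning window.
    """
    if window_points < 3:
        raise ValueError("window must span >= 3 samples")
    t, y = series.times_h, series.area_um2
    if len(t) < window_points:
        raise ValueError(f"series of {len(t)} points shorter than window {window_points}")
    best = None
    for i in range(len(t) - window_points + 1):
        tw = t[i:i + window_points]
        if bounds_h is not None and (tw[0] < bounds_h[0] or tw[-1] > bounds_h[1]):
            continue
        s = _ols_slope(tw, y[i:i + window_points])
        if best is None or s < best[0]:
            best = (s, (float(tw[0]), float(tw[-1])))
    if best is None:
        raise ValueError("no window fits inside the supplied bounds")
    return best


def detect_killing_bounds(series: RedAreaSeries, decline_points: int = 3,
                          floor_frac: float = 0.05) -> tuple[float, float]:
    """Heuristic (onset, eradication) bounds: first sustained decline and
    first time the area drops below ``floor_frac`` of its running peak.
    Off by default in :func:`killing_rate`."""
    y = series.area_um2
    d = np.diff(y)
    onset = series.times_h[0]
    for i in range(len(d) - decline_points + 1):
        if np.all(d[i:i + decline_points] < 0):
            onset = float(series.times_h[i])
            break
    peak = float(y.max())
    end = series.times_h[-1]
    below = np.where(y < floor_frac * peak)[0]
    if len(below):
        end = float(series.times_h[below[0]])
    return onset, max(end, onset)


def killing_rate(target_series: RedAreaSeries, control_series: RedAreaSeries,
                 window_points: int = 8,
                 bounds_h: tuple[float, float] | None = None,
                 normalization: str = "difference") -> KillingRate:
    """Normalized killing rate: steepest target decline against control growth.

    ``difference`` (default): ``control_slope - raw_slope`` (>= 0 when killing
    outpaces growth).  ``ratio``: ``raw_slope / control_slope``.
    """
    if len(target_series.times_h) != len(control_series.times_h) or not np.allclose(
            target_series.times_h, control_series.times_h):
        raise ValueError("target and control series must share a time grid")
    raw, window = steepest_slope(target_series, window_points, bounds_h)
    mask = (control_series.times_h >= window[0]) & (control_series.times_h <= window[1])
    ctrl = _ols_slope(control_series.times_h[mask], control_series.area_um2[mask])
    if normalization == "difference":
        norm = ctrl - raw
    elif normalization == "ratio":
        if ctrl == 0:
            raise ValueError("control slope is zero; ratio normalization undefined")
        norm = raw / ctrl
    else:
        raise ValueError("normalization must be 'difference' or 'ratio'")
    return KillingRate(raw_slope=raw, control_slope=ctrl,
                       normalized_rate=float(norm), window=window)
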