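"""Psychometric metrics extracted from measured intelligibility points.

Three clinical metrics characterize a speech audiometry session: the 50%
intelligibility score (the speech reception threshold, SRT - the level or
SNR at which half the phonemes are repeated correctly), the maximum
intelligibility (the highest percent score reached anywhere on the curve,
which stays below 100% under rollover), and the slope of the psychometric
function at the 50% point (% per dB), which summarizes how abruptly
intelligibility grows around threshold.

Two estimators are provided. ``interpolation`` (default) monotonizes the
points by isotonic pooling - measured curves may be locally non-monotone
(a speech maximum) while the SRT is defined on the rising limb - and reads
the first 50% crossing off the piecewise-linear curve, scanning in the
direction of improving intelligibility. ``logistic_fit`` least-squares
fits a four-parameter logistic and evaluates its 50% crossing and the
analytic derivative there; it gives smoother slope estimates when the
points are dense.

When the points never bracket 50%, the SRT (and hence the slope) is
undefined: both estimators return ``None`` explicitly rather than
extrapolating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit, isotonic_regression

from .procedures import IntelligibilityPoint

__all__ = ["PsychometricSummary", "srt50", "max_intelligibility", "slope_at_50",
           "summarize"]

Method = Literal["interpolation", "logistic_fit"]


@dataclass(frozen=True)
class PsychometricSummary:
    srt50: float | None
    max_intelligibility: float
    slope50: float | None
    method: Method


def _xy(points: Sequence[IntelligibilityPoint]) -> tuple[np.ndarray, np.ndarray]:
    pts = sorted(points, key=lambda p: p.x)
    x = np.array([p.x for p in pts], dtype=float)
    y = np.array([p.pct for p in pts], dtype=float)
    # collapse duplicate x to their mean so the curve is a function of x
    if len(np.unique(x)) != len(x):
        ux = np.unique(x)
        uy = np.array([y[x == v].mean() for v in ux])
        x, y = ux, uy
    return x, y


def _monotone(y: np.ndarray) -> np.ndarray:
    return isotonic_regression(y, increasing=True).x


def _four_param_logistic(x, floor, ceiling, k, x0):
    return floor + (ceiling - floor) / (1.0 + np.exp(-k * (x - x0)))


def _fit_logistic(x: np.ndarray, y: np.ndarray):
    floor0 = float(np.clip(y.min(), 0.0, 49.0))
    ceil0 = float(np.clip(y.max(), 51.0, 100.0))
    x0_0 = float(x[np.argmin(np.abs(y - 50.0))])
    p0 = (floor0, ceil0, 0.5, x0_0)
    bounds = (
        [0.0, 50.0 + 1e-6, 1e-4, x.min() - 60.0],
        [50.0 - 1e-6, 100.0, 20.0, x.max() + 60.0],
    )
    popt, _ = curve_fit(
        _four_param_logistic, x, y, p0=p0, bounds=bounds, maxfev=20000
    )
    return popt


def _fit_srt_and_slope(points) -> tuple[float | None, float | None]:
    x, y = _xy(points)
    if len(x) < 2 or y.max() < 50.0 or y.min() > 50.0:
        return None, None
    floor, ceiling, k, x0 = _fit_logistic(x, y)
    c = (50.0 - floor) / (ceiling - floor)
    if not 0.0 < c < 1.0:
        return None, None
    srt = x0 - np.log(1.0 / c - 1.0) / k
    if not x.min() <= srt <= x.max():
        return None, None
    slope = (ceiling - floor) * k * c * (1.0 - c)
    return float(srt), float(slope)


def _interp_crossing(x: np.ndarray, y: np.ndarray) -> tuple[float, int] | None:
    """First x where the monotone piecewise-linear curve reaches 50%.

    Returns ``(srt, i)`` with ``i`` the index of the first point at or
    above 50%, or None when 50% is never bracketed.
    """
    if y.max() < 50.0 or y.min() > 50.0:
        return None
    i = int(np.argmax(y >= 50.0))
    if y[i] == 50.0:
        return float(x[i]), i
    if i == 0:  # curve starts above 50 without crossing inside the range
        return None
    x1, x2, y1, y2 = x[i - 1], x[i], y[i - 1], y[i]
    return float(x1 + (50.0 - y1) * (x2 - x1) / (y2 - y1)), i


def srt50(
    points: Sequence[IntelligibilityPoint], method: Method = "interpolation"
) -> float | None:
    """50% intelligibility score, or None when 50% is never bracketed."""
    if len(points) < 2:
        raise ValueError("need at least two points to locate the 50% crossing")
    if method == "logistic_fit":
        return _fit_srt_and_slope(points)[0]
    x, y = _xy(points)
    hit = _interp_crossing(x, _monotone(y))
    return None if hit is None else hit[0]


def max_intelligibility(points: Sequence[IntelligibilityPoint]) -> float:
    """Maximum percent score over the points (the speech maximum)."""
    if len(points) == 0:
        raise ValueError("need at least one point")
    return float(max(p.pct for p in points))


def slope_at_50(
    points: Sequence[IntelligibilityPoint], method: Method = "interpolation"
) -> float | None:
    """Slope (% per dB) of the psychometric function at its 50% point."""
    if method == "logistic_fit":
        return _fit_srt_and_slope(points)[1]
    x, y = _xy(points)
    y = _monotone(y)
    hit = _interp_crossing(x, y)
    if hit is None:
        return None
    _, i = hit
    if y[i] > 50.0:  # interior crossing: slope of the bracketing segment
        return float((y[i] - y[i - 1]) / (x[i] - x[i - 1]))
    # exact 50% at a point: slope towards the next strictly higher point
    above = np.nonzero(y > 50.0)[0]
    if len(above) == 0:
        return None
    j = int(above[0])
    return float((y[j] - y[i]) / (x[j] - x[i]))


def summarize(
    points: Sequence[IntelligibilityPoint], method: Method = "interpolation"
) -> PsychometricSummary:
    """All three metrics of one session's point set."""
    return PsychometricSummary(
        srt50=srt50(points, method),
        max_intelligibility=max_intelligibility(points),
        slope50=slope_at_50(points, method),
        method=method,
    )
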