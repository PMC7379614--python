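"""Relative two-phase decay model.

After transcription is arrested with rifampicin, a transcript pool typically
shows a short *delay* phase (rifampicin uptake, polymerase run-off) followed
by first-order *decay*.  The estimator implemented here anchors the fit at
the timepoint of maximal expression (the end of the delay phase), tries every
window running from that peak to each later timepoint, keeps the window whose
log-linear fit has maximal R², and converts the window endpoints into a
half-life:

    T_1/2 = (t - t0) / (log2 N0 - log2 N)

where (t0, N0) is the peak and (t, N) the chosen window end.  The slope of
the ordinary least-squares fit of ln(expression) on time is reported
alongside; for clean exponential decay ln2/|slope| equals the endpoint
half-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ExpressionSeries",
    "DecayFit",
    "FitSettings",
    "DecayClass",
    "halflife_from_endpoints",
    "fit_two_phase",
    "classify_decay",
]


class DecayClass:
    """Decay classification labels (plain strings, usable as enum-lites)."""

    EXPONENTIAL = "exponential"
    NO_DECAY = "no_decay"
    NON_EXPONENTIAL = "non_exponential"
    INSUFFICIENT_DATA = "insufficient_data"

    ALL = (EXPONENTIAL, NO_DECAY, NON_EXPONENTIAL, INSUFFICIENT_DATA)


@dataclass(frozen=True)
class FitSettings:
    """Tunable thresholds of the two-phase fit.

    Parameters
    ----------
    min_window_points
        Minimum points per candidate window (>= 2).  With the default 3, a
        2-point window is used only when no 3-point window exists; its R² is
        then undefined.
    r2_min
        Fits with defined R² below this are classified non-exponential.
    max_halflife_min
        Half-lives above this cap (minutes) are classified no-decay.
    require_full_detection
        If true, any undetected (zero-count) timepoint makes the series
        ``insufficient_data``; if false, undetected points are dropped
        before fitting.
    """

    min_window_points: int = 3
    r2_min: float = 0.5
    max_halflife_min: float = 1000.0
    require_full_detection: bool = True

    def __post_init__(self) -> None:
        if self.min_window_points < 2:
            raise ValidationError("min_window_points must be >= 2")
        if not 0.0 <= self.r2_min <= 1.0:
            raise ValidationError("r2_min must lie in [0, 1]")
        if self.max_halflife_min <= 0:
            raise ValidationError("max_halflife_min must be positive")


@dataclass
class ExpressionSeries:
    """One entity's expression over the post-rifampicin chase.

    ``values`` are non-negative expression levels (copies·mL⁻¹ for qPCR,
    mRNA:rRNA ratio for metatranscriptomes) at strictly increasing
    ``timepoints`` (minutes since rifampicin addition).  The pre-treatment
    control taken before rifampicin is stored separately in
    ``pre_treatment_value`` and never enters the fit: pre-treatment abundance
    is typically several-fold below the post-treatment peak and would fake
    growth if included.
    """

    entity_id: str
    timepoints: np.ndarray
    values: np.ndarray
    condition: str = ""
    detected: np.ndarray | None = None
    pre_treatment_value: float | None = None

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.detected is None:
            self.detected = self.values > 0
        self.detected = np.asarray(self.detected, dtype=bool)
        if not (len(self.timepoints) == len(self.values) == len(self.detected)):
            raise ValidationError(
                f"{self.entity_id}: timepoints/values/detected lengths differ"
            )
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValidationError(f"{self.entity_id}: timepoints must strictly increase")
        if np.any(self.values < 0):
            raise ValidationError(f"{self.entity_id}: negative expression value")
        if self.pre_treatment_value is not None and self.pre_treatment_value < 0:
            raise ValidationError(f"{self.entity_id}: negative pre-treatment value")


@dataclass
class DecayFit:
    """Result of a two-phase fit for one series.

    ``half_life_min`` is defined (positive) iff ``decay_class`` is
    exponential; ``r_squared`` is ``None`` for 2-point windows.
    """

    entity_id: str
    condition: str = ""
    t0_time: float | None = None
    end_time: float | None = None
    n_window: int = 0
    slope_ln: float | None = None
    r_squared: float | None = None
    half_life_min: float | None = None
    decay_class: str = DecayClass.INSUFFICIENT_DATA


def halflife_from_endpoints(t0: float, n0: float, t: float, n: float) -> float | None:
    """Half-life from the window endpoints: (t − t0) / (log2 N0 − log2 N).

    Positive iff the pool shrank (N < N0); negative for growth.  Returns
    ``None`` when N == N0 (no change: a half-life is undefined and the
    series signals no decay).

    Raises
    ------
    ValidationError
        If t <= t0 or either expression value is non-positive.
    """
    if t <= t0:
        raise ValidationError(f"endpoint time {t} must exceed start time {t0}")
    if n0 <= 0 or n <= 0:
        raise ValidationError("expression values must be positive for a half-life")
    if n == n0:
        return None
    return (t - t0) / (math.log2(n0) - math.log2(n))


def classify_decay(
    slope_ln: float,
    r_squared: float | None,
    half_life: float | None,
    settings: FitSettings = FitSettings(),
) -> str:
    """Assign a decay class from a fitted slope, R² and half-life.

    no_decay if the slope is non-negative or the half-life is undefined,
    non-positive, or above the cap; non_exponential if R² is defined and
    below ``settings.r2_min``; exponential otherwise.
    """
    if slope_ln >= 0:
        return DecayClass.NO_DECAY
    if half_life is None or half_life <= 0 or half_life > settings.max_halflife_min:
        return DecayClass.NO_DECAY
    if r_squared is not None and r_squared < settings.r2_min:
        return DecayClass.NON_EXPONENTIAL
    return DecayClass.EXPONENTIAL


def _ols_loglinear(t: np.ndarray, v: np.ndarray) -> tuple[float, float | None]:
    """OLS of ln(v) on t; returns (slope, R² or None for 2 points)."""
    logv = np.log(v)
    if len(t) == 2:
        slope = (logv[1] - logv[0]) / (t[1] - t[0])
        return float(slope), None
    res = stats.linregress(t, logv)
    return float(res.slope), float(res.rvalue**2)


def fit_two_phase(
    series: ExpressionSeries, settings: FitSettings = FitSettings()
) -> DecayFit:
    """Fit the relative two-phase decay model to one expression series.

    The peak (latest timepoint attaining the maximum value — an earlier
    plateau belongs to the delay phase) anchors every candidate window; the
    window with maximal R² of the log-linear fit wins, ties going to the
    longer window.  The half-life comes from the endpoint formula applied to
    the first and last value of the chosen window, the slope from the OLS
    fit over the whole window.
    """
    fit = DecayFit(entity_id=series.entity_id, condition=series.condition)

    detected = series.detected
    if settings.require_full_detection and not bool(np.all(detected)):
        return fit  # insufficient_data
    t = series.timepoints[detected]
    v = series.values[detected]
    if len(t) < 2:
        return fit

    if np.all(v == v[0]):
        i0 = int(np.flatnonzero(v == v.max())[-1])
        fit.decay_class = DecayClass.NO_DECAY
        fit.t0_time = float(t[i0])
        return fit

    i0 = int(np.flatnonzero(v == v.max())[-1])
    n = len(t)
    if n - i0 < 2:
        # peak is the last point: nothing to fit downstream of it
        fit.decay_class = DecayClass.NO_DECAY
        fit.t0_time = float(t[i0])
        return fit

    candidates = [
        (j, n_pts)
        for j in range(i0 + 1, n)
        if (n_pts := j - i0 + 1) >= settings.min_window_points
    ]
    if not candidates:
        # 2-point fallback: only possible window is peak -> next point(s)
        candidates = [(j, j - i0 + 1) for j in range(i0 + 1, n)]

    best: tuple[float, int, float, float | None] | None = None  # (r2, j, slope, r2raw)
    for j, _ in candidates:
        slope, r2 = _ols_loglinear(t[i0 : j + 1], v[i0 : j + 1])
        r2_key = -math.inf if r2 is None else r2
        # ties -> longer window (larger j)
        if best is None or (r2_key, j) > (best[0], best[1]):
            best = (r2_key, j, slope, r2)
    assert best is not None
    _, j, slope, r2 = best

    fit.t0_time = float(t[i0])
    fit.end_time = float(t[j])
    fit.n_window = j - i0 + 1
    fit.slope_ln = slope
    fit.r_squared = r2
    half_life = halflife_from_endpoints(t[i0], v[i0], t[j], v[j])
    fit.decay_class = classify_decay(slope, r2, half_life, settings)
    if fit.decay_class == DecayClass.EXPONENTIAL:
        fit.half_life_min = half_life
    return fit


def fits_to_records(fits: Sequence[DecayFit]) -> list[dict]:
    """Flatten fits into plain dicts for tabular output."""
    return [
        {
            "entity_id": f.entity_id,
            "condition": f.condition,
            "t0_time": f.t0_time,
            "end_time": f.end_time,
            "n_window": f.n_window,
            "slope_ln": f.slope_ln,
            "r_squared": f.r_squared,
            "half_life_min": f.half_life_min,
            "decay_class": f.decay_class,
        }
        for f in fits
    ]
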