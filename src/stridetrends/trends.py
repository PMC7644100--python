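"""Trend segments and their summary statistics.

A fitted piecewise-linear trend is cut at its knots into linear segments.
Two dimensionless quantities describe each segment:

* normalized duration — the sum of the gait-parameter values over the
  segment's strides divided by the trial mean of that parameter; for a
  stationary parameter this is within its coefficient of variation of the
  plain stride count, and it is the quantity whose distribution has an
  exponential tail;
* normalized slope — the trend's value change over the segment divided by
  the product of the trial mean and the normalized duration, i.e. the
  per-stride relative rate of change; its distribution is heavy-tailed and
  well approximated by a Cauchy law.

Segments tile the trial: the piece before the first knot and after the
last knot count as segments, and a stride sitting exactly on a knot is
assigned to the segment on its left.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .mars import MarsModel, predict
from .scaling import estimate_alpha

__all__ = [
    "TrendSegment",
    "ExponentialFit",
    "CauchyFit",
    "extract_segments",
    "normalized_duration",
    "normalized_slope",
    "fit_exponential",
    "fit_cauchy",
    "small_slope_sections",
]

MIN_SEGMENT_STRIDES = 2


@dataclass(frozen=True)
class TrendSegment:
    """One linear piece of a piecewise-linear trend.

    ``start_idx``/``end_idx`` are the 1-based stride indices of the
    segment's boundary knots (or series ends), so consecutive segments
    share their interior boundary.  For duration/slope statistics the
    shared boundary stride is counted in the left segment only; ``first``
    marks the leading segment, which owns its left boundary stride.
    """

    start_idx: int
    end_idx: int
    delta_y: float
    norm_duration: float
    norm_slope: float
    first: bool = False

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("end_idx must exceed start_idx")

    @property
    def n_strides(self) -> int:
        """Number of strides counted toward this segment."""
        return self.end_idx - self.start_idx + (1 if self.first else 0)

    def covered_values(self, values: np.ndarray) -> np.ndarray:
        """The raw series over this segment's strides (1-based indexing)."""
        lo = self.start_idx - 1 if self.first else self.start_idx
        return values[lo:self.end_idx]


def _values_of(series) -> np.ndarray:
    return np.asarray(getattr(series, "values", series), dtype=float)


def normalized_duration(segment: TrendSegment, series) -> float:
    """Sum of parameter values over the segment, divided by the trial mean."""
    values = _values_of(series)
    covered = segment.covered_values(values)
    if covered.size == 0:
        raise ValueError("segment covers no strides of this series")
    return float(covered.sum() / values.mean())


def normalized_slope(segment: TrendSegment, series) -> float:
    """Trend change over the segment per unit of normalized duration."""
    nd = normalized_duration(segment, series)
    if nd == 0:
        raise ValueError("zero normalized duration")
    values = _values_of(series)
    return float(segment.delta_y / (values.mean() * nd))


def extract_segments(model: MarsModel, series) -> list[TrendSegment]:
    """Cut a fitted trend at its knots into tiling linear segments.

    An intercept-only model has no trend, hence no segments.  Segments
    shorter than ``MIN_SEGMENT_STRIDES`` counted strides (possible when two
    knots are adjacent) are discarded: a one-stride piece has no defined
    slope.
    """
    values = _values_of(series)
    n = values.size
    if not model.terms:
        return []
    knots = [k for k in model.knots if 1.0 < k < n]
    boundaries = [1.0] + knots + [float(n)]
    trend_at = predict(model, np.asarray(boundaries))
    segments: list[TrendSegment] = []
    for j in range(len(boundaries) - 1):
        start, end = int(round(boundaries[j])), int(round(boundaries[j + 1]))
        first = j == 0
        count = end - start + (1 if first else 0)
        if count < MIN_SEGMENT_STRIDES:
            continue
        # per-stride slope of this piece, accumulated over counted strides
        slope = (trend_at[j + 1] - trend_at[j]) / (end - start)
        delta_y = float(slope * count)
        shell = TrendSegment(start, end, delta_y, np.nan, np.nan, first)
        nd = normalized_duration(shell, values)
        ns = float(delta_y / (values.mean() * nd))
        segments.append(TrendSegment(start, end, delta_y, nd, ns, first))
    return segments


@dataclass(frozen=True)
class ExponentialFit:
    """Maximum-likelihood exponential fit, rate = 1/mean."""

    rate: float
    n: int
    gof_p: float


@dataclass(frozen=True)
class CauchyFit:
    location: float
    scale: float
    n: int
    gof_p: float


def fit_exponential(durations: Sequence[float], gof: str = "ks") -> ExponentialFit:
    """Fit an exponential law to (normalized) trend durations.

    The MLE rate is the reciprocal sample mean.  Goodness of fit is a
    Kolmogorov-Smirnov test against the fitted law by default; ``gof="ad"``
    uses a Monte-Carlo Anderson-Darling test, which weighs the tails more
    heavily and can disagree with KS.
    """
    x = np.asarray(durations, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 durations")
    if np.any(x <= 0):
        raise ValueError("durations must be strictly positive")
    rate = 1.0 / x.mean()
    if gof == "ks":
        p = float(stats.kstest(x, "expon", args=(0.0, 1.0 / rate)).pvalue)
    elif gof == "ad":
        res = stats.goodness_of_fit(stats.expon, x, known_params={"loc": 0.0},
                                    statistic="ad", n_mc_samples=199,
                                    rng=np.random.default_rng(0))
        p = float(res.pvalue)
    else:
        raise ValueError("gof must be 'ks' or 'ad'")
    return ExponentialFit(rate=float(rate), n=x.size, gof_p=p)


def fit_cauchy(slopes: Sequence[float], gof: str = "ks") -> CauchyFit:
    """Maximum-likelihood Cauchy fit to (normalized) trend slopes."""
    x = np.asarray(slopes, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 slopes")
    if np.ptp(x) == 0:
        raise ValueError("slopes are degenerate (all equal)")
    # heavy tails defeat generic starting values; seed the MLE with the
    # median and half-IQR, which are consistent for location and scale
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    loc, scale = stats.cauchy.fit(x, loc=q2, scale=max((q3 - q1) / 2, 1e-30))
    if gof == "ks":
        p = float(stats.kstest(x, "cauchy", args=(loc, scale)).pvalue)
    elif gof == "ad":
        res = stats.goodness_of_fit(stats.cauchy, x, statistic="ad",
                                    n_mc_samples=199,
                                    rng=np.random.default_rng(0))
        p = float(res.pvalue)
    else:
        raise ValueError("gof must be 'ks' or 'ad'")
    return CauchyFit(location=float(loc), scale=float(scale),
                     n=x.size, gof_p=p)


def small_slope_sections(segments: Sequence[TrendSegment], series,
                         min_norm_len: float = 40.0,
                         max_abs_norm_slope: float = 1e-3,
                         ) -> list[tuple[np.ndarray, float]]:
    """Raw-series fragments over long, nearly flat trend segments.

    Selects segments whose normalized duration exceeds ``min_norm_len``
    (strict) and whose absolute normalized slope is below
    ``max_abs_norm_slope``, and returns each fragment with its madogram
    scaling exponent.  On such fragments the trend contributes almost
    nothing, so the exponent reflects the residual dynamics.
    """
    if min_norm_len <= 0 or max_abs_norm_slope <= 0:
        raise ValueError("thresholds must be positive")
    values = _values_of(series)
    out: list[tuple[np.ndarray, float]] = []
    for seg in segments:
        if seg.norm_duration > min_norm_len and \
                abs(seg.norm_slope) < max_abs_norm_slope:
            frag = seg.covered_values(values)
            out.append((frag, estimate_alpha(frag, "MD").alpha))
    return out
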