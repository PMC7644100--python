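"""Scaling-exponent estimators for short physiological time series.

Two families of estimators are provided:

* **DFA-n** (detrended fluctuation analysis of polynomial order n).  The
  mean-centred series is integrated into a profile, the profile is split
  into non-overlapping boxes of size ``n``, an order-n polynomial is fitted
  in each box, and the root-mean-square deviation from the fits gives the
  fluctuation function F(n).  The scaling exponent alpha is the slope of
  log F against log n.

* **Madogram** (order-1 variogram).  For a self-affine path Y, the power
  variation V(l) = (1/(2(N-l))) sum |Y_{i+l} - Y_i| at lags 1 and 2 yields
  the box-dimension estimate D = 2 - (log V(2) - log V(1)) / log 2 and the
  scaling exponent alpha = 2 - D.  It is O(N), has no tuning parameters,
  and is notably robust on short windows.

Conventions.  DFA takes the *noise-like* series (a bounded gait parameter
or fGn) and integrates internally.  The madogram operates on the *path*:
:func:`madogram_alpha` expects a cumulatively summed signal, and
:func:`estimate_alpha` with ``method="MD"`` integrates the mean-centred
series before calling it.  In window sweeps over FBM paths, DFA is applied
to within-window increments and the madogram to the window path itself;
both then estimate the same Hurst exponent H.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DfaResult",
    "MadogramResult",
    "ScalingEstimate",
    "WindowSweepResult",
    "default_window_sizes",
    "dfa",
    "madogram_alpha",
    "estimate_alpha",
    "window_sweep",
]

METHODS = ("DFA1", "DFA2", "DFA3", "MD")


class ConstantSeriesError(ValueError):
    """Raised when the scaling exponent is undefined (constant input)."""


@dataclass(frozen=True)
class DfaResult:
    order: int
    alpha: float
    window_sizes: tuple[int, ...]
    fluctuation: tuple[float, ...]
    fit_r2: float


@dataclass(frozen=True)
class MadogramResult:
    alpha: float
    fractal_dim: float
    v1: float
    v2: float
    p: float = 1.0


@dataclass(frozen=True)
class ScalingEstimate:
    """A scaling exponent with its method tag and provenance."""

    alpha: float
    method: str
    n: int
    detail: object = field(default=None, compare=False)


def default_window_sizes(n: int, order: int) -> list[int]:
    """Geometric grid of DFA box sizes, ratio 2**(1/8), from 4 to N/4.

    The lower end is raised to ``2 * (order + 1)`` for higher detrending
    orders so every box supports its polynomial fit with residual degrees
    of freedom.
    """
    lo = max(4, 2 * (order + 1))
    hi = n // 4
    if hi < lo:
        raise ValueError(
            f"series too short for DFA{order}: need >= {4 * lo} samples, got {n}"
        )
    sizes: list[int] = []
    v = float(lo)
    while v <= hi + 1e-9:
        iv = int(round(v))
        if not sizes or iv > sizes[-1]:
            sizes.append(iv)
        v *= 2.0 ** 0.125
    return sizes


def _dfa_fluctuation(profile: np.ndarray, size: int, order: int) -> float:
    n_boxes = profile.size // size
    seg = profile[: n_boxes * size].reshape(n_boxes, size)
    t = np.arange(size, dtype=float)
    # one Vandermonde solve for all boxes of this size
    v = np.vander(t, order + 1)
    coef, *_ = np.linalg.lstsq(v, seg.T, rcond=None)
    resid = seg.T - v @ coef
    return float(np.sqrt(np.mean(resid**2)))


def dfa(y: Sequence[float], order: int = 1,
        window_sizes: Iterable[int] | None = None) -> DfaResult:
    """Detrended fluctuation analysis of order ``order``.

    Parameters
    ----------
    y : array-like
        Noise-like series (integrated internally).
    order : int
        Polynomial detrending order (1-3 typical).
    window_sizes : iterable of int, optional
        Box sizes; defaults to :func:`default_window_sizes`.
    """
    y = np.asarray(y, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if np.ptp(y) == 0.0:
        raise ConstantSeriesError("DFA undefined for constant series")
    if window_sizes is None:
        sizes = default_window_sizes(y.size, order)
    else:
        sizes = sorted(set(int(s) for s in window_sizes))
        if any(s < order + 2 for s in sizes):
            raise ValueError(f"window sizes must be >= order + 2 = {order + 2}")
        if y.size < 2 * max(sizes):
            raise ValueError("series shorter than twice the largest box")
    profile = np.cumsum(y - y.mean())
    fluct = np.array([_dfa_fluctuation(profile, s, order) for s in sizes])
    if np.any(fluct == 0.0):
        raise ConstantSeriesError("zero fluctuation; exponent undefined")
    logn = np.log(sizes)
    logf = np.log(fluct)
    slope, intercept = np.polyfit(logn, logf, 1)
    pred = slope * logn + intercept
    sst = np.sum((logf - logf.mean()) ** 2)
    r2 = 1.0 - np.sum((logf - pred) ** 2) / sst if sst > 0 else 1.0
    return DfaResult(order=order, alpha=float(slope),
                     window_sizes=tuple(sizes),
                     fluctuation=tuple(fluct), fit_r2=float(r2))


def madogram_alpha(path: Sequence[float], p: float = 1.0) -> MadogramResult:
    """Madogram (order-p variogram) scaling exponent of a *path*.

    The input must already be the unbounded, cumulatively summed signal;
    use :func:`estimate_alpha` for bounded noise-like series.
    """
    path = np.asarray(path, dtype=float)
    if path.size < 3:
        raise ValueError("madogram needs at least 3 samples")
    n = path.size
    d1 = np.abs(path[1:] - path[:-1]) ** p
    d2 = np.abs(path[2:] - path[:-2]) ** p
    v1 = d1.sum() / (2.0 * (n - 1))
    v2 = d2.sum() / (2.0 * (n - 2))
    if v1 == 0.0 or v2 == 0.0:
        raise ConstantSeriesError("zero power variation; exponent undefined")
    fractal_dim = 2.0 - (np.log(v2) - np.log(v1)) / (p * np.log(2.0))
    return MadogramResult(alpha=float(2.0 - fractal_dim),
                          fractal_dim=float(fractal_dim),
                          v1=float(v1), v2=float(v2), p=p)


def estimate_alpha(series: Sequence[float], method: str = "MD") -> ScalingEstimate:
    """Estimate the scaling exponent of a noise-like series.

    ``method`` is one of ``DFA1``, ``DFA2``, ``DFA3`` (polynomial
    detrending of the internally integrated profile) or ``MD`` (madogram of
    the cumulative sum of the mean-centred series).
    """
    values = np.asarray(getattr(series, "values", series), dtype=float)
    method = method.upper()
    if method.startswith("DFA"):
        order = int(method[3:])
        res = dfa(values, order=order)
        return ScalingEstimate(alpha=res.alpha, method=method,
                               n=values.size, detail=res)
    if method == "MD":
        path = np.cumsum(values - values.mean())
        res = madogram_alpha(path)
        return ScalingEstimate(alpha=res.alpha, method="MD",
                               n=values.size, detail=res)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


@dataclass(frozen=True)
class WindowSweepResult:
    """Per-window scaling exponents as a function of window length."""

    k_values: tuple[int, ...]
    alphas: Mapping[str, Mapping[int, tuple[float, ...]]]

    def median(self, method: str, k: int) -> float:
        return float(np.median(self.alphas[method][k]))


def window_sweep(series: np.ndarray, k_values: Iterable[int],
                 methods: Sequence[str] = ("DFA1", "MD"),
                 input_kind: str = "noise") -> WindowSweepResult:
    """Scaling exponents of non-overlapping windows of varying length.

    Parameters
    ----------
    series : 1-d or 2-d array
        One series, or an ensemble with one series per row.
    k_values : iterable of int
        Window lengths; each series is split into ``floor(N/k)``
        non-overlapping windows starting at index 0, remainder discarded.
    methods : sequence of str
        Estimators to apply per window.
    input_kind : {"noise", "path"}
        ``"path"`` for self-affine paths (FBM): DFA then operates on
        within-window increments and the madogram on the window path
        directly.  ``"noise"`` for bounded series: both estimators receive
        the window values under the :func:`estimate_alpha` conventions.
    """
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    if input_kind not in ("noise", "path"):
        raise ValueError("input_kind must be 'noise' or 'path'")
    ks = sorted(set(int(k) for k in k_values))
    if arr.shape[1] < max(ks):
        raise ValueError("series shorter than the largest window")
    out: dict[str, dict[int, tuple[float, ...]]] = {m: {} for m in methods}
    for k in ks:
        n_win = arr.shape[1] // k
        wins = arr[:, : n_win * k].reshape(arr.shape[0] * n_win, k)
        for method in methods:
            vals = []
            for w in wins:
                if input_kind == "path":
                    if method == "MD":
                        vals.append(madogram_alpha(w).alpha)
                    else:
                        vals.append(
                            dfa(np.diff(w), order=int(method[3:])).alpha)
                else:
                    vals.append(estimate_alpha(w, method).alpha)
            out[method][k] = tuple(vals)
    return WindowSweepResult(k_values=tuple(ks), alphas=out)
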