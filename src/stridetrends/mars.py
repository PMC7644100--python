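"""One-dimensional additive piecewise-linear regression splines.

Trends are modelled as a linear combination of hinge ("reflected pair")
basis functions,

    f(x) = b0 + sum_m b_m h_m(x),   h in {max(0, x - t), max(0, t - x)},

built greedily (forward pass: at each step the reflected pair whose
addition maximally reduces the residual sum of squares is appended and all
coefficients are re-estimated by least squares) and then pruned backward by
generalized cross-validation,

    GCV(lam) = SSE(lam) / [1 - M(lam)/N]^2,   M(lam) = r + c K,

where r counts linearly independent basis functions (including the
intercept), K counts distinct knots, and c is the knot penalty (default 2,
the customary value for additive models).  Because each reflected pair
spans {1, x - t, |x - t|}, the model is an arbitrary continuous piecewise
linear function of x; in gait analysis x is simply the stride index.

Only the additive, order-1 case is implemented: candidate terms are never
multiplied by an existing hinge, so the fit is a sum of univariate pieces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["BasisTerm", "MarsConfig", "MarsModel",
           "forward_pass", "backward_prune", "fit_mars", "predict"]


@dataclass(frozen=True)
class BasisTerm:
    """One hinge function: ``max(0, x - knot)`` ('+') or ``max(0, knot - x)`` ('-')."""

    knot: float
    direction: str  # '+' or '-'
    coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("+", "-"):
            raise ValueError("direction must be '+' or '-'")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.direction == "+":
            return np.maximum(0.0, x - self.knot)
        return np.maximum(0.0, self.knot - x)


@dataclass(frozen=True)
class MarsConfig:
    """Fitting configuration.

    stop_threshold : minimum R^2 gain per forward step (default 1e-3).
    gcv_penalty_c  : knot penalty c in M = r + cK (default 2).
    max_terms      : ceiling on basis functions incl. intercept (default 43,
        i.e. up to 21 knots — twice the knot count expected of a 5-minute
        trial with ~23-stride mean segment duration, so the forward budget
        never binds on typical trials).
    """

    stop_threshold: float = 1e-3
    gcv_penalty_c: float = 2.0
    max_terms: int = 43

    def __post_init__(self) -> None:
        if self.stop_threshold <= 0:
            raise ValueError("stop_threshold must be > 0")
        if self.gcv_penalty_c < 0:
            raise ValueError("gcv_penalty_c must be >= 0")
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")


@dataclass(frozen=True)
class MarsModel:
    intercept: float
    terms: tuple[BasisTerm, ...]
    gcv: float
    fitted: np.ndarray = field(compare=False)
    residuals: np.ndarray = field(compare=False)
    effective_params: float
    n_terms: int  # basis functions including the intercept

    @property
    def knots(self) -> list[float]:
        """Sorted distinct knot locations."""
        return sorted({t.knot for t in self.terms})

    def to_json(self) -> str:
        return json.dumps({
            "intercept": self.intercept,
            "terms": [{"knot": t.knot, "direction": t.direction,
                       "coefficient": t.coefficient} for t in self.terms],
            "gcv": self.gcv,
            "effective_params": self.effective_params,
        })

    @classmethod
    def from_json(cls, payload: str) -> "MarsModel":
        d = json.loads(payload)
        terms = tuple(BasisTerm(t["knot"], t["direction"], t["coefficient"])
                      for t in d["terms"])
        return cls(intercept=d["intercept"], terms=terms, gcv=d["gcv"],
                   fitted=np.empty(0), residuals=np.empty(0),
                   effective_params=d["effective_params"],
                   n_terms=1 + len(terms))


def predict(model: MarsModel, x_new: np.ndarray) -> np.ndarray:
    """Evaluate the fitted piecewise-linear model at new abscissae."""
    x_new = np.asarray(x_new, dtype=float)
    out = np.full_like(x_new, model.intercept, dtype=float)
    for term in model.terms:
        out += term.coefficient * term.evaluate(x_new)
    return out


def _design(x: np.ndarray, terms: tuple[BasisTerm, ...]) -> np.ndarray:
    cols = [np.ones_like(x)]
    cols.extend(t.evaluate(x) for t in terms)
    return np.column_stack(cols)


def _fit_coefs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ coef) ** 2))
    return coef, sse


def _effective_params(X: np.ndarray, n_knots: int, c: float) -> float:
    r = int(np.linalg.matrix_rank(X))
    return r + c * n_knots


def _gcv(sse: float, m_eff: float, n: int) -> float:
    if m_eff >= n:
        return np.inf
    return sse / (1.0 - m_eff / n) ** 2


def _build(x: np.ndarray, y: np.ndarray, terms: tuple[BasisTerm, ...],
           config: MarsConfig) -> MarsModel:
    """Least-squares refit of a fixed term set, with GCV bookkeeping."""
    X = _design(x, terms)
    coef, sse = _fit_coefs(X, y)
    fitted = X @ coef
    n_knots = len({t.knot for t in terms})
    m_eff = _effective_params(X, n_knots, config.gcv_penalty_c)
    new_terms = tuple(replace(t, coefficient=float(c))
                      for t, c in zip(terms, coef[1:]))
    return MarsModel(intercept=float(coef[0]), terms=new_terms,
                     gcv=_gcv(sse, m_eff, x.size),
                     fitted=fitted, residuals=y - fitted,
                     effective_params=m_eff, n_terms=1 + len(terms))


def forward_pass(x: np.ndarray, y: np.ndarray,
                 config: MarsConfig | None = None) -> MarsModel:
    """Greedy forward construction of the hinge basis (unpruned model).

    At each iteration every interior training abscissa is a candidate knot;
    the reflected pair giving the largest drop in residual sum of squares
    is appended and all coefficients are re-estimated.  Iteration stops
    when the R^2 gain falls below ``config.stop_threshold`` or the model
    reaches ``config.max_terms`` basis functions.
    """
    config = config or MarsConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing (duplicates are degenerate)")

    n = x.size
    sst = float(np.sum((y - y.mean()) ** 2))
    terms: tuple[BasisTerm, ...] = ()
    if sst == 0.0:  # constant response: intercept only
        return _build(x, y, terms, config)

    # candidate knots: interior abscissae (boundary knots duplicate the
    # global line and make the design singular)
    cand = x[1:-1]
    upos = np.maximum(0.0, x[:, None] - cand[None, :])  # N x C
    uneg = np.maximum(0.0, cand[None, :] - x[:, None])

    used = np.zeros(cand.size, dtype=bool)
    X = np.ones((n, 1))
    coef, sse = _fit_coefs(X, y)

    while X.shape[1] + 2 <= config.max_terms and not used.all():
        q, _ = np.linalg.qr(X)
        resid = y - q @ (q.T @ y)
        u = upos - q @ (q.T @ upos)
        v = uneg - q @ (q.T @ uneg)
        uu = np.einsum("ij,ij->j", u, u)
        vv = np.einsum("ij,ij->j", v, v)
        uv = np.einsum("ij,ij->j", u, v)
        ur = u.T @ resid
        vr = v.T @ resid
        det = uu * vv - uv * uv
        scale = np.maximum(uu * vv, 1e-300)
        ok = det > 1e-10 * scale
        red_pair = np.where(
            ok,
            (vv * ur**2 - 2 * uv * ur * vr + uu * vr**2) / np.where(ok, det, 1.0),
            0.0,
        )
        # rank-deficient pair: fall back to the better single column
        with np.errstate(divide="ignore", invalid="ignore"):
            red_single = np.maximum(
                np.where(uu > 0, ur**2 / uu, 0.0),
                np.where(vv > 0, vr**2 / vv, 0.0),
            )
        reduction = np.where(ok, red_pair, red_single)
        reduction[used] = -np.inf

        best = int(np.argmax(reduction))
        # deterministic tie-break: smallest knot value
        tied = np.flatnonzero(reduction >= reduction[best] - 1e-12 * max(sse, 1.0))
        if tied.size > 1:
            best = int(tied[np.argmin(cand[tied])])
        if reduction[best] / sst < config.stop_threshold:
            break

        used[best] = True
        t = float(cand[best])
        terms = terms + (BasisTerm(t, "+"), BasisTerm(t, "-"))
        X = np.column_stack([X, upos[:, best], uneg[:, best]])
        coef, new_sse = _fit_coefs(X, y)
        sse = new_sse
        if sse <= 1e-12 * sst:
            break

    return _build(x, y, terms, config)


def backward_prune(model: MarsModel, x: np.ndarray, y: np.ndarray,
                   config: MarsConfig | None = None) -> MarsModel:
    """Backward deletion: return the GCV-minimizing model.

    Starting from the forward model, the term whose removal least
    increases the residual sum of squares is deleted repeatedly down to the
    intercept-only model; the model with the smallest GCV along this
    sequence is returned (ties resolved in favour of fewer terms).
    """
    config = config or MarsConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    best = _build(x, y, model.terms, config)
    current = tuple(model.terms)
    while current:
        # delete the term whose removal gives the smallest SSE increase
        best_sse, best_idx = np.inf, 0
        for i in range(len(current)):
            reduced = current[:i] + current[i + 1:]
            _, sse = _fit_coefs(_design(x, reduced), y)
            if sse < best_sse:
                best_sse, best_idx = sse, i
        current = current[:best_idx] + current[best_idx + 1:]
        candidate = _build(x, y, current, config)
        if candidate.gcv <= best.gcv * (1.0 + 1e-12):
            best = candidate

    # numeric hygiene: drop lone near-zero coefficients
    scale = float(np.std(y)) or 1.0
    kept = tuple(t for t in best.terms if abs(t.coefficient) > 1e-12 * scale)
    if len(kept) != len(best.terms):
        best = _build(x, y, kept, config)
    return best


def fit_mars(x: np.ndarray, y: np.ndarray,
             config: MarsConfig | None = None) -> MarsModel:
    """Forward construction followed by GCV pruning."""
    config = config or MarsConfig()
    return backward_prune(forward_pass(x, y, config), x, y, config)
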