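"""Phase-randomized surrogates and trend/residual resampling experiments.

Phase randomization keeps a series' amplitude spectrum (hence its full
autocorrelation function) while destroying any structure carried by the
Fourier phases.  Two variants are provided:

* independent surrogates (IS): each series gets its own random phases;
* cross-correlated surrogates (CCS): one shared random phase field is
  *added* to the spectra of two series, which preserves each amplitude
  spectrum and their cross-spectrum, hence the ST-SL coupling.

Marginal distributions are not preserved (no amplitude-adjustment
iteration); surrogate values are Gaussianized versions of the original.

The composite-ensemble experiment addresses a different question: signals
built as (fitted trend) + (randomly shuffled residuals) have residuals
devoid of serial correlation by construction, so any apparent persistence
of the composites is attributable to the trend alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .scaling import estimate_alpha

__all__ = [
    "SurrogateSpec",
    "CompositeEnsemble",
    "phase_randomize",
    "cross_correlated_surrogates",
    "composite_ensemble",
    "surrogate_comparison",
]


@dataclass(frozen=True)
class SurrogateSpec:
    kind: str = "IS"  # "IS" or "CCS"
    seed: int = 0
    n_realizations: int = 50

    def __post_init__(self) -> None:
        if self.kind not in ("IS", "CCS"):
            raise ValueError("kind must be 'IS' or 'CCS'")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


def _random_phases(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform phases for the positive-frequency bins that may rotate.

    DC never rotates (keeps the mean); for even n the Nyquist bin is real
    and is kept fixed too, so the output stays real-valued.
    """
    n_rfft = n // 2 + 1
    free = n_rfft - 2 if n % 2 == 0 else n_rfft - 1
    phases = np.zeros(n_rfft)
    mask = np.zeros(n_rfft, dtype=bool)
    mask[1:1 + free] = True
    phases[mask] = rng.uniform(0.0, 2.0 * np.pi, size=free)
    return phases, mask


def phase_randomize(y: Sequence[float], seed: int = 0) -> np.ndarray:
    """Independent phase-randomized surrogate of one series.

    The amplitude spectrum and the mean are preserved exactly; positive
    (non-DC, non-Nyquist) frequencies receive iid uniform phases.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 8:
        raise ValueError("need at least 8 samples")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(y)
    phases, mask = _random_phases(y.size, rng)
    new_phase = np.where(mask, phases, np.angle(spec))
    return np.fft.irfft(np.abs(spec) * np.exp(1j * new_phase), n=y.size)


def cross_correlated_surrogates(y1: Sequence[float], y2: Sequence[float],
                                seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Surrogate pair sharing one random phase field.

    The same random phase increment is added to both spectra, so each
    output keeps its own amplitude spectrum while the cross-spectrum (and
    with it the ST-SL cross-correlation function) is preserved.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape:
        raise ValueError("series must have equal lengths")
    if y1.size < 8:
        raise ValueError("need at least 8 samples")
    rng = np.random.default_rng(seed)
    phases, _ = _random_phases(y1.size, rng)
    rot = np.exp(1j * phases)
    s1 = np.fft.irfft(np.fft.rfft(y1) * rot, n=y1.size)
    s2 = np.fft.irfft(np.fft.rfft(y2) * rot, n=y2.size)
    return s1, s2


@dataclass(frozen=True)
class CompositeEnsemble:
    """Trend + shuffled-residual composites and their scaling exponents."""

    trend: np.ndarray
    residual_pool: np.ndarray
    realizations: np.ndarray  # n_realizations x N
    exponents: dict[str, np.ndarray]  # method -> per-realization alpha

    def median_alpha(self, method: str) -> float:
        return float(np.median(self.exponents[method]))


def composite_ensemble(trend: Sequence[float], residuals: Sequence[float],
                       n_realizations: int = 100, seed: int = 0,
                       methods: Sequence[str] = ("DFA1", "DFA2", "DFA3", "MD"),
                       ) -> CompositeEnsemble:
    """Build trend + permuted-residual composites and estimate their scaling.

    Each realization is ``trend + permutation(residuals)`` with independent
    permutations, so the noise is serially uncorrelated by construction
    while its marginal multiset is conserved.
    """
    trend = np.asarray(trend, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    if trend.shape != residuals.shape:
        raise ValueError("trend and residuals must have equal lengths")
    rng = np.random.default_rng(seed)
    real = np.empty((n_realizations, trend.size))
    for j in range(n_realizations):
        real[j] = trend + rng.permutation(residuals)
    exponents = {
        m: np.array([estimate_alpha(row, m).alpha for row in real])
        for m in methods
    }
    return CompositeEnsemble(trend=trend, residual_pool=residuals,
                             realizations=real, exponents=exponents)


def surrogate_comparison(series_set: Sequence[np.ndarray],
                         spec: SurrogateSpec,
                         statistic: Callable[[np.ndarray], np.ndarray | float],
                         paired_set: Sequence[np.ndarray] | None = None,
                         test: str = "ks") -> dict:
    """Compare a statistic between original series and surrogate realizations.

    For each of ``spec.n_realizations`` surrogate draws, the statistic is
    evaluated on every series (IS) or every pair (CCS, requires
    ``paired_set``); the distribution over series is compared with the
    original one by a two-sample test ("ks" or "ad").  Returns the
    per-realization p-values and the rejection fraction at 0.05.
    """
    originals = [np.asarray(s, float) for s in series_set]
    if spec.kind == "CCS" and paired_set is None:
        raise ValueError("CCS comparison needs paired_set")

    def eval_stat(arrs: list[np.ndarray]) -> np.ndarray:
        return np.concatenate([np.atleast_1d(np.asarray(statistic(a), float))
                               for a in arrs])

    base = eval_stat(originals)
    pvals = []
    for r in range(spec.n_realizations):
        surro = []
        for i, s in enumerate(originals):
            sub_seed = spec.seed + 1_000_003 * r + i
            if spec.kind == "IS":
                surro.append(phase_randomize(s, seed=sub_seed))
            else:
                s1, _ = cross_correlated_surrogates(
                    s, np.asarray(paired_set[i], float), seed=sub_seed)
                surro.append(s1)
        other = eval_stat(surro)
        if test == "ks":
            p = float(stats.ks_2samp(base, other).pvalue)
        elif test == "ad":
            p = float(np.clip(stats.anderson_ksamp([base, other])
                              .significance_level, 0.0, 1.0))
        else:
            raise ValueError("test must be 'ks' or 'ad'")
        pvals.append(p)
    pvals = np.array(pvals)
    return {"pvalues": pvals,
            "rejection_fraction": float(np.mean(pvals < 0.05))}
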