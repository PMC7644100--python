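"""Fractional Brownian motion / fractional Gaussian noise simulation.

Fractional Gaussian noise (fGn) is the stationary increment process of
fractional Brownian motion (FBM).  Its autocovariance is

    gamma(k) = 1/2 (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}),

with Hurst exponent ``H``.  Paths are synthesised by the exact
circulant-embedding (Davies-Harte) method: the covariance sequence is
embedded in a circulant matrix whose eigenvalues are obtained by FFT, and
Gaussian variates are coloured in the spectral domain.  Embedding is exact
whenever every eigenvalue is non-negative, which holds for all H in (0, 1]
at the lengths used here; should the embedding fail, the O(n^2) Hosking
recursion is used instead, which is exact for any valid covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FbmSpec", "generate_fbm", "generate_fgn", "fgn_from_fbm"]


@dataclass(frozen=True)
class FbmSpec:
    """Specification of an FBM ensemble.

    Parameters
    ----------
    hurst : float
        Hurst exponent, in (0, 1].  H = 0.5 is ordinary Brownian motion.
    length : int
        Number of samples per path (>= 2).
    n_paths : int
        Number of independent paths.
    seed : int
        Seed for the pseudo-random generator.
    """

    hurst: float
    length: int
    n_paths: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.hurst <= 1.0):
            raise ValueError(f"hurst must be in (0, 1], got {self.hurst}")
        if self.length < 2:
            raise ValueError(f"length must be >= 2, got {self.length}")
        if self.n_paths < 1:
            raise ValueError(f"n_paths must be >= 1, got {self.n_paths}")


def _fgn_autocovariance(n: int, hurst: float) -> np.ndarray:
    """Autocovariance gamma(0..n) of unit-variance fGn."""
    k = np.arange(n + 1, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1.0) ** h2 - 2.0 * k ** h2 + np.abs(k - 1.0) ** h2)


def _fgn_davies_harte(n: int, hurst: float, n_paths: int,
                      rng: np.random.Generator) -> np.ndarray | None:
    """Exact circulant-embedding synthesis; None if embedding fails."""
    g = _fgn_autocovariance(n, hurst)
    circ = np.concatenate([g, g[-2:0:-1]])  # length 2n
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-8 * lam.max():
        return None
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    w = np.zeros((n_paths, m), dtype=complex)
    w[:, 0] = np.sqrt(lam[0] / m) * rng.standard_normal(n_paths)
    a = rng.standard_normal((n_paths, m // 2 - 1))
    b = rng.standard_normal((n_paths, m // 2 - 1))
    w[:, 1:m // 2] = np.sqrt(lam[1:m // 2] / (2 * m)) * (a + 1j * b)
    w[:, m // 2] = np.sqrt(lam[m // 2] / m) * rng.standard_normal(n_paths)
    w[:, m // 2 + 1:] = np.conj(w[:, 1:m // 2][:, ::-1])
    return np.fft.fft(w, axis=1).real[:, :n]


def _fgn_hosking(n: int, hurst: float, n_paths: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Hosking's recursion: exact sequential conditional sampling."""
    g = _fgn_autocovariance(n, hurst)
    out = np.empty((n_paths, n))
    phi = np.zeros((n_paths, n))
    z = rng.standard_normal((n_paths, n))
    out[:, 0] = z[:, 0]
    v = 1.0
    phi_prev = np.zeros(n)
    for i in range(1, n):
        # Durbin-Levinson update of the AR coefficients of fGn
        kappa = (g[i] - np.dot(phi_prev[: i - 1], g[i - 1:0:-1])) / v
        phi_i = np.empty(i)
        phi_i[: i - 1] = phi_prev[: i - 1] - kappa * phi_prev[: i - 1][::-1]
        phi_i[i - 1] = kappa
        v *= 1.0 - kappa * kappa
        mean = out[:, :i] @ phi_i[::-1]
        out[:, i] = mean + np.sqrt(v) * z[:, i]
        phi_prev[:i] = phi_i
    del phi
    return out


def generate_fgn(spec: FbmSpec) -> np.ndarray:
    """Generate stationary fractional Gaussian noise.

    Returns an ``(n_paths, length)`` array of unit-variance fGn with the
    Hurst exponent of *spec*.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    fgn = _fgn_davies_harte(spec.length, spec.hurst, spec.n_paths, rng)
    if fgn is None:
        fgn = _fgn_hosking(spec.length, spec.hurst, spec.n_paths, rng)
    return fgn


def generate_fbm(spec: FbmSpec) -> np.ndarray:
    """Generate fractional Brownian motion paths.

    Returns an ``(n_paths, length)`` array.  Each path starts at 0 and its
    remaining ``length - 1`` samples are the cumulative sum of an exact fGn
    sample, so :func:`fgn_from_fbm` recovers stationary increments with the
    requested Hurst exponent.
    """
    rng = np.random.default_rng(spec.seed)
    fgn = _fgn_davies_harte(spec.length - 1, spec.hurst, spec.n_paths, rng)
    if fgn is None:
        fgn = _fgn_hosking(spec.length - 1, spec.hurst, spec.n_paths, rng)
    paths = np.empty((spec.n_paths, spec.length))
    paths[:, 0] = 0.0
    np.cumsum(fgn, axis=1, out=paths[:, 1:])
    return paths


def fgn_from_fbm(path: np.ndarray) -> np.ndarray:
    """First differences of an FBM path (its fGn increments).

    ``np.cumsum(fgn_from_fbm(p)) + p[0]`` reproduces ``p[1:]`` exactly.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 1 or path.size < 2:
        raise ValueError("path must be a 1-d array of length >= 2")
    return np.diff(path)
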