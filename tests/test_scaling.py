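"""DFA and madogram estimators: exact laws, oracle equivalence, bias decay."""

import numpy as np
import pytest

from stridetrends import (ConstantSeriesError, FbmSpec, dfa, estimate_alpha,
                          generate_fbm, generate_fgn, madogram_alpha,
                          window_sweep)


# --- independent reference implementations (no vectorization tricks) -------

def naive_dfa(y, order, sizes):
    y = np.asarray(y, float)
    profile = np.cumsum(y - np.mean(y))
    logf = []
    for s in sizes:
        nb = len(profile) // s
        total, count = 0.0, 0
        for b in range(nb):
            seg = profile[b * s:(b + 1) * s]
            t = np.arange(s, dtype=float)
            coef = np.polyfit(t, seg, order)
            total += float(np.sum((seg - np.polyval(coef, t)) ** 2))
            count += s
        logf.append(np.log(np.sqrt(total / count)))
    return float(np.polyfit(np.log(sizes), logf, 1)[0])


def naive_madogram(path):
    path = np.asarray(path, float)
    n = len(path)
    v1 = sum(abs(path[i + 1] - path[i]) for i in range(n - 1)) / (2 * (n - 1))
    v2 = sum(abs(path[i + 2] - path[i]) for i in range(n - 2)) / (2 * (n - 2))
    d = 2 - (np.log(v2) - np.log(v1)) / np.log(2)
    return 2 - d


# --- oracle equivalence ----------------------------------------------------

@pytest.mark.parametrize("seed", range(10))
def test_dfa_matches_naive_reference(seed):
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(400)
    res = dfa(y, order=1)
    assert res.alpha == pytest.approx(
        naive_dfa(y, 1, list(res.window_sizes)), abs=1e-10)


@pytest.mark.parametrize("seed", range(10))
def test_madogram_matches_naive_reference(seed):
    rng = np.random.default_rng(100 + seed)
    path = np.cumsum(rng.standard_normal(300))
    assert madogram_alpha(path).alpha == pytest.approx(
        naive_madogram(path), abs=1e-10)


@pytest.mark.parametrize("order", [2, 3])
def test_higher_order_dfa_matches_naive_reference(order):
    rng = np.random.default_rng(42)
    y = rng.standard_normal(600)
    res = dfa(y, order=order)
    assert res.alpha == pytest.approx(
        naive_dfa(y, order, list(res.window_sizes)), abs=1e-10)


# --- exact laws and degenerate inputs --------------------------------------

def test_affine_path_has_dimension_one():
    """A straight line has fractal dimension 1, so alpha = 1 exactly."""
    res = madogram_alpha(3.0 * np.arange(100.0))
    assert res.v2 / res.v1 == pytest.approx(2.0, rel=1e-12)
    assert res.fractal_dim == pytest.approx(1.0, abs=1e-12)
    assert res.alpha == pytest.approx(1.0, abs=1e-12)
    res2 = madogram_alpha(5.0 - 0.25 * np.arange(50.0))
    assert res2.alpha == pytest.approx(1.0, abs=1e-12)


def test_constant_input_raises():
    const = np.full(200, 3.14)
    with pytest.raises(ConstantSeriesError):
        dfa(const, order=1)
    with pytest.raises(ConstantSeriesError):
        madogram_alpha(const)
    with pytest.raises(ConstantSeriesError):
        estimate_alpha(const, "MD")


def test_too_short_input_rejected():
    with pytest.raises(ValueError):
        dfa(np.random.default_rng(0).standard_normal(12), order=1)
    with pytest.raises(ValueError):
        madogram_alpha(np.array([1.0, 2.0]))


# --- recovery of known exponents -------------------------------------------

def test_white_noise_alpha_half_all_methods(rng):
    y = rng.standard_normal(10000)
    for method in ("DFA1", "DFA2", "DFA3", "MD"):
        assert estimate_alpha(y, method).alpha == pytest.approx(0.5, abs=0.07)


def test_dfa_recovers_persistent_fgn():
    fgn = generate_fgn(FbmSpec(hurst=0.75, length=2**13, n_paths=1, seed=6))[0]
    assert dfa(fgn, order=1).alpha == pytest.approx(0.75, abs=0.05)


def test_dfa_on_fbm_increments_consistent_with_generator():
    path = generate_fbm(FbmSpec(hurst=0.75, length=2**13, n_paths=1, seed=8))[0]
    assert dfa(np.diff(path), order=1).alpha == pytest.approx(0.75, abs=0.05)


def test_madogram_recovers_brownian_path():
    path = generate_fbm(FbmSpec(hurst=0.5, length=4096, n_paths=1, seed=9))[0]
    assert madogram_alpha(path).alpha == pytest.approx(0.5, abs=0.05)


def test_short_series_madogram_near_residual_hurst():
    alphas = [estimate_alpha(
        generate_fgn(FbmSpec(hurst=0.48, length=260, n_paths=1, seed=s))[0],
        "MD").alpha for s in range(60)]
    assert np.mean(alphas) == pytest.approx(0.48, abs=0.07)


@pytest.mark.parametrize("h", [0.3, 0.5, 0.7, 0.9])
def test_madogram_ensemble_recovery(h):
    paths = generate_fbm(FbmSpec(hurst=h, length=1024, n_paths=200,
                                 seed=int(h * 100)))
    med = np.median([madogram_alpha(p).alpha for p in paths])
    assert med == pytest.approx(h, abs=0.05)


def test_trend_inflates_scaling_exponent(default_trial):
    raw = estimate_alpha(default_trial.st.values, "DFA1").alpha
    resid = estimate_alpha(default_trial.st_residuals, "DFA1").alpha
    assert raw > resid


# --- window sweep -----------------------------------------------------------

def test_window_sweep_structure_and_counts():
    paths = generate_fbm(FbmSpec(hurst=0.75, length=260, n_paths=20, seed=4))
    sweep = window_sweep(paths, [40, 100, 260], methods=("DFA1", "MD"),
                         input_kind="path")
    assert sweep.k_values == (40, 100, 260)
    # floor(260/40)=6 windows per path, remainder discarded
    assert len(sweep.alphas["MD"][40]) == 20 * 6
    assert len(sweep.alphas["MD"][100]) == 20 * 2
    assert len(sweep.alphas["DFA1"][260]) == 20


def test_window_sweep_bias_shrinks_with_window_length():
    """|median - H| decreases from k=40 to k=260 for DFA1 and MD."""
    for h, seed in ((0.40, 31), (0.75, 32)):
        paths = generate_fbm(FbmSpec(hurst=h, length=260, n_paths=150,
                                     seed=seed))
        sweep = window_sweep(paths, [40, 260], methods=("DFA1", "MD"),
                             input_kind="path")
        for method in ("DFA1", "MD"):
            err40 = abs(sweep.median(method, 40) - h)
            err260 = abs(sweep.median(method, 260) - h)
            assert err260 <= err40 + 0.01


def test_window_sweep_rejects_oversized_windows():
    paths = generate_fbm(FbmSpec(hurst=0.5, length=100, n_paths=2, seed=0))
    with pytest.raises(ValueError):
        window_sweep(paths, [200], input_kind="path")
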