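"""Trend segmentation and the duration/slope statistics."""

import numpy as np
import pytest
from scipy import stats

from stridetrends import (GaitTrialSpec, MarsConfig, TrendSegment,
                          extract_segments, fit_cauchy, fit_exponential,
                          fit_mars, generate_gait_trial, normalized_duration,
                          normalized_slope, small_slope_sections)
from stridetrends.mars import BasisTerm, MarsModel


def _model_with_knots(knot_coefs, intercept=1.0):
    terms = tuple(BasisTerm(k, d, c)
                  for k, d, c in knot_coefs)
    return MarsModel(intercept=intercept, terms=terms, gcv=0.0,
                     fitted=np.empty(0), residuals=np.empty(0),
                     effective_params=1 + 3 * len({k for k, _, _ in knot_coefs}),
                     n_terms=1 + len(terms))


def test_intercept_only_model_has_no_segments():
    model = _model_with_knots([])
    assert extract_segments(model, np.ones(250)) == []


def test_single_knot_splits_into_two_tiling_segments():
    model = _model_with_knots([(100.0, "+", 0.001), (100.0, "-", 0.002)])
    segs = extract_segments(model, np.ones(250))
    assert len(segs) == 2
    assert (segs[0].start_idx, segs[0].end_idx) == (1, 100)
    assert (segs[1].start_idx, segs[1].end_idx) == (100, 250)
    # every stride counted exactly once, knot stride assigned left
    assert segs[0].n_strides + segs[1].n_strides == 250


def test_constant_series_duration_equals_stride_count():
    seg = TrendSegment(start_idx=1, end_idx=23, delta_y=0.0,
                       norm_duration=np.nan, norm_slope=np.nan, first=True)
    values = np.full(250, 1.1)
    assert normalized_duration(seg, values) == pytest.approx(23.0)


def test_normalized_slope_formula_and_sign():
    values = np.full(100, 1.0)
    seg = TrendSegment(start_idx=1, end_idx=10, delta_y=0.01,
                       norm_duration=10.0, norm_slope=np.nan, first=True)
    assert normalized_slope(seg, values) == pytest.approx(0.001)
    seg_flat = TrendSegment(start_idx=1, end_idx=10, delta_y=0.0,
                            norm_duration=10.0, norm_slope=np.nan, first=True)
    assert normalized_slope(seg_flat, values) == 0.0


def test_segments_partition_every_trial(quiet_trial):
    model = fit_mars(quiet_trial.st.stride_index, quiet_trial.st.values)
    segs = extract_segments(model, quiet_trial.st.values)
    if segs:
        covered = sum(s.n_strides for s in segs)
        # adjacent-knot pieces shorter than 2 strides may be dropped
        assert covered >= len(quiet_trial.st) - 2 * len(segs)
        assert segs[0].first and segs[0].start_idx == 1
        assert segs[-1].end_idx == len(quiet_trial.st)
        for a, b in zip(segs, segs[1:]):
            assert b.start_idx == a.end_idx


def test_known_knots_recovered_on_quiet_trials():
    """With low noise the segment count is close to the ground truth."""
    errs = []
    for seed in range(8):
        trial = generate_gait_trial(GaitTrialSpec(residual_cv=0.003,
                                                  seed=300 + seed))
        model = fit_mars(trial.st.stride_index, trial.st.values)
        segs = extract_segments(model, trial.st.values)
        errs.append(len(segs) - (len(trial.true_knots_st) + 1))
    assert abs(np.mean(errs)) <= 2.0


def test_exponential_fit_is_reciprocal_mean():
    fit = fit_exponential(np.full(50, 1 / 0.043))
    assert fit.rate == pytest.approx(0.043, rel=1e-12)
    with pytest.raises(ValueError):
        fit_exponential([1.0] * 5)
    with pytest.raises(ValueError):
        fit_exponential([1.0] * 9 + [-1.0])


def test_exponential_rate_recovery_from_sample(rng):
    sample = rng.exponential(1 / 0.043, size=1500)
    fit = fit_exponential(sample)
    assert fit.rate == pytest.approx(0.043, abs=0.005)
    assert fit.gof_p > 0.01  # sample really is exponential


def test_cauchy_fit_recovery_and_errors(rng):
    sample = stats.cauchy.rvs(loc=8e-4, scale=1.2e-3, size=1600,
                              random_state=rng)
    fit = fit_cauchy(sample)
    assert fit.location == pytest.approx(8e-4, abs=3e-4)
    assert fit.scale == pytest.approx(1.2e-3, abs=2e-4)
    grid = np.concatenate([-np.linspace(0.1, 1, 10), [0.0],
                           np.linspace(0.1, 1, 10)])
    assert fit_cauchy(grid).location == pytest.approx(0.0, abs=1e-4)
    with pytest.raises(ValueError):
        fit_cauchy(np.ones(20))


def test_duration_rate_recovered_from_generated_trials():
    """Aggregated pipeline durations refit the generator's exponential rate."""
    durations = []
    for seed in range(25):
        trial = generate_gait_trial(GaitTrialSpec(seed=700 + seed))
        for series in (trial.st, trial.sl):
            model = fit_mars(series.stride_index, series.values)
            durations += [s.norm_duration
                          for s in extract_segments(model, series.values)]
    fit = fit_exponential(durations)
    assert fit.rate == pytest.approx(0.043, abs=0.010)


def test_small_slope_selection_thresholds():
    values = np.full(250, 1.0)
    steep = TrendSegment(1, 60, delta_y=0.3, norm_duration=60.0,
                         norm_slope=5e-3, first=True)
    flat_short = TrendSegment(60, 80, delta_y=0.0, norm_duration=20.0,
                              norm_slope=0.0)
    flat_long = TrendSegment(80, 180, delta_y=0.001, norm_duration=100.0,
                             norm_slope=1e-5)
    rng = np.random.default_rng(0)
    noisy = values + rng.normal(0, 0.01, 250)
    out = small_slope_sections([steep, flat_short, flat_long], noisy)
    assert len(out) == 1
    frag, alpha = out[0]
    assert frag.size == 100
    assert np.isfinite(alpha)
    assert small_slope_sections([steep], noisy) == []
    with pytest.raises(ValueError):
        small_slope_sections([flat_long], noisy, min_norm_len=0.0)


def test_planted_flat_segment_alpha_matches_residual_hurst():
    """A planted zero-slope segment's fragment carries the residual exponent."""
    from stridetrends import FbmSpec, generate_fgn

    n, mean_st, cv = 250, 1.1, 0.006
    x = np.arange(1.0, n + 1)
    # trend: 95 strides up at 2e-3, 60 strides flat, 95 strides down
    slopes = np.repeat([2e-3, 0.0, -2e-3], [95, 60, 95]) * mean_st
    trend = mean_st + np.concatenate([[0.0], np.cumsum(slopes[:-1])])
    alphas = []
    for seed in range(60):
        resid = generate_fgn(FbmSpec(hurst=0.48, length=n, n_paths=1,
                                     seed=4000 + seed))[0]
        y = trend + resid * cv * mean_st / resid.std()
        model = fit_mars(x, y)
        segs = extract_segments(model, y)
        for frag, alpha in small_slope_sections(segs, y):
            if frag.size >= 40:
                alphas.append(alpha)
    assert len(alphas) >= 20
    assert np.median(alphas) == pytest.approx(0.48, abs=0.08)
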