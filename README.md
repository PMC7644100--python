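# stridetrends

Trend-aware fractal analysis of spatio-temporal gait time series.

During treadmill walking, stride time (ST) and stride length (SL) drift in
slow, piecewise-linear **trends** while fluctuating around them with
small-amplitude noise. Classical detrended fluctuation analysis (DFA)
reports ST and SL as strongly persistent (scaling exponent α > 0.5), but
that persistence can be an artifact of the trends themselves: DFA's
polynomial detrending cannot remove piecewise-linear structure.
`stridetrends` separates the two contributions explicitly and provides the
tooling to show which one carries the apparent long-range correlation.

The package is for movement scientists and physiologists analysing
per-stride series (and for anyone estimating Hurst exponents of short,
trended physiological signals).

## What it computes

- **Piecewise-linear trend extraction** — one-dimensional additive
  regression splines over reflected hinge pairs max(0, x−t), max(0, t−x),
  built greedily and pruned by generalized cross-validation
  GCV(λ) = SSE(λ)/[1 − M(λ)/N]², M(λ) = r + cK (knot penalty c = 2).
- **Scaling exponents** — DFA of order 1–3 (α is the log-log slope of the
  fluctuation function F(n) of the integrated series) and the **madogram**
  estimator: from the order-1 power variations V(1), V(2) of the path,
  D̂ = 2 − log₂[V(2)/V(1)] and α = 2 − D̂. The madogram is nearly unbiased
  even on 40-sample windows, where DFA1 overshoots badly.
- **Trend-segment statistics** — normalized durations (exponential fit,
  rate λ) and normalized slopes (Cauchy fit, scale γ) of the trend pieces.
- **Speed control** — trend speed v⁽ᵗʳᵉⁿᵈ⁾ᵢ = SL-trendᵢ/ST-trendᵢ and the
  trend speed control parameter TSC = Σᵢ(vᵢ − ⟨SS⟩)²/(N⟨SS⟩²), zero iff
  the trend speed sits exactly on the mean stride speed.
- **Surrogates** — independent and cross-correlated phase-randomized
  surrogates, and trend + shuffled-residual composite ensembles.
- **Simulation** — exact fractional Gaussian noise / fractional Brownian
  motion (circulant embedding) and fully parameterized synthetic gait
  trials with ground-truth trends, for estimator calibration and testing.

## Worked example

```python
import numpy as np
from stridetrends import (GaitTrialSpec, generate_gait_trial, fit_mars,
                          estimate_alpha)

trial = generate_gait_trial(GaitTrialSpec(seed=2))          # 250 strides
model = fit_mars(trial.st.stride_index, trial.st.values)     # ST trend
print(len(model.knots))                                      # -> 10
print(round(estimate_alpha(trial.st.values, "MD").alpha, 2))    # -> 0.98
print(round(estimate_alpha(model.residuals, "MD").alpha, 2))    # -> 0.51
```

The raw stride-time series looks strongly persistent (α ≈ 0.98), but after
removing the fitted piecewise-linear trend the residual exponent drops to
≈ 0.5: the persistence lived in the trend, not in the noise. The
`examples/` directory holds one short script per capability (simulation,
trend extraction, scaling estimators, the FBM window study, surrogates,
full pipeline), each printing the numbers it computes with a line on what
they mean.

A thin CLI mirrors the batch workflows:

```sh
stridetrends simulate --n-trials 5 --seed 1 --out trials/
stridetrends analyze trials/trial_1.csv
stridetrends surrogate trials/trial_1.csv --kind CCS --n 10
stridetrends fbm-study --n-paths 200
```

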