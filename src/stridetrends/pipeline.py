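"""Per-trial and cross-trial gait analysis.

For one trial the pipeline fits a piecewise-linear trend to stride time
and stride length, splits each series into trend + residual, estimates
scaling exponents of the raw and detrended series with all four
estimators, extracts trend segments, and computes the speed-control
quantities:

* trend speed v_i = (SL trend)_i / (ST trend)_i — the speed the trends
  alone would produce at stride i;
* the trend speed control parameter
  TSC = sum_i (v_i - <SS>)^2 / (N <SS>^2), which is zero exactly when the
  trend speed equals the trial-mean stride speed at every stride (an RMS
  variant, its square root, is available via ``sqrt=True``);
* coefficients of variation of trend speed, SS, SL and ST;
* Pearson correlations between ST and SL for the raw series, the trends,
  and the residuals.

Cross-trial hypothesis testing delegates to standard implementations
(scipy/statsmodels): Shapiro-Wilk, Kruskal-Wallis and one-way ANOVA with
Tukey HSD post hocs, two-sample Kolmogorov-Smirnov and Anderson-Darling,
and left-sided one-sample tests against 0.5 for anti-persistence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mars import MarsConfig, MarsModel, fit_mars
from .scaling import METHODS, ScalingEstimate, estimate_alpha
from .series import StrideSeries
from .trends import TrendSegment, extract_segments

__all__ = [
    "TrialAnalysis",
    "trend_speed",
    "tsc",
    "coefficient_of_variation",
    "correlations",
    "analyze_trial",
    "group_statistics",
]


def trend_speed(st_trend: np.ndarray, sl_trend: np.ndarray) -> np.ndarray:
    """Per-stride ratio of the SL trend to the ST trend (m/s)."""
    st_trend = np.asarray(st_trend, dtype=float)
    sl_trend = np.asarray(sl_trend, dtype=float)
    if st_trend.shape != sl_trend.shape:
        raise ValueError("trend arrays must have equal lengths")
    if np.any(st_trend <= 0):
        raise ValueError("stride-time trend must be strictly positive")
    return sl_trend / st_trend


def tsc(v_trend: np.ndarray, ss: np.ndarray, sqrt: bool = False) -> float:
    """Trend speed control parameter.

    Normalized squared deviation of the trend speed from the trial-mean
    stride speed; zero iff the two coincide at every stride.  ``sqrt=True``
    returns the RMS variant.
    """
    v_trend = np.asarray(v_trend, dtype=float)
    ss = np.asarray(getattr(ss, "values", ss), dtype=float)
    if v_trend.shape != ss.shape:
        raise ValueError("v_trend and ss must have equal lengths")
    mean_ss = ss.mean()
    if mean_ss == 0:
        raise ValueError("mean stride speed is zero")
    value = float(np.sum((v_trend - mean_ss) ** 2) / (v_trend.size * mean_ss**2))
    return float(np.sqrt(value)) if sqrt else value


def coefficient_of_variation(series) -> float:
    """Sample standard deviation over mean, as a fraction."""
    values = np.asarray(getattr(series, "values", series), dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ValueError("zero mean; COV undefined")
    return float(values.std(ddof=1) / mean)


def correlations(st, sl, st_model: MarsModel,
                 sl_model: MarsModel) -> dict[str, float]:
    """Pearson correlation of ST vs SL: raw values, trends, residuals."""
    st_vals = np.asarray(getattr(st, "values", st), dtype=float)
    sl_vals = np.asarray(getattr(sl, "values", sl), dtype=float)
    if st_vals.shape != sl_vals.shape:
        raise ValueError("series must have equal lengths")

    def rho(a: np.ndarray, b: np.ndarray) -> float:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    return {
        "rho_raw": rho(st_vals, sl_vals),
        "rho_trend": rho(st_model.fitted, sl_model.fitted),
        "rho_noise": rho(st_model.residuals, sl_model.residuals),
    }


@dataclass
class TrialAnalysis:
    """Everything the pipeline computes for one trial."""

    st_model: MarsModel
    sl_model: MarsModel
    segments: Mapping[str, list[TrendSegment]]
    exponents: Mapping[tuple[str, str, str], ScalingEstimate]
    # keyed by (parameter, "raw"|"residual", method)
    trend_speed: np.ndarray = field(repr=False, default=None)
    tsc: float = float("nan")
    cov: Mapping[str, float] = field(default_factory=dict)
    correlations: Mapping[str, float] = field(default_factory=dict)

    def alpha(self, parameter: str, signal: str, method: str) -> float:
        return self.exponents[(parameter, signal, method)].alpha


def analyze_trial(st: StrideSeries, sl: StrideSeries,
                  ss: StrideSeries | None = None,
                  config: MarsConfig | None = None,
                  methods: Sequence[str] = METHODS,
                  tsc_sqrt: bool = False) -> TrialAnalysis:
    """Full per-trial analysis of an ST/SL(/SS) triplet.

    SS is computed as SL/ST when not supplied.  An intercept-only trend is
    legitimate ("no trends" trials): the residual is then the mean-centred
    raw series and the segment list is empty.
    """
    config = config or MarsConfig()
    if len(st) != len(sl):
        raise ValueError("ST and SL must have equal lengths")
    if ss is None:
        ss = StrideSeries(sl.values / st.values, "SS",
                          subject_id=st.subject_id, trial_id=st.trial_id,
                          pws_percent=st.pws_percent,
                          treadmill_speed=st.treadmill_speed)

    x = st.stride_index
    st_model = fit_mars(x, st.values, config)
    sl_model = fit_mars(x, sl.values, config)

    segments = {"ST": extract_segments(st_model, st.values),
                "SL": extract_segments(sl_model, sl.values)}

    exponents: dict[tuple[str, str, str], ScalingEstimate] = {}
    for name, series, model in (("ST", st, st_model), ("SL", sl, sl_model)):
        for method in methods:
            exponents[(name, "raw", method)] = estimate_alpha(
                series.values, method)
            exponents[(name, "residual", method)] = estimate_alpha(
                model.residuals, method)
    for method in methods:
        exponents[("SS", "raw", method)] = estimate_alpha(ss.values, method)

    v_trend = trend_speed(st_model.fitted, sl_model.fitted)
    return TrialAnalysis(
        st_model=st_model,
        sl_model=sl_model,
        segments=segments,
        exponents=exponents,
        trend_speed=v_trend,
        tsc=tsc(v_trend, ss.values, sqrt=tsc_sqrt),
        cov={
            "trend_speed": coefficient_of_variation(v_trend),
            "SS": coefficient_of_variation(ss.values),
            "SL": coefficient_of_variation(sl.values),
            "ST": coefficient_of_variation(st.values),
        },
        correlations=correlations(st.values, sl.values, st_model, sl_model),
    )


def _tukey_rows(groups: Mapping[str, np.ndarray]) -> list[dict]:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([np.asarray(v, float) for v in groups.values()])
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=0.05)
    rows = []
    for (g1, g2, _meandiff, p_adj, *_rest) in res.summary().data[1:]:
        rows.append({"test": "tukey_hsd", "groups": f"{g1} vs {g2}",
                     "statistic": float("nan"), "p": float(p_adj)})
    return rows


def group_statistics(groups: Mapping[str, Sequence[float]],
                     anti_persistence_null: float = 0.5,
                     parametric: bool | None = None) -> pd.DataFrame:
    """Standard cross-group hypothesis tests on per-trial statistics.

    ``groups`` maps a label (e.g. a treadmill-speed level) to per-trial
    values.  Emits a tidy table with Shapiro-Wilk normality per group, a
    Kruskal-Wallis or ANOVA omnibus test (chosen by normality unless
    ``parametric`` forces it) with Tukey post hocs, pairwise KS and
    Anderson-Darling tests, and left-sided one-sample tests of each group
    against ``anti_persistence_null`` (t-test when normal, Wilcoxon signed
    rank otherwise).  Groups with fewer than 3 values are skipped per test.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 1:
        raise ValueError("need at least one group")
    rows: list[dict] = []

    normal = True
    for label, vals in groups.items():
        if vals.size < 3:
            rows.append({"test": "shapiro_wilk", "groups": label,
                         "statistic": float("nan"), "p": float("nan")})
            continue
        sw = stats.shapiro(vals)
        normal &= sw.pvalue > 0.05
        rows.append({"test": "shapiro_wilk", "groups": label,
                     "statistic": float(sw.statistic), "p": float(sw.pvalue)})
    use_parametric = normal if parametric is None else parametric

    usable = {k: v for k, v in groups.items() if v.size >= 3}
    if len(usable) >= 2:
        arrays = list(usable.values())
        if use_parametric:
            om = stats.f_oneway(*arrays)
            name = "anova"
        else:
            om = stats.kruskal(*arrays)
            name = "kruskal_wallis"
        rows.append({"test": name, "groups": " vs ".join(usable),
                     "statistic": float(om.statistic), "p": float(om.pvalue)})
        rows.extend(_tukey_rows(usable))
        labels = list(usable)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = usable[labels[i]], usable[labels[j]]
                ks = stats.ks_2samp(a, b)
                rows.append({"test": "ks_2samp",
                             "groups": f"{labels[i]} vs {labels[j]}",
                             "statistic": float(ks.statistic),
                             "p": float(ks.pvalue)})
                with warnings.catch_warnings():
                    # AD p-values are clipped to [0.001, 0.25] by design
                    warnings.simplefilter("ignore", UserWarning)
                    ad = stats.anderson_ksamp([a, b])
                rows.append({"test": "anderson_darling",
                             "groups": f"{labels[i]} vs {labels[j]}",
                             "statistic": float(ad.statistic),
                             "p": float(np.clip(ad.significance_level, 0, 1))})

    for label, vals in groups.items():
        if vals.size < 3 or np.ptp(vals) == 0:
            continue
        if use_parametric:
            t = stats.ttest_1samp(vals, anti_persistence_null,
                                  alternative="less")
            rows.append({"test": "t_less_than_null", "groups": label,
                         "statistic": float(t.statistic),
                         "p": float(t.pvalue)})
        else:
            w = stats.wilcoxon(vals - anti_persistence_null,
                               alternative="less")
            rows.append({"test": "wilcoxon_less_than_null", "groups": label,
                         "statistic": float(w.statistic),
                         "p": float(w.pvalue)})
    return pd.DataFrame(rows, columns=["test", "groups", "statistic", "p"])
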