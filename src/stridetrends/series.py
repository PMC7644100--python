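"""Per-trial stride series container and CSV I/O.

A trial of treadmill walking yields three per-stride series: stride time
(ST, seconds), stride length (SL, meters) and stride speed (SS = SL/ST,
m/s), indexed by stride number.  Trials are exchanged as plain CSV with
columns ``stride_index, st_s, sl_m, ss_mps`` (UTF-8, '.' decimal point);
synthetic trials additionally carry ``true_st_trend, true_sl_trend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StrideSeries", "read_trial_csv", "write_trial_csv"]

PARAMETERS = ("ST", "SL", "SS")
_UNITS = {"ST": "s", "SL": "m", "SS": "m/s"}


@dataclass(frozen=True)
class StrideSeries:
    """One gait parameter's per-stride values plus trial metadata."""

    values: np.ndarray
    parameter: str
    subject_id: str = ""
    trial_id: str = ""
    pws_percent: int | None = None
    treadmill_speed: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.parameter not in PARAMETERS:
            raise ValueError(f"parameter must be one of {PARAMETERS}")
        if vals.ndim != 1 or vals.size < 40:
            raise ValueError("a stride series needs at least 40 strides")
        if np.any(vals <= 0):
            raise ValueError(f"{self.parameter} values must be strictly positive")
        if self.pws_percent is not None and not (80 <= self.pws_percent <= 120):
            raise ValueError("pws_percent must be within 80-120")

    def __len__(self) -> int:
        return self.values.size

    @property
    def unit(self) -> str:
        return _UNITS[self.parameter]

    @property
    def stride_index(self) -> np.ndarray:
        """1-based stride numbers, the abscissa for trend fitting."""
        return np.arange(1, self.values.size + 1, dtype=float)


def read_trial_csv(path, subject_id: str = "", trial_id: str = "",
                   pws_percent: int | None = None,
                   treadmill_speed: float | None = None) -> dict[str, StrideSeries]:
    """Read one trial; SS is computed as SL/ST when the column is absent."""
    df = pd.read_csv(path)
    required = {"st_s", "sl_m"}
    if not required.issubset(df.columns):
        raise ValueError(f"trial CSV must contain columns {sorted(required)}")
    st = df["st_s"].to_numpy(float)
    sl = df["sl_m"].to_numpy(float)
    ss = df["ss_mps"].to_numpy(float) if "ss_mps" in df.columns else sl / st
    meta = dict(subject_id=subject_id, trial_id=trial_id,
                pws_percent=pws_percent, treadmill_speed=treadmill_speed)
    return {
        "ST": StrideSeries(st, "ST", **meta),
        "SL": StrideSeries(sl, "SL", **meta),
        "SS": StrideSeries(ss, "SS", **meta),
    }


def write_trial_csv(path, st: np.ndarray, sl: np.ndarray,
                    ss: np.ndarray | None = None,
                    true_st_trend: np.ndarray | None = None,
                    true_sl_trend: np.ndarray | None = None) -> None:
    st = np.asarray(st, float)
    sl = np.asarray(sl, float)
    data = {
        "stride_index": np.arange(1, st.size + 1),
        "st_s": st,
        "sl_m": sl,
        "ss_mps": sl / st if ss is None else np.asarray(ss, float),
    }
    if true_st_trend is not None:
        data["true_st_trend"] = np.asarray(true_st_trend, float)
    if true_sl_trend is not None:
        data["true_sl_trend"] = np.asarray(true_sl_trend, float)
    pd.DataFrame(data).to_csv(path, index=False)
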