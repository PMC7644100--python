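"""Generate one synthetic treadmill trial and look at its structure.

A trial is 250 strides of stride time (ST) and stride length (SL), each the
sum of a piecewise-linear trend (shared knot times, coupled slopes) and
anti-persistent fractional Gaussian noise; stride speed is SS = SL/ST.
"""

import numpy as np

from stridetrends import GaitTrialSpec, generate_gait_trial

spec = GaitTrialSpec(seed=7)
trial = generate_gait_trial(spec)

print(f"strides:            {len(trial.st)}")
print(f"trend segments:     {len(trial.true_knots_st) + 1}")
print(f"mean ST / SL / SS:  {trial.st.values.mean():.3f} s / "
      f"{trial.sl.values.mean():.3f} m / {trial.ss.values.mean():.3f} m/s")
print(f"COV ST / SL / SS:   {trial.st.values.std() / trial.st.values.mean():.2%} / "
      f"{trial.sl.values.std() / trial.sl.values.mean():.2%} / "
      f"{trial.ss.values.std() / trial.ss.values.mean():.2%}")
rho = np.corrcoef(trial.true_st_trend, trial.true_sl_trend)[0, 1]
print(f"trend correlation:  {rho:.2f}  (ST and SL trends move together)")

trial.to_csv("synthetic_trial.csv")
print("wrote synthetic_trial.csv (stride_index, st_s, sl_m, ss_mps, "
      "true_st_trend, true_sl_trend)")
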