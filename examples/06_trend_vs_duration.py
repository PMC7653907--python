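"""Nonlinear growth of event duration under a linear warming trend.

With thresholds fixed to an early baseline, a linear background trend
lengthens detected events faster than linearly: as the background
approaches the threshold, exceedance runs connect. This script measures
mean longest duration at several trend rates.
"""

import numpy as np

import mhwx

cfg = mhwx.SynthConfig(seed=42)
rates = [0.0, 0.5, 1.0, 2.0]
summary, detail = mhwx.trend_duration_experiment(cfg, rates, replicates=60)

print("trend (degC/decade)  mean longest duration (d)  MC s.e.")
for _, row in summary.iterrows():
    print(f"  {row.trend_C_per_decade:4.1f}               "
          f"{row.mean_longest_d:8.1f}              {row.mc_se:5.1f}")

m = summary.set_index("trend_C_per_decade")["mean_longest_d"]
slopes = np.diff(m.values) / np.diff(rates)
print(f"slopes between successive rates: "
      f"{', '.join(f'{s:.0f}' for s in slopes)} d per degC/decade")

zero = detail[detail.trend_C_per_decade == 0.0]
late = (zero.central_year >= cfg.start_year + 2 * cfg.n_years // 3).mean()
print(f"no-trend control: {100 * late:.0f}% of longest events in the final "
      f"third of the record (uniform expectation ~33%)")

# Increasing slopes are the nonlinearity: duration gains accelerate with
# the trend rate because the duration metric saturates toward permanent
# exceedance once the background shifts by order of the threshold margin.
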