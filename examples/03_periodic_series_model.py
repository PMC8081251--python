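"""The periodic two-level activity model and its critical high period.

A series z(t) is zero with probability 1-rho and otherwise geometric with a
rate lambda(t) that alternates between lambda_h and lambda_l in n intervals
per period. The environmental modulation strength, measured by the rate
fluctuation sigma_lambda^2, peaks at t_h = T/[n(ratio+1)].
"""

import numpy as np

from netmse import (PeriodicSeriesConfig, average_curves, critical_high_period,
                    generate_series, lambda_variance, mse_curve, solve_rates)

BASE = dict(Z=1000, T=2000, rho=0.2, n=5)

cfg = PeriodicSeriesConfig(**BASE, t_h=100, ratio=3.0)
prof = solve_rates(cfg)
print(f"solved rates: lambda_h={prof.lambda_h:.4g}, lambda_l={prof.lambda_l:.4g}, "
      f"lambda_int={prof.lambda_int:.4g}")
print(f"rate fluctuation sigma_lambda^2 = {lambda_variance(prof):.4f}")
print(f"critical high period t_h* = {critical_high_period(3.0, 2000, 5):.0f} steps "
      "(fluctuation decreases beyond it)")

rng = np.random.default_rng(17)
for ratio, t_h in ((1.0, 100), (3.0, 100), (3.0, 300)):
    c = PeriodicSeriesConfig(**BASE, t_h=t_h, ratio=ratio)
    avg = average_curves(
        [mse_curve(generate_series(c, rng), tau_max=100) for _ in range(50)])
    print(f"ratio={ratio:g} t_h={t_h}: mean total={np.mean([generate_series(c, rng).sum() for _ in range(50)]):.0f}"
          f"  S_E slope[10,100]={avg.slope(10, 100):+.5f}")

print("\nWithout modulation (ratio 1) the entropy profile falls with scale;"
      "\nmodulation at the critical t_h flattens it; stretching t_h past the"
      "\ncritical value weakens the modulation and restores the decay.")
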