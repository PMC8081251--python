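"""Full analysis of a (simulated) multi-day face-to-face contact stream.

Builds a two-day tij file with the simulator, partitions it into days,
derives the per-step counts of newly activated links K(t) and all activated
links W(t), and summarizes their multiscale entropy and heterogeneity /
memory statistics.
"""

import tempfile
from pathlib import Path

import numpy as np

from netmse.pipeline import analyze, make_fixture

taus = np.array([1, 2, 5, 10, 20, 40, 70, 100])

with tempfile.TemporaryDirectory() as tmp:
    tij = make_fixture("case2", seed=5, out_dir=tmp, days=2)[0]
    out = Path(tmp) / "analysis"
    summary = analyze(tij, steps_per_day=2000, out_dir=out, taus=taus)

    print(f"events: {summary['n_events']}, days: {summary['n_days']}")
    for name, H, M in summary["stats"]:
        print(f"  {name}: heterogeneity H={H:+.3f}  memory M={M:+.3f}")
    avg = summary["mse_K_mean"]
    print("day-averaged entropy of K(t):",
          "  ".join(f"tau={t}:{v:.2f}" for t, v in zip(avg.tau, avg.mean)))

print("\nH > 0 flags heavy-tailed per-step counts (bursts); M > 0 flags"
      "\npersistence between consecutive steps. The S_E-vs-tau profile"
      "\nlocates the timescales on which the contact dynamics look complex.")
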