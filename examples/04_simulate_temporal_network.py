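"""One run of the environmental temporal-network simulator.

Per step, K(t) new links form between activity-chosen nodes and L(t) old
links re-activate preferentially by accumulated weight; both budgets follow
the periodic two-level model. The output is a full temporal network whose
aggregated link weights are heavy-tailed.
"""

import numpy as np

from netmse import (ModelConfig, aggregate, classify_mse_shape, average_curves,
                    generate_network, gini, mse_curve)

cfg = ModelConfig(t_h=100, ratio_K=9.0, ratio_L=1.5, seed=11)  # strongest regime
net = generate_network(cfg)
s = net.series
print(f"realized totals: K={s.K} links, W={s.W} activations, L={s.L} re-activations")
print(f"counters: {net.counters}")

agg = aggregate(net.events)
w = agg.weights()
print(f"aggregated network: N={agg.N}, links={agg.n_links}, "
      f"median weight={np.median(w):.0f}, max weight={w.max()}, "
      f"Gini(weights)={gini(w):.2f}")

curves = [mse_curve(generate_network(
    ModelConfig(t_h=100, ratio_K=9.0, ratio_L=1.5, seed=[11, r])).series.K_t,
    tau_max=100) for r in range(30)]
avg = average_curves(curves)
print(f"mean S_E^K shape over 30 runs: {classify_mse_shape(avg)!r} "
      f"(slopes [10,40]={avg.slope(10, 40):+.4f}, [40,100]={avg.slope(40, 100):+.4f})")

print("\nThe high Gini reflects the rich-get-richer weight dynamics; the"
      "\n'increasing' entropy shape is the signature of strong periodic"
      "\nenvironmental modulation of link creation.")
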