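"""Planted communities, modularity, and recovery of the mixing ratio p.

With N_c communities, a newly activated node picks intra-community partners
with weight 1 and inter-community partners with weight p. Modularity Q of
the planted partition falls as p grows, and p can be re-estimated from the
aggregated network as the inter/intra link-density ratio.
"""

import numpy as np

from netmse import (CommunityMap, ModelConfig, aggregate,
                    estimate_mixing_ratio, generate_network, modularity)


def planted_map(cfg):
    labels = cfg.community_labels()
    return CommunityMap({i: int(labels[i]) for i in range(cfg.N)})


for p in (0.0, 0.2, 0.5, 1.0):
    qs, phats = [], []
    for r in range(5):
        cfg = ModelConfig(N=250, n_communities=5, p=p, seed=[43, r])
        net = generate_network(cfg)
        agg = aggregate(net.events)
        qs.append(modularity(agg, planted_map(cfg)))
        if p > 0:
            phats.append(estimate_mixing_ratio(agg, planted_map(cfg)))
    phat = f"{np.mean(phats):.3f}" if phats else "0 (no inter links)"
    print(f"p={p:<4g} planted-partition Q={np.mean(qs):+.3f}   p_hat={phat}")

print("\nQ ~ 0.8 at p=0 (isolated communities) falling to ~0 at p=1 (no"
      "\ncommunity structure); p_hat recovers the generating p from link"
      "\ncounts alone.")
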