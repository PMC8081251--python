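# netmse

Multiscale-entropy analysis and generative models for temporal contact
networks.

## The problem

Face-to-face interaction datasets (SocioPatterns-style proximity records,
one contact event per 20-second step) define *temporal networks*: links
exist only at the moments nodes interact. Their system-level dynamics are
captured by per-step counts — the number of newly activated links *K*(*t*),
of all activated links *W*(*t*), and of re-activations
*L*(*t*) = *W*(*t*) − *K*(*t*) — whose temporal correlations span many
timescales and are shaped both by internal interaction mechanisms and by
periodic environmental schedules (classes, breaks, shifts).

`netmse` provides, for researchers studying such systems:

* **Multiscale entropy (MSE).** The sample entropy
  *S*<sub>E</sub>(*m*, *r*) = ln(Σ<sub>t</sub>C<sub>t</sub><sup>m</sup> / Σ<sub>t</sub>C<sub>t</sub><sup>m+1</sup>)
  — the negative log conditional probability that templates matching for
  *m* points within Chebyshev tolerance *r* (self-matches excluded) still
  match at *m*+1 points — evaluated on coarse-grained copies of a series
  (non-overlapping windows of size τ), with defaults *m* = 2 and
  *r* = 0.15 σ frozen from the original series. Decreasing
  *S*<sub>E</sub>(τ) is the white-noise signature, flat is 1/*f*-like,
  increasing is 1/*f*²-like; reference generators for all three noises are
  included.
* **Heterogeneity and memory.** *H* = (σ<sub>x</sub> − m<sub>x</sub>)/(σ<sub>x</sub> + m<sub>x</sub>)
  (−1 for constant series, 0 for exponential values, > 0 for heavy tails)
  and the lag-one memory coefficient *M* ∈ [−1, 1].
* **A periodic two-level activity model.** z(*t*) is 0 with probability
  1 − ρ and otherwise a positive integer with mean λ(*t*), where λ(*t*)
  alternates between λ<sub>h</sub> (for *t*<sub>h</sub> steps) and
  λ<sub>l</sub> within each of *n* intervals, calibrated so that
  E[Σz(*t*)] = *Z*. The rate fluctuation σ<sub>λ</sub>² peaks at the
  critical duration *t*<sub>h</sub>\* = *T*/[*n*(λ<sub>h</sub>/λ<sub>l</sub> + 1)].
* **An environmental temporal-network simulator.** Per step, *K*(*t*)
  activity-chosen nodes create links to never-connected partners (with
  community mixing ratio *p*: intra-community weight 1 vs inter-community
  weight *p*), and *L*(*t*) existing links re-activate preferentially by
  accumulated weight Π<sub>i</sub>(*t*) = w<sub>i</sub>(*t*−1)/Σ<sub>j</sub>w<sub>j</sub>(*t*−1),
  producing heavy-tailed link-weight distributions. A plain activity-driven
  null model (no budgets, no preferential activation) is included for
  comparison.
* **I/O and statistics** for tij contact files, daily partitioning,
  aggregated networks, linear/logarithmic binning, planted-partition
  modularity *Q*, and a link-density estimator of *p*.

## Worked example

```python
import numpy as np
from netmse import (ModelConfig, aggregate, average_curves, classify_mse_shape,
                    generate_network, gini, mse_curve)

cfg = ModelConfig(t_h=100, ratio_K=9.0, ratio_L=1.5, seed=11)
net = generate_network(cfg)
print(net.series.K, net.series.W)          # realized totals

agg = aggregate(net.events)
print(gini(agg.weights()))                 # weight concentration

curves = [mse_curve(generate_network(
    ModelConfig(t_h=100, ratio_K=9.0, ratio_L=1.5, seed=[11, r])).series.K_t,
    tau_max=100) for r in range(30)]
print(classify_mse_shape(average_curves(curves)))
```

prints (see `examples/04_simulate_temporal_network.py`)

```
realized totals: K=1344 links, W=10446 activations, L=9102 re-activations
aggregated network: N=100, links=1344, median weight=1, max weight=276, Gini(weights)=0.78
mean S_E^K shape over 30 runs: 'increasing' (slopes [10,40]=-0.0004, [40,100]=+0.0091)
```

A median link weight of 1 against a maximum of 276 (Gini 0.78) is the
rich-get-richer signature of preferential activation, and the `'increasing'`
entropy shape of {*K*(*t*)} is the fingerprint of strong periodic
environmental modulation of link creation. The other scripts under
`examples/` demonstrate noise calibration, contact-stream analysis, the
periodic series model, and community mixing; each prints the numbers it
computes and what they mean. A thin CLI (`netmse analyze|simulate|periodic|
noise|fixtures`) wraps the same pipelines for shell use.

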