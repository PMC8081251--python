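# Methods

This note documents the models and estimators implemented in `netmse`, the
conventions chosen where several were defensible, and the limits of what
the synthetic-data tests demonstrate.

## Network-level series from contact streams

A contact stream is a set of events (*t*, *i*, *j*) on 1-based integer
steps; link activity is binary per step, so duplicate records collapse and
self-contacts are rejected. From a stream we derive *W*(*t*) (distinct
pairs active at *t*), *K*(*t*) (pairs whose earliest event is at *t*) and
*L*(*t*) = *W*(*t*) − *K*(*t*). Days are fixed-length windows of
`steps_per_day` steps supplied by the caller and re-indexed to start at
step 1; empirical deployments have irregular active hours, so an explicit
parameter is preferable to any wall-clock rule. Timestamps in tij files
are divided by `step_seconds` only when *every* timestamp is a multiple of
it, which makes write∘read the identity.

## Sample entropy and the MSE curve

S_E(m, r) = ln(Σ_t C_t^m / Σ_t C_t^{m+1}) with Chebyshev matching within
tolerance r and self-matches excluded. Two conventions matter:

* **Template counts.** We build T − m templates at *both* lengths m and
  m + 1 (the length-(m+1) window starting at t = T − m still fits). The
  more common implementation uses T − m − 1 templates at length m + 1;
  the difference is one template and vanishes for long series, but exact
  oracle tests must use our convention.
* **Tolerance freezing.** r = 0.15 σ is computed once from the original
  (τ = 1) series with the population standard deviation and reused at
  every scale; it is never recomputed from coarse-grained copies.

Coarse-graining averages non-overlapping windows of τ points and drops a
trailing partial window. Scales whose coarse series is shorter than m + 2,
or with zero match counts, yield NaN ("undefined") entries that are
counted, excluded from day/replicate averages, and never raised as errors:
short coarse series at large τ can legitimately have no matches.

For iid N(0, 1) data the conditional matching probability is
P(|X − X′| ≤ r) with X − X′ ~ N(0, 2/τ) after coarse-graining, giving the
closed form S_E = −ln erf(0.15 √τ / 2) (≈ 2.47 at τ = 1) used as an
independent calibration oracle.

The curve-shape classifier uses least-squares slopes s1, s2 of the
averaged curve on τ ∈ [10, 40] and [40, 100]: s2 < 0 is "rise-then-fall",
s2 ≥ |s1| is "increasing", anything else "peak-then-flat". It is
parameter-free; the windows are the two halves (log-wise) of the standard
τ ≤ 100 analysis range.

## Heterogeneity and memory

H = (σ − m)/(σ + m) of the series values and the lag-one coefficient M,
whose leading/trailing windows get their own means and population
standard deviations. Both are undefined (errors) for degenerate inputs
(all-zero series; zero-variance windows).

## Noise generators

White: iid standard normals. 1/f: Voss–McCartney with 16 sources (source
k refreshes every 2^k steps), standardized; 16 sources give ≥ 2 decades of
1/f scaling for T = 3×10⁴ (measured periodogram slope −0.99). 1/f²:
standardized cumulative sum of white noise (measured slope −1.98).

## Periodic two-level activity model

Parameters (Z, T, ρ, n, t_h, ratio): the budget identity
Z = ρ[λ_h t_h + λ_l(T/n − t_h)]n fixes both rates given the contrast
ratio = λ_h/λ_l and t_h. The positive part of z(t) must live on
{1, 2, …} with mean λ(t); we realize it as a geometric distribution with
success probability 1/λ(t), which preserves the budget *exactly* in
expectation but requires λ ≥ 1. For sub-unit rates (reachable at strong
contrast, e.g. ratio 9 with the reference budgets) the generator, when
explicitly allowed, falls back to the ceiling of an exponential variate —
the smallest-mean discretization of the exponential law on positive
integers — whose mean exceeds λ, so those steps overshoot the budget
slightly (for the strongest reference regime, by ~18% on the K-budget).
The network simulator enables this fallback; the stand-alone periodic API
raises by default.

The rate fluctuation σ_λ² = λ_int²(c)²s(1−s)/[1+cs]², with c = ratio − 1
and s = t_h/(T/n), holds exactly against direct time-averaging and — under
the fixed-budget constraint, which pins λ_int — peaks at
t_h\* = T/[n(ratio+1)]. The critical value is meaningful only with the
budget held fixed; at fixed (λ_h, λ_l) the maximizer would instead be
s = 1/2.

## Temporal-network simulator

Per step t: (1) K(t) nodes are drawn sequentially without replacement with
probability ∝ activity (a node creates at most one new link per step);
each links to a partner drawn among non-self, never-connected candidates
with weight 1 (same community) or p (other community). A node with no
eligible candidate is skipped and another active node is drawn; if the
budget still cannot be met the step is truncated with a logged counter.
(2) L(t) links from the registry E_t (links created before step t)
re-activate, drawn sequentially without replacement with probability
∝ accumulated weight w(t−1); weights are frozen for the whole step and
updated afterwards, and newly created links enter the registry with weight
1 only after the step. (3) While the registry is small, a positive L(t)
draw exceeding |E_t| is redrawn from its geometric law until it fits; with
an empty registry it is forced to 0 (a positive-integer draw can never
satisfy l ≤ 0 — any implementation must special-case this).

All randomness flows from one seed through four named sub-streams (budget
counts, node choice, partner choice, activation), so each stage can be
pinned independently and full runs are byte-reproducible.

**Known bias.** The redraw rule strictly lowers E[L(t)] while the registry
is small: the run starts from isolated nodes, so E[Σ L(t)] falls short of
the calibration target L by ~0.5% at the reference configuration
(measured ≈ 8940 vs 9000; the K-budget is unbiased). This is inherent to
the mechanism, not a numerical artifact; the budget *series* before
registry clamping conserve exactly and are tested separately. A 3-SE test
of the realized totals at 200 runs sits exactly at this bias and fails.

**Communities** are equal contiguous blocks of N/N_c nodes. Modularity Q
is Newman–Girvan on the *binary* aggregated network (weighted Q would mix
in the preferential-activation dynamics, which is a separate mechanism).
The mixing estimator p̂ = (inter-link density)/(intra-link density)
matches the generator's partner weighting in both limits, but is biased
upward when intra-community candidate pools saturate: at N = 100 with
K = 1000 the mean degree (20) exceeds the 19 available intra partners, and
p̂ overshoots 0.2 by ~0.06. Recovery experiments therefore run at N = 250
(same budgets), where the estimator is unbiased to within ±0.005.

**Null model.** Each node independently activates with probability a_i per
step and links to a uniformly random partner — the plain activity-driven
model, without budgets or preferential activation. With F(a) ∝ a^−γ on
[ε, 1] (defaults γ = 2.5, ε = 10⁻³), aggregated degrees inherit the
exponent γ. Two finite-size effects shape the measurable range: uniform
incoming links add ≈ T·E[a] (~6) to every degree, flattening P(k) below
k ≈ 100, and distinct-partner saturation compresses the tail on the scale
k ~ N. Exponent-recovery experiments therefore use N = 3×10⁴ and fit a
truncated-support maximum-likelihood estimator on k ∈ [150, 2000]
(offset < 4% of the lower cutoff, saturation < 2%); the plain Hill
estimator on bounded-support samples is biased upward and is only used
when no upper bound applies.

**Degree tails under budgeting.** The budgeted model does *not* produce
heavier aggregated-degree tails than the null at matched link creations:
first-order creation rates coincide (K·a_i/Σa) and the one-new-link-per-
node-per-step cap trims the most active nodes, so the budgeted p99/p99.9
degrees are equal or smaller. What the budget-plus-preferential mechanism
does produce is heavy link-*weight* tails (Gini ≈ 0.80 vs 0.45 for a
uniform-re-activation ablation on identical seeds; P(w) spanning > 2.5
decades at the reference scale), and the property tests assert exactly
that contrast.

## Scales used in tests

Stochastic acceptance checks run at desk scale: 100 replicates where 10³
would be ideal for curve averaging (noise trends: 10 series of T = 3×10⁴;
modularity and regime classification: 100 networks per configuration;
conservation: 200 runs; mixing recovery: 50 runs). These were chosen as
the package's standard quick-validation sizes; every threshold tested is
stated with the statistical margin it assumes (3 standard errors, or a
fixed tolerance wider than the measured spread across disjoint seed
batches).

## What the synthetic data does and does not show

The simulator reproduces the *mechanisms* the analysis targets — periodic
environmental modulation, preferential re-activation, planted communities,
heterogeneous activities — with stationary parameters and equal-sized
communities. It does not emulate empirical features such as irregular
recording hours, participant turnover across days, unequal class sizes,
spatial constraints, or recording noise. Passing tests therefore validate
the estimators and generators against each other and against closed forms;
they do not certify conclusions about any particular empirical dataset.
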