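# feastfamine

Population-dynamics modelling of a heritable **live fast, die young** growth
strategy competing against a **live slow, die old** strategy under
feast/famine nutrient cycles, together with the estimators that parameterize
the model from bench assays.  Built for quantitative biologists studying
bet-hedging epigenetic states (e.g., prion-based switches in budding yeast)
who want to go from plate-reader curves, viability series, and competition
counts to a seeded, uncertainty-aware prediction of competitive fitness.

## The model

Two sub-populations x₀ (LS-DO, growth rate µ₀, death rate δ₀) and x₁ (LF-DY,
µ₁, δ₁) alternate between a nutrient-replete phase of duration τ₁ and a
starvation phase of duration τ₂:

    x_i → x_i e^{µ_i τ₁}   (growth)      x_i → x_i e^{−δ_i τ₂}   (starvation)

Only the population ratio matters, and after N cycles it has the closed form

    log(x₁/x₀)(N) = log(x₁/x₀)(0) + N·[(µ₁−µ₀)τ₁ − (δ₁−δ₀)τ₂]

so a growth advantage paid for with a death cost wins exactly when
Δµ·τ₁ > Δδ·τ₂.  Around this core the package provides:

* `population_model` — the grow/starve recursion, its closed form, and
  phase-space scans over durations or advantage/cost;
* `rate_inference` — maximal proliferation rate (peak of the smoothed
  derivative of growth data), exponential death constant (log-linear CFU
  fit), selection coefficient (logit slope of marker fraction vs
  generations), median replicative lifespan;
* `ensemble` — Monte Carlo propagation of empirical rate distributions into
  a predicted competition trajectory (median + 95% band, 1000 draws);
* `phenotypes` — large-cell threshold statistics, sphere-volume conversion,
  G1 reduction, polysome/monosome area ratio, dual-luciferase normalization,
  GFP-screen Z-score calls, positional CAI profiles;
* `synthdata` — seeded generators for every assay type, so the whole
  pipeline runs with no external data;
* a `feastfamine` CLI (`simulate`, `estimate`, `montecarlo`, `phasespace`,
  `analyze`, `generate`) with provenance recording.

## Worked example

Thirty cycles with a 1% growth advantage and a 1% death cost, feast twice as
long as famine:

```python
from feastfamine import population_model as pm

r0 = pm.StrategyRates(1.0, 1.0, "LS-DO")
r1 = pm.StrategyRates(1.01, 1.01, "LF-DY")
cycle = pm.EnvironmentCycle(tau_grow=2.0, tau_starve=1.0, n_cycles=30)
print(pm.analytic_log_ratio(r0, r1, cycle))
# 0.30000000000000027
```

Per cycle the fast strategy nets 0.01·2 − 0.01·1 = 0.01 in log ratio; after
30 cycles the LF-DY population is e^0.3 ≈ 1.35× the LS-DO population.  At
equal durations (τ₁ = τ₂) the same rates give exactly 0 — the strategies are
neutral.

Estimating growth rates from noisy synthetic plate-reader curves:

```python
import numpy as np
from feastfamine import synthdata as sd, rate_inference as ri

est = {}
for curve in sd.gen_growth_curves(sd.GrowthCurveSpec(seed=1)):
    rate, _ = ri.estimate_growth_constant(curve, window=15, min_od=0.1)
    est.setdefault(curve.strain, []).append(rate)
print({k: round(float(np.mean(v)), 3) for k, v in est.items()})
# {'naive': 0.32, 'prion': 0.5}
```

The two strains were simulated at true maximal rates 0.35 and 0.56 per hour;
the peak-of-derivative estimator recovers their ~60% gap (here 56%) from
four replicates each.

The same pipeline runs from the shell:

```sh
feastfamine simulate --tau1 2 --tau2 1 --out out/
head -3 out/trajectory.csv
# cycle,phase,log_x0,log_x1,log_ratio
# 0,start,0.0,0.0,0.0
# 1,grow,2.0,2.02,0.020000000000000018
```

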