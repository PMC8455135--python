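# Methods

## The model

`feastfamine` models competition between two heritable growth strategies in a
fluctuating nutrient environment: a *live-fast-die-young* (LF-DY) state with a
higher exponential growth constant µ₁ but a higher starvation death constant
δ₁, and a *live-slow-die-old* (LS-DO) state with (µ₀, δ₀).  The environment
alternates between a nutrient-replete phase of duration τ₁ and a starvation
phase of duration τ₂.  Within a phase each sub-population changes
exponentially:

    growth:      x_i → x_i · exp(µ_i τ₁)
    starvation:  x_i → x_i · exp(−δ_i τ₂)

Lag and stationary kinetics are neglected because they do not move the
*ratio* of the two sub-populations, which is the only quantity the model
tracks (no carrying-capacity coupling).  Iterating the two phases gives a
recursion whose closed form is linear in the cycle count N:

    log(x₁/x₀)(N) = log(x₁/x₀)(0) + N·[(µ₁−µ₀)τ₁ − (δ₁−δ₀)τ₂]

`run_cycles` iterates the recursion; `analytic_log_ratio` evaluates the
closed form; a property test requires agreement to 1e−10 in log space.  All
internal arithmetic is in natural-log abundance (no overflow over arbitrarily
many cycles); phase-space grids export log₁₀ ratios for heatmap-style plots.

The equal-fitness boundary is τ₂/τ₁ = Δµ/Δδ.  The "1% growth advantage, 1%
higher death cost" scan is implemented as additive offsets on rates
normalized to a unit baseline (µ₀ = δ₀ = 1, µ₁ = δ₁ = 1.01): only equal
*absolute* offsets make the two strategies exactly neutral at equal phase
durations, which is the behaviour the scan is meant to exhibit; explicit
four-rate input is accepted for any other reading.  Scans default to 50×50
grids and N = 30 cycles.

## Rate inference

* **Maximal proliferation rate** (`estimate_growth_constant`): peak of the
  smoothed derivative of the growth data.  The default *specific* mode
  differentiates ln OD (units 1/h — the constant the model consumes); the
  *absolute* mode differentiates OD directly (the plate-reader bar-chart
  convention).  Smoothing is a centered moving average applied to the OD
  series and again to the derivative; the default window is 5 points and
  should scale with sampling density (15 points for 10-minute sampling).
  An optional OD floor (`min_od`) excludes readings near the instrument
  detection limit, where additive OD noise dominates the log-derivative.
  For a logistic curve the specific rate at the floor is µ(1 − OD/K), so a
  common floor rescales all strains identically and between-strain ratios
  are unaffected; we use `min_od = 0.1` for dense noisy curves.
* **Death constant** (`estimate_decay_constant`): least-squares slope of
  ln CFU against day, negated.  Zero counts are dropped with a warning (the
  model class is log-linear); an all-zero series is an error.
* **Selection coefficient** (`estimate_selection_coefficient`): least-squares
  slope of the log marker odds ln(f/(1−f)) against generations, with its
  regression standard error.  Raw colony counts enter through the
  Haldane–Anscombe continuity correction (r+0.5)/(n+1) so saturated counts
  stay off the logit boundary.
* **Median replicative lifespan** (`median_survival`): sample median
  (midpoint convention for even n) plus the empirical complementary CDF as
  the survival curve.  No censoring machinery — all observations are
  complete division counts.

Per-replicate estimates pool into a `RateDistribution` (raw sample plus
mean/SD, sample-SD ddof = 1), the sampling pool for the ensemble.

## Monte Carlo ensemble

`run_ensemble` draws (µ₀, µ₁, δ₀, δ₁) independently with replacement from the
empirical pools — nonparametric resampling, since no distributional family is
asserted for the replicate-level measurements — runs the recursion per draw
under a serial-passage protocol, and summarizes the LF-DY fraction per
generation by the median and the empirical 2.5–97.5 percentile band (linear
interpolation).  The default ensemble size is 1000 draws.  The protocol
defaults to 10 passages of 10 bulk generations (a 1:1000 dilution ≈ 2¹⁰);
generation time within a draw is anchored to the reference strain,
t_gen = ln2/µ₀, so "a passage of g generations" is a property of the bulk
regrowth rather than of either competitor alone.  A starvation interval per
passage is explicit and defaults to 0 (growth-only competition); death-rate
draws enter only when it is set, in the same time unit as the δ pools.
Draws pair µ and δ independently — no correlation structure is imposed.
A fixed seed makes the whole summary bit-reproducible, and degenerate
single-point pools reproduce the deterministic model exactly.

## Phenotype quantifications

* **Large cells**: threshold = naive mean area + one sample SD (ddof = 1,
  pooled across naive replicates); "large" is area ≥ threshold.  Fractions
  are invariant under affine unit rescaling applied to both samples.
* **Sphere volumes**: radius = √(area/π); percent volume difference of b
  over a is 100·[(area_b/area_a)^{3/2} − 1] — it depends only on the area
  ratio.
* **G1 reduction**: 100·(f_naive − f_test)/f_naive on unbudded-cell
  percentages.
* **Polysome/monosome ratio**: the minimum absorbance between the monosome
  and disome peak centers defines zero; the shifted trace (negatives clipped
  to 0) is integrated by trapezoid over the annotated monosome region and
  the summed polysome regions.  The rule removes any constant offset exactly
  and any absorbance rescaling cancels in the ratio; a *sloped* baseline is
  only removed at a single point, so steep slopes bias the ratio — the
  synthetic trace uses a realistic shallow slope (1e−4 A260/mm) under which
  the residual is well inside the 0.05 reporting tolerance.
* **Dual-luciferase**: firefly/Renilla per well, per-genotype means within a
  reporter variant, naive mean scaled to 1.0.
* **GFP screen**: GFP/OD values are Z-scored across proteins within each
  replicate of each background separately; a protein's score is its
  replicate-mean Z.  *Robust* means replicate-level Z SD < 1 in both
  backgrounds (the threshold is a parameter — the filter's exact reading is
  ambiguous, so it is explicit); a call is up/down when robust and
  |ΔZ| ≥ 1.0 (≥, configurable).  Z-scoring makes calls invariant to
  per-replicate multiplicative gain.
* **CAI profiles**: per-codon relative-adaptiveness weights (Sharp–Li:
  usage divided by the synonymous-family maximum; zero-usage codons clamped
  to 0.01), windowed geometric mean centered at each codon (default 11
  codons, clipped at sequence ends), arithmetic mean across sequences long
  enough to cover each position.  A single trailing stop codon is excluded.
  The weight table is an input because no single reference gene set is
  canonical.

## Synthetic data

Generators are pure functions of their spec (parameters + seed).  Families
are modelling choices: logistic growth with additive Gaussian OD noise;
exponential viability decay with Poisson colony counts plated at the
dilution that targets ~200 colonies per timepoint (as bench protocols dilute
into a countable range — this keeps the log-linear fit unbiased at late
days); discretized Gompertz lifespans with the scale calibrated so the
continuous median hits the target (shape 0.15/division); logit-linear marker
drift with binomial colony sampling; Gaussian gradient peaks (±2.5 SD region
annotations truncate every peak proportionally, leaving area ratios exact)
on a linear baseline; lognormal multiplicative noise for reporter plates and
the GFP screen, with a shared per-protein baseline inducing the observed
between-background correlation.

Defaults encode the study conditions: growth rates 0.35/0.56 1/h (4
replicates, 48 h at 10-min sampling, noise SD 0.003), CLS days 0–80 at 8
replicates (δ 0.05/0.08 per day), RLS medians 30/23 at n = 280, selection
s = 0.01 sampled every 10 generations to 100 with 1000 colonies,
polysome:monosome 3.2, luciferase fold 1.5 over 8 wells at 5% noise, areas
22.01/25.36 µm².

What the generators do *not* emulate: plate-edge and evaporation artifacts,
lag-phase heterogeneity, culture acidification during CLS, mother-cell
censoring, gradient-fractionator drift, and batch effects across plates.
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated noise models, not robustness to every artifact of real
instruments.

## Numerical choices and limitations

* Derivatives via `np.gradient` (central differences, one-sided at edges).
* Percentiles via `np.percentile` with linear interpolation.
* Even-n medians by the midpoint convention.
* Negative baseline-subtracted absorbance clipped at 0 before integration.
* Large-cell comparison uses ≥; screen calls use ≥ the threshold.
* Sub-seeds for pipeline stages derive deterministically from the run seed
  (CRC32 of the stage name mixed into a `SeedSequence`), so stages re-run in
  isolation reproduce exactly.
* The deterministic model is intentionally minimal: no demographic noise, no
  density dependence, no switching between states within a lineage.  It
  answers "which strategy wins, and how fast" — not absolute abundances.
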