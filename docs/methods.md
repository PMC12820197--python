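# Methods

## The model

`thermassembly` is an individual-based, eco-evolutionary model of how a
temperature regime assembles the thermal-limit traits (CTmin, CTmax) of
an ectotherm community, together with the trait-space analytics used to
summarize either model output or field trait tables.

### Temperature process

Temperature is hierarchical on two timescales.  A *block mean* is
redrawn every `t_span` steps from Normal(`t_mean`, `sigma_long`²)
("long-term variability": seasonal-scale excursions lasting many
organismal lifespans).  Each step's realized temperature adds
Normal(0, `sigma_short`²) noise around the current block mean
("short-term variability": sub-generation fluctuation).  Over long runs
the realized variance decomposes as `sigma_short² + sigma_long²`.  A
sine mode replaces the Gaussian block means with a deterministic wave of
amplitude `√2·sigma_long` (so its SD over whole periods equals
`sigma_long`), making the two long-term regimes directly comparable.
Defaults: `t_span = 250` steps and a per-step mortality near 0.05
(organismal lifespan ≈ 20 steps), so one step ≪ lifespan ≪ block
length — short-term noise is felt within a generation, long-term
variation across many.

### Productivity

Productivity follows a tent function of temperature: 0 at 0 °C, rising
linearly to 1 at 30 °C, falling to 0 at 40 °C.  It is the simplest shape
consistent with a unimodal resource curve that peaks at 30 °C and
vanishes at thermal extremes; the three nodes are configurable.  The
multiplier `pm` enters the model three ways:

* carrying capacity `K = round(k0 · pm(t_mean))`;
* per-step fecundity is scaled by `pm(T_t)` at the realized temperature;
* **mortality is scaled by scarcity `1/pm(t_mean)`** (capped so no rate
  exceeds 0.95).  Scarce resources raise starvation risk for everyone;
  benign productive environments relax the environmental filter.

The scarcity–mortality link is the mechanism behind the favorability
prediction: the set of thermal strategies whose expected fecundity
clears their expected mortality (the "viable wedge" in (CTmin, CTmax)
space) expands as productivity rises and collapses past the optimum.  A
mean-field calculation of that wedge (expected fecundity vs expected
mortality per strategy on a grid) shows its area growing nearly
linearly over 14–24 °C and peaking at 30 °C under the default rates.
With the link disabled (`productivity_link=False`) the multiplier is a
constant and every temperature level is statistically identical —
the constant-productivity control scenario.

### Thermal performance curves

A species' TPC is the symmetric parabola `P(T) = 6·h·u(1−u)` with
`u = (T − CTmin)/(CTmax − CTmin)`, zero at and outside the critical
limits.  In the default *constrained* mode all curves share total area
`A0 = 20` performance·°C (`h = A0/width`), enforcing the
specialist–generalist trade-off: a 2 °C-wide specialist peaks at 15, a
30 °C generalist at 1.  *Relaxed* mode frees the height (immigrants
draw it uniformly from the range the constrained mode would span),
removing the trade-off for the robustness scenario.  Real TPCs are
left-skewed; the symmetric shape is the minimal choice given only the
constraints "smooth, zero at the limits, fixed area", and the curve
builder is the single place a different shape would plug in.

Immigrant traits: CTmin ~ U(−10, 35) °C, width ~ U(2, 30) °C.
Mutation-mode speciation perturbs a resident parent's CTmin and width
with Gaussian offsets (SD 1 °C each, width floored at 1 °C).

### Demography

Each step, at realized temperature `T_t`:

1. **Mortality.**  Each individual of species *i* dies with probability
   `d_i = scarcity · (d_out − (d_out − d_in)·q_i)` where
   `q_i = P_i(T_t)/(P_i(T_t) + perf_half)`.  Mortality falls smoothly
   from `d_out` (no performance) toward `d_in` (high performance);
   `perf_half` (default 0.5) sets how quickly performance buys
   survival.  The smooth form treats the critical limits as the onset
   of performance loss rather than instant death, and reduces to the
   sharp in-range/out-of-range dichotomy as `perf_half → 0`.
2. **Arrival.**  With probability `immigration_rate` one species
   arrives (prior draw, or mutant of an abundance-weighted parent in
   mutation mode) at `min(n0, K − N)` individuals.  Arrivals claim
   mortality-freed capacity *before* the recruitment lottery;
   otherwise saturated (favorable) environments would never admit
   immigrants and the immigrant supply would covary with favorability.
   In mutation mode an empty assemblage has no parent and falls back
   to a prior draw (recolonization).
3. **Reproduction.**  Expected fecundity
   `f_i = r_max · pm(T_t) · crowding_i · P_i(T_t) · N_i`, with
   `crowding_i = max(0, 1 − (αN)_i/K)`.  The competition coefficients
   `α_ij` are MacArthur overlap integrals of the unit-area TPC shapes,
   so thermally similar species compete strongly while dissimilar
   strategies partition the resource axis (`α_ii = 1`; a wide
   generalist exerts little crowding on a specialist nested inside its
   range).  Total recruit demand is Poisson(Σf), truncated at the free
   capacity `K − N`.
4. **Lottery competition.**  Recruits are allocated multinomially with
   weights equal to the expected fecundities — performance × abundance
   damped by niche-local crowding, the relative-fitness rule.  With
   competition off, performance is removed from the allocation weights
   (∝ `N_i · crowding_i`) while the capacity cap stays, isolating the
   abiotic filter.
5. Species reaching abundance 0 are recorded extinct with their
   lifespan.

All randomness is species-level (binomial / Poisson / multinomial
counts), distributionally equivalent to per-individual Bernoulli fates
but orders of magnitude faster; the equivalence is verified against a
per-individual oracle in the test suite.  One master seed spawns
independent streams for environment, demography and arrivals, so
scenario toggles never shift unrelated draws.

Defaults: `d_in = 0.05`, `d_out = 0.3`, `r_max = 0.4`, `k0 = 2000`,
`immigration_rate = 0.02`, `n0 = 10`, `n_init = 20`,
`perf_half = 0.5`.  With these rates a benign mid-gradient environment
(18 °C, `sigma_short` 2.5) equilibrates at a few hundred to a few
thousand individuals and a handful of coexisting species per run, with
total abundance, richness and mean species lifespan all increasing
toward the 30 °C optimum and collapsing beyond ~36 °C.

### Sweeps and the per-level assemblage

A sweep varies one of `t_mean`, `sigma_short`, `sigma_long` over
ordered levels with replicate runs per level (deterministically derived
seeds; changing one cell's seed leaves all others untouched).  A single
simulation ends with few coexisting species — competitive exclusion
inside one realized thermal niche is strong — so the *level assemblage*
is the pooled final trait table of all replicates at that level:
different replicates fix different winners from the viable wedge, and
the pool samples the wedge.  All level responses (hypervolume, TTrange
mean/SD, richness, total abundance, mean lifespan, strategy ratios) are
computed on these pooled tables, and trends are OLS fits of level
response on the varied parameter (slope, 95% CI, t-test p, R²).

## Trait-space analytics

* **Pooled standardization.**  CTmin and CTmax are z-scored with one
  mean/SD per trait computed over the pooled species set of *all*
  assemblages being compared.  Per-assemblage scaling would erase
  exactly the between-assemblage volume differences of interest.
* **Hypervolume.**  The area of the 95% highest-density region of a
  weighted Gaussian KDE of the standardized (CTmin, CTmax) points,
  species weighted by individual counts.  To control for richness the
  estimate averages 100 repeats of a 20-species subsample (all species,
  single repeat, when richness ≤ 20).  Subsampling is
  abundance-weighted without replacement, so common species anchor the
  estimate and vagrant singletons are rarely drawn.  Exact-duplicate
  trait points are merged (weights summed) before density estimation,
  which makes the estimate invariant to duplicating every species.
  The KDE is separable-Gaussian on a 256×256 grid padded by 3
  bandwidths; the HDR threshold takes highest-density cells until ≥95%
  of grid mass is enclosed (ties at the threshold included).
  Bandwidths default to the per-dimension Silverman rule over the
  distinct subsampled points; sweep analyses instead share one fixed
  bandwidth (0.10 standardized units) across all levels of a sweep, so
  level volumes differ only through their point clouds — per-level
  Silverman bandwidths on 10–40-point pooled clouds fluctuate enough to
  dominate the between-level signal.  The bandwidth is injectable
  everywhere for sensitivity analyses.
* **TTrange statistics.**  Unweighted mean and sample SD of per-species
  CTmax − CTmin.
* **Thermal strategies.**  k-means with k = 4 on the standardized
  traits (50 restarts, best inertia), with deterministic label
  semantics: highest-CTmin centroid = warm-adapted, lowest =
  cold-adapted; of the remaining two, higher CTmax = heat-tolerant,
  lower = heat-sensitive.
* **Density contours.**  The 95% iso-density contour polygons of the
  same grid KDE; the enclosed area equals a single-repeat,
  full-richness hypervolume by construction (shared code path).

## Climate metrics

From half-hourly logger series: annual mean (mean of daily means), DTR
(mean of daily max − daily min), STR (mean daily max of the warmest
month − mean daily min of the coldest month, months ranked by monthly
mean temperature, ties to the earliest calendar month).  Metrics are
invariant to record order.

## Synthetic assemblages

`generate_synthetic_assemblages` emulates the *shape* of a multi-site
field campaign: 9 sites along a 12–28 °C gradient, 20–100 species per
site drawn from site-specific bivariate normals in (CTmin, TTrange)
with CTmin center (+0.8 °C/°C) and CTmin SD (+0.25 °C/°C) increasing
with site temperature, CTmin–TTrange correlation −0.3, and shifted-
Poisson specimen counts (mean 8).  It deliberately contains a known
positive dispersion→hypervolume gradient so the analysis pipeline can
be tested for parameter recovery.  It does not emulate phylogenetic
structure, detection bias, or measurement error in the thermal limits,
so recovering the gradient shows the *analytics* work, not that any
field inference would be unconfounded.

## Numerical choices and degenerate inputs

Tables with fewer than 3 distinct trait points are degenerate:
hypervolume 0 with a flag, contouring and classification raise.  Levels
whose replicates all go extinct yield NaN responses and are excluded
from trend fits.  KDE grid mass is self-normalized (it sums to 1 within
~2% at default resolution).  The equal-area constraint is exact to
quadrature tolerance 1e−5.  The warming-limit peak is read from level
means smoothed with a centered 3-level moving average, which
stabilizes the argmax against replicate noise.

## What passing tests do and do not show

The simulation reproduces, at the scales exercised in the tests: the
decline of mean TTrange and the rise of richness, total abundance and
mean lifespan with mean temperature up to the productivity optimum; the
collapse beyond it (the hypervolume peak sits at 29–30 °C for most
seeds); the shift toward generalists (higher mean TTrange) under
long-term variability; the constant-productivity null; and sign
agreement between the immigration/mutation and constrained/relaxed
scenario pairs.  Several quantities do *not* reproduce robustly under
the default rates, and their tests are expected to fail: the emergent
hypervolume–temperature trend in the rising regime is positive but
weak relative to assembly stochasticity (OLS R² across an 11-level
sweep is typically ~0.2, not ~0.9, even though a deterministic
viable-wedge calculation of the same mechanism gives R² > 0.95);
TTrange-SD and strategy-ratio trends flip sign between seeds because
each pooled level assemblage holds only tens of species; and under
combined variability (long-term SD 2.5 with short-term SD ≥ 4) the
tolerance-width prior cannot cover the realized temperature span, so
assemblages thin out and the hypervolume acquires a genuine negative
short-term-variability trend instead of a null.  All of these are
statements about this model's dynamics under the default rates; none
of them are evidence about moths.

## Known limitations

* No spatial structure, age structure, plasticity, or within-species
  trait variance; speciation (mutation mode) changes traits only at
  arrival.
* The TPC shape is symmetric; empirical curves are left-skewed.
* Exact replication of the R `hypervolume`/`ks` estimators (including
  the "samse" pilot bandwidth) is out of scope; the HDR-area estimator
  here is self-contained and validated against the closed-form Gaussian
  case.
* Hypervolumes are 2-D only.
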