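# thermassembly

Eco-evolutionary simulation and trait-space analytics for the assembly
of thermal-limit traits (CTmin, CTmax) in ectotherm communities.

Community ecologists have three competing explanations for why some
assemblages hold a wider variety of thermal strategies than others: the
**favorability hypothesis** (warm, productive environments relax
environmental filtering and support more strategies), the **climatic
variability hypothesis** (seasonal variation selects for broad-tolerance
generalists and compresses trait diversity), and the **short-term
variability hypothesis** (sub-generation fluctuation favors specialists
through transient windows).  `thermassembly` implements an
individual-based model in which these mechanisms can be switched on,
swept, and compared, plus the assemblage-level analytics needed to put
model output and field trait tables on the same footing.

## The model in brief

* Temperature is hierarchical: block means ~ N(T̄, σ²_long) redrawn
  every `t_span` steps, per-step noise ~ N(0, σ²_short); a sine mode
  with matched long-term SD is available.
* Productivity is a tent function of temperature peaking at 30 °C.  It
  sets the carrying capacity K, scales fecundity, and its inverse
  scales all mortality (resource scarcity sharpens the environmental
  filter; benign environments relax it).
* Every species has a thermal performance curve
  `P(T) = 6h·u(1−u)`, `u = (T−CTmin)/(CTmax−CTmin)`, zero outside the
  critical limits.  By default all curves share total area A₀
  (`h = A₀/width`): narrow specialists peak high, wide generalists low.
* Each step: performance-dependent mortality → immigration (or
  mutation-driven speciation) → Poisson reproduction damped by
  niche-local crowding (MacArthur overlap of the performance curves) →
  lottery recruitment with weights ∝ performance × abundance.
* Assemblage analytics: pooled z-scoring of (CTmin, CTmax); weighted
  Gaussian-KDE **hypervolume** = area of the 95% highest-density region,
  averaged over 100 random 20-species subsamples; TTrange
  (CTmax − CTmin) mean and SD; k-means classification into
  warm-adapted / heat-tolerant / cold-adapted / heat-sensitive
  strategies; OLS trend summaries (β, 95% CI, p, R²).

See `docs/methods.md` for the full model description, parameter table
and design rationale.

## Worked example

```python
import numpy as np
from thermassembly import (
    EnvironmentConfig, SimulationConfig, SweepSpec, run_sweep,
)

spec = SweepSpec(
    parameter="t_mean",
    levels=(14, 16, 18, 20, 22, 24),
    base=SimulationConfig(
        env=EnvironmentConfig(sigma_short=2.5, sigma_long=0.0),
        n_steps=10_000,
    ),
    replicates=8,
    master_seed=5,
)
res = run_sweep(spec)
print(res.level_data[["hypervolume", "ttrange_mean", "ttrange_sd",
                      "richness", "total_abundance"]].round(3))
reg = res.regressions["ttrange_mean"]
print(f"mean TTrange slope {reg.beta:.2f} degC/degC, "
      f"95% CI ({reg.ci95_low:.2f}, {reg.ci95_high:.2f}), R2={reg.r_squared:.2f}")
```

prints (seeds fixed, so these numbers are reproducible):

```
       hypervolume  ttrange_mean  ttrange_sd  richness  total_abundance
level
14           0.330        15.394       6.906       5.0            536.0
16           0.544        12.105       5.025      12.0           5033.0
18           0.596        10.638       4.135      10.0           6218.0
20           0.510         9.915       4.222      12.0           6640.0
22           0.547         7.642       2.816      12.0          10441.0
24           0.542         9.353       4.531      15.0           9552.0
mean TTrange slope -0.63 degC/degC, 95% CI (-1.09, -0.18), R2=0.79
```

Reading it: warming from 14 to 24 °C raises total abundance and species
richness (the favorability/more-individuals channel) while the mean
thermal tolerance range *shrinks* — warm assemblages gain specialists —
with a significantly negative trend.  Each level's assemblage is the
pool of its replicate runs; the hypervolume column is the 95%
kernel-density area of that pooled trait cloud in standardized units².

The `examples/` directory holds one short script per capability
(temperature process, single simulation, hypervolume estimation,
gradient sweep, scenario contrast, synthetic multi-site pipeline,
climate metrics), each printing a few annotated numbers.

A thin CLI wraps the same functions:

```bash
thermassembly simulate --seed 1 --out runs/demo
thermassembly sweep --parameter t_mean --levels 14,16,18,20,22,24 --out runs/sweep
thermassembly metrics --log logger.csv
thermassembly synth --seed 1 --out fixtures/
```

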