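"""Run one eco-evolutionary simulation and inspect the final assemblage.

A benign mid-gradient environment (18 degC, short-term SD 2.5) filters
the uniform immigrant stream down to a few coexisting strategies whose
tolerance ranges bracket the realized temperatures.
"""

from thermassembly import EnvironmentConfig, SimulationConfig, run_simulation

cfg = SimulationConfig(
    env=EnvironmentConfig(t_mean=18.0, sigma_short=2.5, sigma_long=0.0),
    n_steps=20_000,
    seed=3,
)
rec = run_simulation(cfg)

print(f"carrying capacity K = {rec.capacity}")
print(f"final richness      = {rec.final_richness}")
print(f"total abundance     = {int(rec.trait_table['n'].sum())}")
print(f"mean species lifespan = {rec.mean_lifespan:.0f} steps")
print("\nfinal assemblage (CTmin, CTmax, abundance):")
tab = rec.trait_table.sort_values("n", ascending=False)
for row in tab.itertuples():
    print(f"  {row.ctmin_c:6.1f}  {row.ctmax_c:6.1f}  {int(row.n):5d}")
# Surviving ranges cover the temperature bulk (18 +/- ~5 degC); species
# that never overlap it die at the scarcity-scaled outside rate within
# a few steps of arriving.
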