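"""Generate a complete synthetic study scenario and describe it.

Builds gridded meteorology, a birch landscape (tree cover and heat-sum
threshold maps), a station network, a "true" seasonal release correction
field, and noisy daily observations of the resulting pollen season.
"""

import numpy as np

from pollenda import GridSpec, NoiseConfig, RunConfig, build_year_scenario

cfg = RunConfig(
    grid=GridSpec(0.0, 10.0, 46.0, 54.0, 10, 8),
    n_stations=10,
    station_layout="stratified",
    noise=NoiseConfig(lognormal_sigma=0.3, missing_prob=0.05),
    seed=1,
)
scen = build_year_scenario(cfg, year=2000)

print(f"meteo: {len(scen.meteo.times)} daily steps from {scen.meteo.times[0].date()}")
print(f"  temperature range  {scen.meteo.T.min() - 273.15:6.1f} .. "
      f"{scen.meteo.T.max() - 273.15:6.1f} C")
print(f"  wind speed mean    {scen.meteo.U.mean():6.1f} m/s")
print(f"landscape: tree cover mean {scen.landscape.phi.mean():.3f}, "
      f"flowering-start threshold {scen.landscape.H_fs.min():.0f} .. "
      f"{scen.landscape.H_fs.max():.0f} K day")
print(f"truth correction field xi in [{scen.xi_true.min():.2f}, {scen.xi_true.max():.2f}]")
print(f"stations: {len(scen.stations)}, "
      f"{int(scen.stations.table.isolated.sum())} isolated")

one = scen.obs["ST000"]
in_season = one["value"][one["valid"]]
print(f"station ST000: {int(one['valid'].sum())} valid days, "
      f"season total {in_season.sum():.0f} pollen day/m3, "
      f"peak {in_season.max():.0f} grains/m3")
# The season total (SPIn) is the quantity the assimilation constrains;
# daily peaks carry the short-term weather signal the inversion ignores.
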