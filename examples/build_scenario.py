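"""Collapse a weather-generator ensemble into one scenario series.

Generates a 10-member, one-year synthetic ensemble, averages every element
except precipitation day by day, and rebuilds precipitation from the
cross-member mean monthly totals and rain-day counts, distributed randomly
within each month. Prints the conservation check the procedure guarantees.
"""

import numpy as np

from grassflux.synth import WeatherGenParams, gen_ensemble
from grassflux.weather import aggregate_ensemble

ensemble = gen_ensemble(WeatherGenParams(), years=1, n_members=10, seed=7)
scenario = aggregate_ensemble(ensemble, seed=7)

jan = scenario.data["date"].dt.month == 1
member_jan = [m.data.loc[jan.to_numpy(), "precip_mm"].sum() for m in ensemble.members]
print(f"member January totals (mm): {np.round(member_jan, 1)}")
print(f"cross-member mean:          {np.mean(member_jan):.3f} mm")
print(f"aggregated January total:   {scenario.data.loc[jan, 'precip_mm'].sum():.3f} mm")
print(f"aggregated annual precip:   {scenario.data['precip_mm'].sum():.0f} mm")
wet = (scenario.data.loc[jan, "precip_mm"] > 0.2).sum()
print(f"January wet days in scenario: {wet}")
# The aggregated monthly total equals the cross-member mean exactly; the
# wet-day count is the rounded mean of the member counts.
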