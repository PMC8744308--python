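"""The two-step floating catchment area (2SFCA) measure on a tiny instance.

Step 1 divides each site's dollars by the population that can reach it
within the 30-minute walkshed (R_j). Step 2 sums, for each block, the
ratios of the sites it can reach (A_i, dollars per person within reach).
"""

import fundshed as fs
from fundshed.travel import TravelTimeMatrix

matrix = TravelTimeMatrix(
    origin_ids=["b1", "b2", "b3"],
    dest_ids=["s1", "s2"],
    minutes=[[10.0, 40.0], [20.0, 20.0], [35.0, 15.0]],
)
populations = {"b1": 10, "b2": 20, "b3": 30}
supply = {"s1": 120.0, "s2": 60.0}

ratios = fs.supply_ratio(supply, matrix, populations, T=30.0)
for r in ratios:
    print(f"{r.site_id}: R = {r.ratio:.1f} $/person "
          f"({r.reachable_population} people within 30 min)")

access = fs.access_2sfca(ratios, matrix, T=30.0)
for b in access:
    print(f"{b.block_id}: A = {b.a_2sfca:.1f} $/person, nearest site "
          f"{b.nearest_minutes:.0f} min, {b.n_within} site(s) in walkshed")

# conservation: population-weighted access equals the dollars supplied
total = sum(populations[b.block_id] * b.a_2sfca for b in access)
print(f"sum_i D_i * A_i = {total:.0f} = total supply "
      f"{sum(supply.values()):.0f} (dollars are conserved)")
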