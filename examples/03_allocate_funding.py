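"""Divide contract dollars across delivery sites and compare the two
container views.

A $300k contract to a provider with a headquarters in area A and two
satellites in area B: the HQ-only view puts every dollar in A; the
site-level view splits it equally among the three delivery sites.
"""

import fundshed as fs
from fundshed.types import Contract, ProgramType, ServiceSite

sites = [
    ServiceSite("p1_hq", "p1", 0, is_headquarter=True),
    ServiceSite("p1_s0", "p1", 1, is_headquarter=False),
    ServiceSite("p1_s1", "p1", 2, is_headquarter=False),
]
contract = Contract("c1", "p1", 300_000.0, ProgramType.HIV_STI)

allocs = fs.allocate_contract(contract, sites)
for a in allocs:
    print(f"  {a.site_id}: ${a.amount:,.0f}")

area_of_site = {"p1_hq": "A", "p1_s0": "B", "p1_s1": "B"}
for mode in ("hq_only", "all_sites"):
    cf = fs.container_funding(allocs, [contract], sites, area_of_site, mode,
                              area_population={"A": 5_000, "B": 20_000})
    view = {a.area_id: (a.dollars, a.dollars_per_capita) for a in cf.areas}
    print(f"{mode}: " + ", ".join(
        f"{k} ${d:,.0f} (${pc:.0f}/person)" for k, (d, pc) in view.items()))
print("-> the conventional HQ-only view misses that two thirds of the "
      "dollars are delivered in area B")
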