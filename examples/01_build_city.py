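"""Generate a synthetic city and look at its structure.

The generator builds a walkable street grid, housing blocks with
over-dispersed populations, tracts with a spatially graded hardship
profile, and providers whose headquarters cluster in low-hardship areas
while satellite sites cluster in medium/high-hardship areas.
"""

import numpy as np

import fundshed as fs

city = fs.generate_scenario(fs.preset("toytown"))

print(f"street network: {city.network.n_nodes} nodes, "
      f"{city.network.n_edges} edges")
pops = [b.population for b in city.blocks]
print(f"blocks: {len(city.blocks)}  population mean {np.mean(pops):.1f}, "
      f"variance {np.var(pops):.0f} (over-dispersed: variance >> mean)")
print(f"tracts: {len(city.tracts)}  providers: {len(city.providers)}  "
      f"sites: {len(city.sites)}")

index = fs.hardship_index({t.tract_id: t.components for t in city.tracts})
labels = fs.tercile_classify(index)
hqs = sum(s.is_headquarter for s in city.sites)
print(f"hardship index range: {min(index.values()):.1f}-"
      f"{max(index.values()):.1f}; {hqs} headquarters, "
      f"{len(city.sites) - hqs} satellites")

# headquarters should sit in low-hardship tracts far more often than
# satellites do — the placement bias the analysis is designed to expose
tract_of_node = {}
for b in city.blocks:
    tract_of_node.setdefault(b.node_id, b.tract_id)
for kind, sel in (("HQ", True), ("satellite", False)):
    sites = [s for s in city.sites if s.is_headquarter is sel]
    frac = np.mean([labels[tract_of_node[s.node_id]] == "low" for s in sites])
    print(f"{kind} sites in low-hardship tracts: {100 * frac:.0f}%")
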