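"""Walking times and catchments on a small street network.

Times are network shortest paths at 3 mph (80.4672 m/min); a 30-minute
catchment keeps pairs strictly under the threshold.
"""

import fundshed as fs

net = fs.generate_street_network(rows=5, cols=5, edge_length_m=804.672,
                                 removal_prob=0.0, seed=0)
print(f"5x5 grid, half-mile edges: {net.n_nodes} nodes, {net.n_edges} edges")

# one corner to the other: 8 edges of half a mile = 4 miles at 3 mph
t = fs.travel_time(net, 0, 24)
print(f"corner to corner: {t:.0f} minutes (4 miles at 3 mph = 80 min)")

m = fs.travel_time_matrix(net, [0, 12, 24], [0, 12, 24])
print("times between corners and center (minutes):")
print(m.minutes.round(1))

by_dest, by_origin = fs.catchment_members(m, T=30.0)
print(f"nodes within a 30-min walk of the center: {sorted(by_dest[12])} "
      "(the corners are 40 min away, outside the walkshed)")
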