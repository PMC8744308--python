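# fundshed

Walkable-catchment equity analysis of contracted health-service funding.

## The problem

City health departments deliver much of their programming through
contracts with nonprofit providers ("delegate agencies"). Open contracts
data typically record only each provider's **headquarters** address, so
the standard way of answering *"how much funding goes to this
neighborhood?"* — summing contract amounts inside an area boundary, the
**container approach** — silently attributes every dollar to the HQ
location. When headquarters cluster in affluent districts while services
are actually delivered at **satellite sites** in higher-hardship
neighborhoods, the container view gets the equity picture backwards.

`fundshed` is a library for researchers, health planners and contract
managers who want to measure whether contracted service *dollars* are
within walkable reach of high-need neighborhoods. It:

* allocates contract dollars to actual delivery sites (recorded shares,
  or an equal split over the headquarters and all satellites);
* computes walking times between housing-block centroids and sites over
  a street network (3 mph, network shortest paths);
* derives three block-level access measures, including funded access per
  capita by the two-step floating catchment area method;
* classifies census tracts by a six-component hardship index and
  cross-tabulates need terciles against funded-access terciles;
* generates fully synthetic cities with the relevant spatial structure,
  so the whole pipeline is testable without any restricted data.

## The access model

Walking time `t_ij` between block `i` and site `j` is the network
shortest path divided by the walking speed (3 mph = 80.4672 m/min). A
site's catchment at threshold `T` (default 30 min) contains the blocks
with `t_ij < T` (strict).

**2SFCA.** Step one computes a supply-demand ratio at each site `j` with
allocated dollars `S_j`:

    R_j = S_j / Σ_i D_i · I(t_ij < T)

where `D_i` is the population of block `i`. Step two sums the ratios
reachable from each block:

    A_i = Σ_j R_j · I(t_ij < T)

`A_i` is in dollars per person within walkable reach. With these binary
weights the measure conserves dollars exactly:
`Σ_i D_i·A_i = Σ_j S_j` over sites whose catchment contains at least one
populated block. The two companion proximity measures are the time to
the nearest site and the number of sites inside the walkshed.

**Hardship.** Each tract's crowded housing, poverty, unemployment, low
education, dependents (all %) and per-capita income ($) are min-max
scaled to 0–100 across tracts, income inverted, and averaged; tracts are
split into low/medium/high terciles of (near-)equal size.

## Worked example

`examples/04_funded_access.py` runs the two 2SFCA steps on a tiny
instance — three blocks (populations 10, 20, 30), two sites ($120 and
$60 of allocated funding), walking times `b1→(10, 40)`, `b2→(20, 20)`,
`b3→(35, 15)` minutes, `T = 30`:

```
s1: R = 4.0 $/person (30 people within 30 min)
s2: R = 1.2 $/person (50 people within 30 min)
b1: A = 4.0 $/person, nearest site 10 min, 1 site(s) in walkshed
b2: A = 5.2 $/person, nearest site 20 min, 2 site(s) in walkshed
b3: A = 1.2 $/person, nearest site 15 min, 1 site(s) in walkshed
sum_i D_i * A_i = 180 = total supply 180 (dollars are conserved)
```

Site `s1` is reachable by 10 + 20 = 30 people, so each carries a $4.0
claim on it; block `b2` reaches both sites and accumulates
4.0 + 1.2 = 5.2 $/person.

`examples/05_equity_pipeline.py` runs the full pipeline on a small
synthetic city whose headquarters sit in low-hardship tracts. The
container comparison it prints:

```
funding share by hardship tercile (%):
          hq_only  all_sites
low          97.5       29.7
medium        2.5       21.6
high          0.0       48.7
```

Counting whole contracts at headquarters puts 97.5% of dollars in
low-hardship areas; following the dollars to the delivery sites reverses
the picture, with 70.3% reaching medium/high-hardship areas.

The other examples cover city generation (`01`), walking times and
catchments (`02`), and dollar allocation (`03`). A thin CLI mirrors the
stages: `fundshed simulate | travel | allocate | access | classify |
run | report` (see `fundshed --help`).

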