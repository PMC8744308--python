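# Methods

## Scope and design

`fundshed` measures *potential* spatial access to contracted service
funding: proximity-based opportunity, not observed utilization. The
pipeline has five stages — synthetic-city generation, network travel
times, dollar allocation to sites, block-level access measures, and
tract-level equity classification — each usable on its own through the
library API and exercised end-to-end by `run_pipeline`.

## Travel times and catchments

* The street network is an undirected graph with planar coordinates in
  meters and strictly positive edge lengths; pedestrian travel has no
  one-way restrictions. Travel time is the network shortest path divided
  by the walking speed, with the conversion fixed at 1 mile = 1609.344 m
  (3 mph = 80.4672 m/min). Times are carried as floating minutes and
  never rounded before thresholding.
* The matrix is computed with one single-source Dijkstra sweep per
  distinct origin node, so many blocks sharing a street node cost one
  sweep.
* Catchments use the **strict** indicator `t < T`; a pair exactly at the
  threshold is outside. This is a knife-edge convention with measure
  zero under continuous times; a `≤` variant for sensitivity analysis
  amounts to passing `T + ε`.
* Unreachable pairs are represented as `inf` plus an explicit
  reachability mask — never a large sentinel time that could leak
  through a threshold.
* External point data are snapped to the nearest node by Euclidean
  distance, ties to the smallest node id. Synthetic blocks and sites sit
  exactly on network nodes, isolating travel-time logic from snapping
  error.

## Dollar allocation

* Contracts flagged citywide, or whose provider has no delivery sites,
  are excluded (logged per exclusion). In-scope dollars are conserved
  through every later stage; conservation is asserted in tests to 1e-6
  relative tolerance or better.
* With recorded site shares the amount is split proportionally (shares
  must sum to 1 within 1e-9). Without shares it is split equally over
  the headquarters and all satellites. `hq_delivers=False` restricts the
  equal split to satellites and emits an explicit $0 allocation for the
  HQ; the default is `True` because service delivery at headquarters
  cannot generally be ruled out from contracts data alone.
* The container aggregation has two modes: `hq_only` attributes each
  contract's full amount to the headquarters' area (the open-data
  convention) and `all_sites` follows the site-level allocations. Sites
  that fall in no area are skipped with a warning count carried in the
  result.
* Amounts are carried as floats throughout; all sums here are short
  (hundreds of terms), so accumulated rounding stays far below the
  1e-6-dollar conservation tolerance. Rounding to whole dollars and
  one-decimal percentages happens only in the report layer.

## Access measures

* 2SFCA with binary (sharp) catchment weights exactly as defined — no
  distance decay, no gravity kernel. Demand `D_i` is total block
  population; a per-program analysis filters the supply side only. An
  optional alternative demand column (e.g. a target-population proxy)
  can be passed as `block_populations`.
* Sites whose catchment contains no populated block get `R_j = 0` with a
  `zero_demand` flag rather than a division error; the conservation
  identity `Σ D_i A_i = Σ S_j` then holds exactly over unflagged sites.
* **Non-monotonicity in T.** `n_within` and `percent_with_access` are
  non-decreasing in the threshold, and so is the population-weighted
  total `Σ D_i A_i`. Individual `A_i` values are *not*: enlarging the
  walkshed adds population to site denominators and can dilute nearby
  blocks' access (a one-site city with a small near block and a large
  far block shows `A_near` dropping from `S/D_near` to
  `S/(D_near+D_far)`). This is a property of the method, not an
  implementation artifact; on the default synthetic city roughly half of
  the block-level transitions between T = 10/20/30/40 decrease. The test
  suite documents the counterexample and asserts monotonicity only for
  the quantities that possess it.

## Hardship index and classification

* The index is the mean of the six components after min-max scaling to
  0–100 across tracts, with per-capita income inverted. This bounded
  construction is a deliberate, documented default — agencies compute
  hardship indices in several ways, and precomputed index values can be
  supplied instead by skipping `hardship_index`. A component constant
  across tracts contributes 0 after scaling and triggers a warning.
* Terciles are rank-based with sizes differing by at most one
  (remainders fill the lower groups first) and ties broken by stable
  insertion order, making the classification invariant under strictly
  monotone transforms.
* Tract aggregation defaults to unweighted block means, with population
  weighting available; blocks that can reach no site are excluded from
  the nearest-minutes mean and counted. Spending terciles are computed
  on the tract-mean 2SFCA value.

## The synthetic-city generator

The generator emulates the statistical structure the analysis needs,
not any real geography:

* **Network**: a rows × cols grid lattice with connectivity-preserving
  random edge thinning — the simplest structure with shortest-path
  heterogeneity. Real networks load from GeoJSON.
* **Blocks**: placed uniformly on nodes, populations negative binomial
  with mean `pop_mean` and variance `mean + mean²/dispersion`
  (over-dispersed counts; defaults mean 60, dispersion 2). Blocks are
  ordered along a diagonal spatial sweep so the contiguous-in-index
  tract grouping is spatially coherent.
* **Tracts**: hardship components are monotone functions of a latent
  position `clip(g·(s−½) + ½ + ε, 0, 1)` where `s` is the tract's
  normalized spatial coordinate, `g` the gradient strength and `ε`
  Gaussian noise (sd 0.15) drawn independently per component; income
  runs opposite to the five adverse components. `g = 0` gives no spatial
  autocorrelation; `g = 1` with zero noise gives a strict gradient.
* **Providers**: each has one HQ, drawn from the low-hardship stratum
  with probability `hq_low_hardship_bias` (default 0.9), and a
  Poisson(3) number of satellites drawn from the medium/high strata with
  probability `satellite_high_hardship_bias` (default 0.8, weighted 0.7
  toward the high stratum so high-hardship areas lead and medium areas
  trail in funded access, the placement pattern the preset is meant to
  exhibit). One contract per provider: lognormal amount (median $200k,
  σ = 1, putting a 150-provider city's total near $50M), program type
  from a 70/16/6/5/3 mix across HIV/STI, health promotion, MICAH, health
  protection and chronic disease, Dirichlet site shares with probability
  0.3, citywide flag with probability 0.15.
* All randomness flows from one `ScenarioConfig.seed` through spawned
  numpy `SeedSequence`s, so runs are bit-reproducible and stages are
  individually reproducible.

What the generator does **not** emulate: real street topology and
density gradients, geocoding error, correlation between block population
and hardship, multi-contract providers, intermediary (pass-through)
funding, or multi-year dynamics. Tests passing on synthetic cities show
the *method* behaves correctly — conservation, reversal under placement
bias, classification contracts — not that any real city exhibits a
particular funding pattern.

## Problem sizes

The default `hq_downtown` study conditions use a 40×40 grid, 4,800
blocks, 600 tracts and 150 providers — large enough for stable tercile
summaries while a full pipeline run (dominated by ~1,600 Dijkstra
sweeps and the 4,800 × ~520 matrix) completes in well under a minute on
one CPU. `toytown` (360 blocks, 60 tracts) serves examples and quick
checks.

## Known limitations

* Block-to-site times only; block-to-block isochrones are out of scope.
* Binary catchments make results sensitive to the threshold choice near
  `T`; no distance-decay variant is provided.
* The hardship construction is one reasonable default among several; it
  is not calibrated to any agency's published index values.
* Funding shares are descriptive; the package performs no statistical
  inference on group differences.
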