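# Methods

## Model

The package measures *potential spatial accessibility*: what the geography and
the supply pattern make possible, not what people actually do. Its assumptions
are the standard ones of floating-catchment accessibility work, made explicit:

- Demand sits at residential-area centroids; everyone in an area shares one
  location and travels by car.
- People use the nearest facility for demand estimation (the Voronoi pressure
  step) but are exposed to every facility inside their potential accessibility
  zone for the distance step.
- A facility's capacity is proportional to its professional head count;
  part-time practice, opening hours, and reputation are invisible.
- Demand is raw population; no adjustment for age or sex structure.

The computation per facility type: nearest-facility travel time per area →
per-IRIS catchment radius (the max over the IRIS's areas — the radius that
guarantees every area in the unit can reach at least one facility) → ZAP
membership (all candidates within the radius, boundary inclusive) → facility
pressure by travel-cost Voronoi assignment → pressure-weighted mean travel
time (PAD). PADs are standardized per type by the rank-based inverse-normal
transform and combined linearly with a negative sign, so the composite rises
as weighted distances shrink.

### Why rank-normal rather than z-scores

Travel-time distributions are strongly right-skewed; a linear z-score of
skewed inputs is "centered and reduced" but nowhere near normal, and a single
remote area would dominate the combined index. The Blom transform
`Φ⁻¹((r − 3/8)/(n + 1/4))` on midranks delivers an almost exactly
standard-normal score whatever the input shape, is strictly monotone (so
per-type rankings survive), and makes equal weights across types meaningful
because every component is on the same scale. Plain z-scoring remains
available (`normalization="zscore"`) for sensitivity analysis.

### The pressure-weight direction

The weight applied to each (area, facility) travel time reflects facility
availability. Two readings are defensible: weight by pressure (the mean is
pulled toward the facilities carrying the demand load — the default) or by
inverse pressure (pulled toward facilities with spare capacity). Both are
implemented behind `weight_mode`; every invariant (bounds between min and max
member cost, scale-equivariance in costs, invariance to uniform pressure
rescaling) holds under either, and the planted-gradient recovery test is run
under both. In inverse mode a zero-pressure facility would get infinite
weight; its weight is computed from the smallest positive member pressure
instead, and an all-zero member set falls back to the unweighted mean — the
same fallback used when the total weight vanishes in the default mode.

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| `speed_kmh` (euclidean metric) | km/h | 50 | mixed rural/peri-urban driving speed |
| `max_snap_m` | m | 5 000 | beyond this, "nearest node" stops being a credible access point; error rather than silently route from the wrong place |
| `weight_mode` | — | `pressure` | see above |
| `normalization` | — | `rank_normal` | see above |
| `sign_convention` | — | −1 | larger index = better access; decile 1 = best |
| combination weights | — | 1 per type | no evidence for any other weighting; explicit config |
| ZAP boundary | — | inclusive (≤) | the facility that defines the radius must belong to the zone it defines |
| nearest-facility ties | — | smallest facility id | any deterministic rule works; this one is reproducible across runs and platforms |

## Numerical choices

- **Deciles by exact rank arithmetic.** Boundaries sit at the empirical
  quantiles 0.1…0.9 (linear interpolation). Rather than comparing floats
  against interpolated cut values — where a value lying exactly on a boundary
  can flip with one ulp of rounding — labels are derived from integer rank
  positions: an element is below the boundary at position `(n−1)(10−j)/10`
  iff its max-tie rank is below `⌊·⌋ + [remainder > 0]`. Ties therefore share
  the better label, constant vectors collapse to one class with a warning, and
  `n < 10` is an error at the area level. Aggregated levels with fewer than 10
  units get no deciles (missing, with a warning) and are excluded from
  agreement tables — a decile of seven communes is not meaningful.
- **Shortest paths.** Dijkstra from every distinct snapped origin node;
  both travel time and road distance are accumulated along the same
  impedance-optimal path. Parallel edges keep the smaller impedance;
  edges are bidirectional unless a `oneway` flag is set. Snap legs (point →
  nearest node) cost zero: with a reasonably dense network the access leg is
  small, and adding it would require a walking-speed model the data cannot
  support.
- **Zero-weight PADs.** If every member pressure is zero (nobody's nearest
  facility), the PAD falls back to the unweighted mean of member costs,
  preserving `min ≤ PAD ≤ max`.
- **Validation is total.** Readers raise typed errors (schema, coordinate
  system, network, unreachable) rather than dropping rows; coordinates that
  fit inside ±180/±90 are refused as lon/lat because all distance math assumes
  planar meters.
- **Determinism.** No stage uses randomness; reruns of the pipeline on the
  same inputs are byte-identical (manifests contain config, version, and input
  checksums, never timestamps).

## The synthetic generator

`scale_access.synthetic` emulates the *structure* of the real inputs: many
small residential areas with lognormal populations (median ≈ 55 persons per
block, heavy right tail), facility types at very different densities (tens of
GPs per region, a handful of emergency departments), a connected planar road
network, and a nested rectangular partition region ⊃ department ⊃ commune ⊃
IRIS with a consistent adjacency table. Grid-network edge speeds are jittered
±25% around `speed_kmh`: real road links are heterogeneous, and a perfectly
uniform grid would manufacture exact travel-time ties between unrelated pairs
that no real network exhibits.

What it does **not** emulate: real settlement geometry (coastlines, valleys,
anisotropic sprawl), realistic road topology (hierarchy, one-ways, dead ends),
facility co-location in medical centers, or any correlation between population
density and professional head counts. Passing tests on this geography
demonstrate that the *computation* is correct and its invariants hold — not
that the index is a validated exposure measure for any real territory.

The gradient fixture plants a dense, facility-rich city cluster against a
sparse rural margin with few facilities and labels every area with its ground
truth, so end-to-end recovery of the urban > rural ordering can be asserted
across seeds and weight modes.

## Problem sizes

The default test suite runs on fixtures of ≤ 50 areas × ≤ 10 facilities
(oracle comparisons), ≤ 8-node graphs (exhaustive path enumeration), and
120–400-area geographies for pipeline-level properties. The reproduction
script uses a 2,000-area, ~220-facility, 400-node-network geography for the
main run and ten 270-area gradient fixtures — sizes at which every quantity
is recomputed from scratch in well under a minute on one core while still
populating ~50 IRIS for the aggregation-agreement statistics.

## Known limitations

- Car-only travel, free-flow times; no time-of-day congestion, public
  transport, or walking.
- Home-to-facility trips only; commuter access from workplaces is ignored.
- Head-count capacity proxy; no full-time-equivalent correction.
- The per-IRIS radius is computed per facility type. A single global radius
  per IRIS across all types is a defensible alternative reading; it is not
  currently implemented as a switch.
- Pressure is computed on each area's full candidate set before ZAP
  restriction; computing it after restriction would couple the two steps and
  is not offered.
- Region chunking changes results only insofar as it restricts candidate
  sets; a facility just beyond a neighboring department is invisible to the
  proximity range by construction, exactly as in region-wise processing of a
  national run.
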