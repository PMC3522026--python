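# Methods

## Model

The access score of dissemination block *i* is the sum over accessible
physician locations of supply divided by demand-weighted impedance,

A_i = Σ_j S_j / (D_j · f(t_ij)),  D_j = Σ_k P_k / f(t_kj),

a gravity-type measure: each location contributes its physician count
*S_j*, discounted by how contested it is (*D_j*, in population
equivalents) and how far it is (*f*). Both sums draw their pairs from a
single Origin–Destination Cost Matrix (ODCM), so the same origin set and
cutoff govern demand and access. This gives the measure a conservation
property used heavily in the tests: when every block is an eligible
origin and every physician reachable, Σ_i P_i·A_i = Σ_j S_j exactly —
the scores distribute the total physician supply over the population.

The impedance is piecewise linear: f = 1 up to 10 minutes, t/10 between
10 and 120 minutes (continuous at both joints: f(10) = 1, f(120) = 12),
and infinite past 120 minutes. It is returned as IEEE `inf`, whose
reciprocal is exactly 0, so beyond-cutoff pairs contribute nothing
without special-casing. Travel time 0 (a block and physician snapped to
the same node) uses the flat branch. The 10-minute flat radius encodes
"no meaningful penalty within a short urban drive"; the 120-minute
cutoff a subjective but defensible ceiling on a reasonable one-way drive
to a family physician; both are parameters (`cutoff_min` in the ODCM,
constants in `gravity`).

## Network and eligibility

Road segments (polyline, length m, speed km/h, direction ∈ {both,
forward, reverse}) become a directed graph whose nodes are polyline
vertices; each vertex-to-vertex arc costs the segment's traversal time
(length/1000/speed·60 minutes) apportioned by Euclidean sub-length, so a
declared length longer than the chord (curvature) inflates all sub-edges
proportionally. Endpoints within 1 mm are one node; parallel arcs keep
the fastest. Shortest paths are Dijkstra (networkx) with the cutoff
applied during the search; ties in path length are irrelevant because
only the time is used.

Eligibility: a block is an origin iff its density strictly exceeds 1
person per 5 km² (0.2/km²) **and** its centroid is within 2500 m
(inclusive) of a graph node; a physician location is a destination iff
it is within 2500 m of a node. Density is tested first, so a sparse and
remote block reports the density reason. Excluded blocks get no score —
they are a separate categorical colour on maps — and, by default, do not
contribute population to demand either (one origin set for both
equations). The alternative reading — filtered blocks still compete for
physicians — is available as `score_region(..., demand_includes_filtered=True)`;
it can only dilute scores, never raise them.

Two deliberate simplifications around snapping: the off-road leg from a
centroid to its snap node costs zero minutes (the 2500 m rule defines an
eligibility radius, not a priced access leg), and snapping targets graph
*nodes*, not interpolated points on edge interiors, which keeps the graph
static; with vertex spacing of 1–3 km in the synthetic road builders the
induced time error is bounded by the spacing over the speed (≤ ~4 min).
Both decisions are recorded in the ODCM metadata. Equidistant snap
candidates resolve to the lexicographically smallest node id (node ids
are quantized coordinate pairs), making snapping deterministic.

Coordinates must be planar projected meters. Files declaring a
geographic CRS (WGS84/CRS84/EPSG:4326) are rejected rather than
reprojected; a coordinate-range heuristic cannot reliably distinguish a
small region in meters from degrees, so the declared CRS is the binding
check and the reader otherwise trusts the input (with a free-text
`crs_note` carried on the region).

## Classification

Mapping classes come from Jenks natural breaks: the contiguous partition
of the sorted scores into k = 5 classes minimizing within-class sum of
squared deviations. It is implemented as an exact dynamic program over
the distinct values weighted by multiplicity (O(k·n²)), not the iterative
reallocation heuristic, so small instances agree exactly with exhaustive
enumeration and equal values can never straddle a class boundary. Breaks
are the class maxima; membership uses inclusive upper bounds (a value on
a break belongs to the lower class). Zero scores are excluded from break
computation: no-access blocks are a categorical outcome, not the low end
of the gradient, mirroring the grey/cream map convention. If fewer than
k distinct positive scores exist, k is reduced with a warning. Breaks
are computed per surface (one region at a time).

## Synthetic regions

The generator emulates the anatomy of the real inputs: block centroids
with heavy-tailed populations (lognormal cores, sparse rural tail, a
sliver of deliberately below-threshold blocks to exercise the exclusion
paths), physicians placed preferentially in population hubs with supply
1 + Poisson(2) (mostly small practices), and roads whose lengths come
from actual generated geometry with class-based speeds (arterial
80 km/h, local 50 km/h by default) so travel times are internally
consistent. One `SeedSequence` per region is split into layout, block,
and physician substreams, so identical spec+seed is byte-identical
output and adding blocks does not reshuffle physician placement.

Pattern geometry, chosen once as plausible Canadian-scale settings:

- `urban_gradient` (preset `gradient_metropolis`, 120 km extent, 260
  blocks, 12 locations): one dominant core plus two secondary towns on a
  3 km road grid; corner-to-center times reach ~90–120 min, so impedance
  spans most of its range and the five Jenks classes fill.
- `binary_remote` (preset `binary_archipelago`, 300 km, 120 blocks, 3
  locations, `disconnect_fraction=1`): settlement hubs ≥ ~50 km apart,
  each a 4×4 km local grid (worst within-hub path 8 km ≈ 9.6 min at
  50 km/h — under the flat-impedance radius by construction), physicians
  in the two largest hubs, and no inter-hub roads: access is binary.
  With `disconnect_fraction < 1`, that share of non-physician hubs gets
  no arterial link road while the rest are connected.
- `corridor` (preset `corridor_province`, 220 km): one arterial spine
  with towns and local branches; physicians only in the western towns,
  so access falls along the corridor.
- `uniform` (preset `uniform_small`, 30 km): uniform blocks on a full
  grid, sized so every block is eligible and within the cutoff — the
  fixture for the conservation identity.

What the generator does **not** emulate: polygon block geometries,
topographic barriers other than road absence, traffic/weather/seasonal
speeds, non-road modes (air, water, snowmobile), and cross-border
access. Passing tests therefore demonstrate the correctness of the
scoring machinery under the stated assumptions, not calibration to any
real province.

## Numerical choices

- Scores and demand are double precision throughout; no rounding until
  the writers (coordinates to mm, scores to 12 significant decimals).
- Node coordinate quantization 1 mm; snap ties by lexicographic node id;
  Jenks ties by the smallest split index (first argmin).
- Degenerate inputs are legal: empty regions, zero-population blocks
  (excluded by the density filter), zero-extent polylines (node only, no
  arcs), physicians with no reachable population (demand 0, inert — they
  can never appear in an access sum, which is asserted).
- Validation is total and raises naming the offending feature id; it
  never silently repairs.

## Problem sizes

The test suite runs regions of 25–260 blocks on grids of ~10³ nodes
(seconds per pipeline run); oracle checks use ≤ 12-node networks against
min-plus matrix relaxation, ≤ 12-value Jenks instances against
exhaustive partition enumeration, and ≤ 5×3 gravity instances against a
naive double loop — sizes at which the independent references are exact.

## Limitations

Travel times are theoretical drive times on the coded network; the model
measures potential, not realized, access and ignores aspatial barriers.
The linear impedance is an assumption — threshold and weighted-zone
variants exist and are out of scope here. Scores are comparable within a
region run, not across regions with different supply/population totals
(the conservation identity makes scores scale as supply over
population). Centroid representation is poor for very large blocks;
that is exactly why blocks larger than 5 km² with remote centroids fall
out of the eligibility rules rather than receiving a misleading score.
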