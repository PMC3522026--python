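# graviaccess

Gravity-model scoring of **potential spatial access** to primary health
care (PHC) physicians on road networks.

Potential spatial access asks whether people *could* reach a first-contact
physician (family physician / general practitioner), given where they
live, where physicians practice, how fast the roads between them are, and
how many other people compete for the same physicians. The package is
aimed at health-services researchers and analysts who want block-level
access scores and mapping classes for a region — real or synthetic —
without a commercial GIS stack.

## The model

Each census dissemination block *i* (the smallest geography with public
population counts, represented by its centroid) receives

```
A_i = Σ_j  S_j / ( D_j · f(t_ij) )
```

where *S_j* is the number of physicians at location *j*, *t_ij* the
road-network travel time in minutes from block *i* to location *j*, and
*D_j* the impedance-weighted population competing for location *j*:

```
D_j = Σ_k  P_k / f(t_kj)
```

The travel-time impedance is piecewise linear:

```
f(t) = 1        t ≤ 10 min         (no travel penalty)
f(t) = t / 10   10 < t ≤ 120 min   (linear penalty, 1 → 12)
f(t) = ∞        t > 120 min        (no access: 1/∞ = 0)
```

A block with no physician inside the 120-minute cutoff scores exactly 0,
the floor of the measure. Travel times come from an Origin–Destination
Cost Matrix over a directed road graph (segment length, speed limit, and
one-way/two-way direction). Block centroids within 2500 m of a road and
with population density above 1 person per 5 km² are origins; physician
locations within 2500 m of a road are destinations. Scores are mapped in
5 classes by exact Jenks natural breaks, with *no access* and *excluded*
blocks kept as their own categorical colours.

## Worked example

`examples/02_score_a_small_region.py` scores a three-block region: a
block 5 minutes from a two-physician clinic, a block 40 minutes away, and
an island block with no road connection:

```
travel times (min): {('near', 'clinic'): 5.0, ('far', 'clinic'): 40.0}
demand at clinic  : 325.0 population-equivalents
block near    status=scored     access=0.006153846153846154
block far     status=scored     access=0.0015384615384615385
block island  status=no_access  access=0.0
```

Demand is `300/f(5) + 100/f(40) = 300 + 25 = 325`. The near block gets
`2/325 ≈ 0.0062` physicians per person-equivalent; the far block's share
is divided by its impedance `f(40) = 4`; the island block holds the
floor score 0.

The other examples show the impedance curve, the two qualitative regimes
on synthetic regions (a metropolitan access gradient occupying all five
Jenks classes, and a binary archipelago where 56.8 % of the population has
no road access and everyone served is within 10 minutes), Jenks
classification of a skewed score distribution, and the GeoJSON/CSV file
round trip.

## Synthetic regions

Real inputs of this kind (physician directories, census block centroids,
licensed road files) are proprietary, so `graviaccess.synthetic`
generates seeded regions with the same anatomy — clustered heavy-tailed
urban populations, sparse below-threshold blocks, physicians concentrated
in hubs, grid/radial/spine/island road topologies. Four presets
(`gradient_metropolis`, `binary_archipelago`, `corridor_province`,
`uniform_small`) are designed around documented qualitative outcomes and
drive the end-to-end tests.

## Command line

```
graviaccess simulate --preset binary_archipelago --seed 7 --out-dir region/
graviaccess odcm  --blocks region/blocks.geojson --physicians region/physicians.geojson \
                  --roads region/roads.geojson --out odcm.csv
graviaccess access --odcm odcm.csv --blocks ... --physicians ... --roads ... --out access.csv
graviaccess classify --access access.csv --k 5 --out classified.csv
graviaccess score --blocks ... --physicians ... --roads ... --out scores.geojson
```

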