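# Methods

This note records the model choices, parameter conventions and numerical
decisions behind `dolina`, and what the synthetic benchmarks do and do not
demonstrate.

## Terrain model and extraction

The input is a bare-earth elevation raster with square metric cells (the
reference configuration is 1 × 1 m), north-up, cell value = elevation at
the cell centre. Nodata cells are treated as off-map: flow may exit into
them, and depressions adjacent to them drain rather than fill.

**Depression filling** is priority-flood: cells are processed outward from
the raster boundary in elevation order, so every cell ends with a
non-ascending 8-connected path off-map and is raised minimally. An epsilon
increment (default 1e-5 m, configurable) is imposed on flats so the filled
surface routes unambiguously. Sinkhole depths and volumes are always
measured on the *original* surface, so epsilon never biases morphometry.

**Routing** is D8: each cell drains to its steepest-descent neighbour, drop
divided by centre distance (diagonals by cell_size·√2). Ties break in the
fixed order E, SE, S, SW, W, NW, N, NE, making watershed membership
deterministic. Multi-direction schemes were rejected because fractional
flow makes basin membership ambiguous.

**Watershed labelling** works on the unfilled surface. Flat regions are
resolved structurally: adjacent no-descent cells necessarily share one
elevation, so connected components of them are flats; a flat with no member
beside an equal-elevation draining cell is a pit and seeds a basin, all
other flats drain breadth-first through their equal-elevation exits. This
ordering matters — classifying flats by the labels already assigned
elsewhere misreads terraced terrain (an annulus-shaped flat above an
unresolved pit flat would become a phantom basin).

**Effluent level** is the pour-point elevation of a watershed: the minimum
over boundary (member, outside-neighbour) pairs of max(z_member,
z_outside); a member on the raster edge or beside nodata spills at its own
elevation. When the divide is locally symmetric this equals the lowest
boundary-cell elevation; at asymmetric saddles the pairwise max is
required, otherwise a pit whose member cell sits just below the divide is
assigned an effluent below its own spill and vanishes from the inventory.

**Confinement** keeps cells strictly below the effluent (cells exactly at
the effluent are excluded) in the 8-connected component containing the
basin minimum; disconnected below-level fragments re-enter the analysis at
the next iteration if they are genuine depressions.

**Ranking** repeats delineation–confinement–fill until no basin confines a
sinkhole; records found at iteration k carry rank k, and parent links are
set by footprint containment. Two consequences of this definition are easy
to miss. First, a single pit centred in a bowl is *one* rank-1 sinkhole
covering the whole bowl — extra rank levels exist only where sibling minima
share saddles. Second, once a sinkhole is filled to a pour that equals the
surrounding floor its divide disappears, so a persistent k-level hierarchy
requires sibling structure at every level.

**Karst filter.** Records shallower than 2 m or narrower than 10 m
(minimum-bounding-box width; thresholds inclusive, both configurable) are
removed as non-karst features. A record containing surviving nested
sinkholes must additionally close at least the depth threshold beyond them:
its effluent minus the minimum original elevation over its cells outside
all surviving descendants. This marginal test removes the *shadow* records
that surface noise otherwise creates — when a centimetre-deep pit sits next
to a sinkhole's spill, the next iteration re-finds the same sinkhole with a
pour a few centimetres higher, and its raw depth passes the filter even
though it adds nothing. Genuine higher-rank sinkholes close metres of
relief beyond their members and are untouched. Ranks of the survivors are
renumbered from the surviving containment hierarchy (leaf survivor = 1);
the delineation is not re-run.

## Morphometry conventions

- Hull: convex hull of the member cells' corner points (cells as unit
  squares). Perimeter is taken on this hull, *not* the raster staircase —
  the staircase inflates perimeter by ~4/π and would give a perfect disc a
  circularity of ~1.62 instead of 1.
- Area: member cell count × cell area (the measured raster region), even
  though the perimeter uses the hull. The asymmetry is deliberate: area is
  a mass-like quantity the raster measures well, perimeter is a smooth
  boundary property the raster measures badly.
- Depth: effluent level − minimum member elevation. Volume: Σ(z_max −
  z_cell)·cell_area over member cells, z_max the highest member elevation.
- Orientation: azimuth of the farthest hull-vertex pair, clockwise from
  grid north, folded to [0°, 180°); exact north–south reports 0°; ties take
  the smaller azimuth. For convex regions the farthest member-cell pair and
  the farthest hull-vertex pair coincide.
- Bounding box via shapely's oriented envelope (rotating calipers); the
  reported width/length are validated in the tests against a brute-force
  0.1°-step rotation search.
- Centroid: area centroid of the hull polygon.
- Density: quartic kernel with unit mass per point, radius default 564.2 m
  (the radius at which π r² = 1 km²), output in counts per km². Surfaces
  integrate to the point count up to edge loss.

## Statistics

- Shannon H′ uses natural logarithms; Simpson D = 1 − Σ p_i². Proportions
  are consumed as given; an optional renormalisation flag divides by their
  sum, and a Braun–Blanquet cover-class → midpoint table is provided for
  surveys recorded in classes.
- Group comparison: Levene's test (classic mean-centred variant) at
  α = 0.05 gates between a pooled t-test and Kruskal–Wallis. For more than
  two heterogeneous groups the Kruskal–Wallis test is followed by the
  Siegel–Castellan mean-rank comparison (|R̄_i − R̄_j| against
  z_{1−α/(k(k−1))}·√(N(N+1)/12·(1/n_i+1/n_j))) rendered as a compact letter
  display. With homogeneous variances and more than two groups a one-way
  ANOVA with Bonferroni pairwise t-tests is used — a configuration the
  reference survey never exercises, chosen as the conventional parametric
  counterpart.
- Volume models: OLS of ln S_vol on ln S_depth (M1), ln S_area (M2), both
  (M3). AIC is reported as n·ln(RSS/n) + 2(k+1); only differences and
  ordering are meaningful, the additive constant is convention-dependent.
  Partial F compares M3 with each nested model.

## Synthetic data

Terrain: depressions are elliptical paraboloids (default) or cones carved
subtractively into a plane (default slope 0.01 m/m) plus correlated noise
(Gaussian-filtered white noise, correlation length 5 m, amplitude as
requested). Paraboloids give closed-form volume π·a·b·d/2 used as an
oracle. Subtractive nesting means each spec deepens the surface at its
centre by exactly its nominal depth relative to the surface without it.
Footprints may not overlap except by declared nesting and may not touch the
raster edge. A point-sampling emulator (`sample_to_dem`) randomly thins
cell centres and re-grids by Delaunay linear interpolation, for robustness
experiments on canopy-gapped ground returns; the four corner cells are
always retained so the interpolation covers the grid.

Vegetation: separate moss (27), fern (17) and seed-plant (115) pools;
per-plot richness is Poisson with group means 8.6/9.0 (moss), 5.3/4.8
(fern) and 29.8/26.6 (seed plants) inside/outside; proportions are a
symmetric Dirichlet over the species present; seed plants are drawn 80%
from the plot's parent-material half of the pool, producing the
compositional separation by substrate seen in karst plot surveys.

What the benchmarks show: the extraction recovers known geometry under
realistic noise amplitudes, and the statistics recover known effect sizes.
What they do not show: performance on real lidar artefacts (striping,
interpolation ridges, canopy leak-through), non-elliptical or compound
doline shapes, and any claim about real Dinaric sinkhole genesis — the
paraboloid/cone profiles are test conveniences.

## Benchmark problem sizes

The recovery benchmark uses a 500 × 500 m grid at 1 m cells with 20
depressions (depths 3–10 m, widths 12–60 m) under 0.2 m correlated noise;
it recovers exactly 20 rank-1 sinkholes with no spurious records and mean
matched centroid error around 1 m (the worst single record on a shallow,
elongated sinkhole can exceed 2 m — noise near an almost-flat rim moves
the pour by decimetres and the confined region by metres). Hydrology is
cross-checked against exhaustive fixpoint, path-walking and reachability
oracles on one hundred 30–50-cell grids; model-fit calibration uses
n = 2000 with residual σ = 0.16; the comparison test's type-I error is
checked with 10 000 null replicates.

## Known limitations

- The iterative ranking is O(iterations × n log n); DEMs with deep noise
  hierarchies (many merge levels) multiply the cost. The 500×500 benchmark
  runs in ~20 s on one core.
- Effluent levels on heavily terraced flats depend on the epsilon-free
  original surface; terraces at *exactly* equal elevations (engineered
  grids) can merge basins that a real surface would keep separate.
- GeoJSON is written in the DEM's projected CRS (recorded in provenance),
  not reprojected to WGS84.
- `compare_groups` treats observations as independent; plots on a survey
  grid have spatial structure the tests ignore.
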