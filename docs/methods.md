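# Methods

This note documents the models, the synthetic-city generator, the numerical
choices, and the limitations of the `parkequity` pipeline. The landscape-
pattern index formulas live in their own sheet, `landscape_metrics.md`.

## Accessibility model

The accessibility engine is a Gaussian two-step floating catchment area
(G2SFCA) with a quality-weighted supply side. Its assumptions:

- **Travel is on foot over the road network.** Every residence snaps to its
  nearest road node (the straight-line connector is added to the distance);
  a park is reached through its nearest entrance. Points farther than a
  snap limit (default 500 m) from any node are excluded with a warning.
- **The park, not the entrance, is the supply unit.** Entrances only define
  access distance (minimum over gates, realized as a multi-source Dijkstra
  seeded with each gate's node connector). Treating each entrance as an
  independent supply point would multiply a park's capacity by its gate
  count and break the conservation law below; this is a deliberate
  modeling decision.
- **Catchments are class-specific**: community 500 m, regional 1000 m,
  citywide 2000 m, comprehensive 3000 m (park classes by area: <2, 2–5,
  5–25, ≥25 hm²). A `uniform` mode scans all parks at one radius for
  sensitivity analyses; the comprehensive score overlays the class-specific
  radii.
- **Decay is a truncated Gaussian**, 1 at the gate, 0 at the catchment
  edge, continuous at the edge and strictly decreasing inside.
- **Supply is C_j = w_s·S + w_fcs·FCs + w_esv·ESV** with S and FCs in hm²
  (the unit choice is configurable; only relative magnitudes matter
  downstream). ESV can be negative, so a negative composite is floored at
  zero with a warning. Default weights (0.7236, 0.1931, 0.0833) are
  published AHP constants; the generating judgment matrix is not public,
  so `ahp_weights` is provided to derive weights from any user matrix
  (normalized principal eigenvector, CR = ((λ_max−n)/(n−1))/RI(n),
  pass at CR < 0.1).

**Conservation.** Exchanging the two sums in the model gives
Σ_i P_i·A_i = Σ_{j : D_j>0} C_j identically. This is the pipeline's
strongest correctness anchor: it holds to 1e-9 on every generated city,
in both radius modes. A corollary used in the tests: the population-
weighted accessibility total is non-decreasing in the uniform radius
(the served-park set only grows). The *unweighted* mean A_i is **not**
monotone in the radius — a larger catchment can redistribute ratio mass
toward high-population residences and lower the simple mean; the package
reports both.

**Geometric-interval classification.** Comprehensive scores are classed by
multiplicative breaks b_m = a·(M/a)^(m/K) between the smallest (a) and
largest (M) positive score; zeros form their own class. The GIS-vendor
"geometric interval" algorithm is proprietary, so this documented
progression is used instead. A value exactly on a break belongs to the
lower class (stabilized against round-off by a 1e-9 relative inflation of
the break). When a degenerate scene has fewer distinct positive scores
than classes, the profile reduces the class count rather than failing.

## ESV construction

Nine landscape-pattern indices are computed per park on a binary
land-cover raster (4-connected green patches; 4 rather than 8 is the
conservative choice for fragmentation and is configurable in spirit via
the labeling call). Indices are min-max standardized with direction, then
integrated by PCA. Because min-max-scaled columns have covariance
eigenvalues far below one, Kaiser retention is applied where it is
defined: on the correlation matrix (columns z-scored), which is also what
the classic statistical packages do by default. Components with
eigenvalue > 1 are retained (first component as fallback), scores are
combined with explained-variance weights, and the composite is affinely
rescaled to mean 50, sd 25 across parks — so fragmented parks can score
negative. Eigenvector sign is fixed by making each vector's
largest-magnitude loading positive, making scores solver-independent.
Constant index columns map to 0.5 with a warning and are dropped from the
PCA (zero variance).

## Equity model

Bivariate local Moran I_i = z_x(i)·Σ_j w_ij z_y(j) with x = comprehensive
accessibility, y = housing price, z-scores using the population standard
deviation, and row-standardized k-nearest-neighbor weights (k = 8;
residences are points, so contiguity is undefined and KNN is the natural
choice). The global statistic is the mean of the local ones (exact under
row standardization). Inference is by conditional permutation (999 draws,
two-sided, α = 0.05, seeded): for each unit, neighbor values of z_y are
drawn uniformly from the other n−1 units while z_x(i) stays fixed.
Quadrant typing compares z_x(i) against the spatial lag of z_y — the
standard bivariate LISA convention. Duplicate coordinates are jittered by
1e-6 m deterministically. Under white noise the significant fraction
calibrates to 0.05 ± 0.02 (checked at n = 500, averaged over seeds —
single-seed fractions fluctuate by a few points, as expected for a
pseudo-p with 999 draws).

## Planning

- **Blind zones.** Explicit: no park entrance within 3000 network meters.
  Implicit: covered, but in the zero or lowest positive accessibility
  class — coverage without meaningful service, the signature of a dense
  core whose demand swamps small local parks.
- **Targets** are the union of lowest-class residences and significant L-L
  communities, with provenance recorded.
- **K-means curve.** For each k, the best of 10 seeded runs; the curve
  value is the mean over clusters of the farthest member distance in the
  standardized (accessibility, local-Moran) feature plane. The knee
  (largest positive second difference) is the default choice of k. The
  reference run overrides it with a planning-context value (k = 6, about
  one new park per major blind cluster at this city's scale) — the same
  way a real study fixes the count from service-circle considerations
  rather than the curve alone; the override is a first-class parameter.
- **PSO.** Particles are 2k-vectors of site coordinates; fitness is
  Σ_t P_t · min_s dist(t, s) (Euclidean during search). Global-best
  update with inertia 0.729 and c₁ = c₂ = 1.494 (the standard
  constriction-equivalent constants), velocities clamped to 20% of the
  bounds span, positions clipped to bounds, fully seeded. The best-so-far
  objective is non-increasing by construction and is verified against a
  1 m grid search in the k = 1 case.
- **Land use enters by snapping**: each PSO site moves to the nearest free
  candidate parcel (centroid distance, one park per parcel, contested
  parcels resolved in site order); the parcel's area fixes the class and
  radius. This replaces the manual map-reading refinement a human planner
  would do with a deterministic rule.
- **Evaluation** re-runs the full accessibility profile and LISA typing
  with the planned parks appended. New parks get class-typical quality
  defaults (ESV by class — community 77.53, citywide 42.74, comprehensive
  7.51, regional −8.26 — and a modest hard fraction), since not-yet-built
  parks have no measured land cover. Removing the new parks from the
  after-city reproduces the before tables to 1e-9 (additivity check in the
  suite).

## The synthetic-city generator

The generator emulates the structure this analysis class assumes, not any
particular city:

- **Dense under-parked core.** Residences are rejection-sampled with a
  core/periphery density ratio (default 4; realized within ±25% over
  seeds). Small parks (community, and regional greenways that follow the
  internal fabric) are placed inside the central core; large parks are
  excluded from it and spread over the periphery by best-candidate
  (blue-noise) sampling, as planned open space tends to be. The result is
  the target pattern: the core is covered by catchments but bottom-class
  served (implicit blindness), the periphery is well served.
- **Price surface** = base − slope·(distance to center) + correlated noise
  (white noise on a coarse grid, moving-average smoothed at the
  correlation length, rescaled to the configured amplitude — a light
  stand-in for a Gaussian process). The shipped slope is negative: the
  dense old core carries the cheaper housing stock, so low access couples
  with low price there and the global bivariate Moran is positive
  (≈0.1–0.3 across seeds).
- **Parks** are rectangles with 1–4 entrances at boundary points nearest
  distinct road nodes; land cover is generated per park with an exact
  4-connected green-patch count (region growth from well-separated seeds,
  verified by connected-component labeling and retried if patches merge).
- **Roads** are a jittered grid; blocks a regular grid carrying mean
  household sizes; population per residence = households × block mean.
- Coordinates are abstract planar meters (no CRS): the analysis only needs
  metric distances.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: clustered estate microstructure (residences
are independent draws from a two-level density), irregular street
topology, park shapes beyond rectangles, correlation between price and
park proximity beyond the radial gradient, and any temporal dynamics.
Directional conclusions (where blind zones sit, that a targeted plan
raises accessibility and shrinks L-L counts) transfer; absolute magnitudes
do not.

## Problem sizes and runtime choices

The shipped reference scenario is an 8 km × 8 km city, 500 residences,
25 parks (10/4/8/3 by class), a 250 m road grid (33 × 33 nodes), and 2 m
land-cover cells — sizes chosen so a full pipeline run takes seconds and
the entire test suite, including five end-to-end seeds, runs in about a
minute, while every statistical structure of interest (core density
contrast, positive price–access coupling, implicit-blind core) is present.
Land cover defaults to 1 m cells for user data; the reference scenario
coarsens to 2 m, which leaves all landscape indices' orderings intact.

## Known limitations

- Walking is the only travel mode; no slope or crossing impedance.
- Supply units (hm²) enter the composite directly; other unit conventions
  change absolute A_i scales (comparisons and classes are scale-free).
- The geometric-interval rule is a documented reconstruction, not the
  proprietary GIS algorithm; lowest-class membership is sensitive to the
  smallest positive score.
- The permutation test treats residences as exchangeable under the null;
  strong heteroskedasticity in real prices would call for a finer null.
- PSO is a heuristic: optimality is only verified exhaustively for k = 1;
  for larger k the non-increasing trace and blob-separation checks are
  necessary, not sufficient, conditions.
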