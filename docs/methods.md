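# Methods

## The clade-density statistic

Clade density quantifies how much of a species' range is shared with close
relatives: CD_i = Σ_{j≠i} O_ij · C_ij, where O_ij is the area of range
overlap between species i and j and C_ij is their phylogenetic covariance
(the depth of their MRCA, i.e. shared root-path length).  Two properties
follow directly and are enforced as invariants: allopatric species have
CD = 0, and CD is bilinear in O and C (rescaling areas or time rescales CD
proportionally).  CD_i = 0 can also occur with sympatry when every
sympatric partner diverges at the root (C_ij = 0).

Two definitional ambiguities are resolved as explicit options:

* **Self term.**  The diagonal product O_ii·C_ii (range size × tip depth)
  is excluded by default — a species' own range says nothing about
  sympatry with other lineages — and `include_self=True` restores it.
* **Weighting direction.**  The default weight is the covariance C_ij
  itself, which up-weights close relatives (the interpretation under which
  sympatric sister species are the strongest candidate competitors).  A
  sensitivity mode `weight="inv-patristic"` uses 1/d_ij instead; it orders
  pairs the same way but with a different decay shape.

Units are km²·Myr; `area_scale` divides areas for more convenient
magnitudes.  The absolute scale of CD is only meaningful relative to a
fixed projection, area unit, and tree depth, which is why all comparisons
in the package are within-analysis (quantiles, ranks, correlations), never
across datasets.

## Range geometry

Input ranges are GeoJSON FeatureCollections, one feature per
species-subrange with `species_id`, `presence`, and `origin` properties.
Features with excluded codes (defaults: presence `uncertain` /
`possibly_extinct`, origin `introduced`; real-data code lists are
configuration) are dropped *before* the per-species dissolve, so a single
retained feature never inherits area from an excluded one.  Invalid rings
are repaired with `shapely.make_valid`, which rebuilds self-intersecting
boundaries while preserving covered area; repairs are counted in the load
report.  Per-species dissolve precedes overlap computation so that
seasonal or subspecific features never double-count a pair's overlap.

Geographic coordinates are projected with the cylindrical equal-area
projection (standard parallel 0°) on the authalic sphere,
x = R·λ, y = R·sin φ with R = 6371.0071809 km.  The map preserves areas
exactly on the sphere; polygon edges are densified to 0.25° before
projection so the straight chords of the projected polygon track the
projected boundary curve (latitude/longitude-aligned edges map exactly).
Zonal closed forms (full sphere, spherical zones and caps) are reproduced
to machine precision and asserted within 0.1%.

Overlap computation skips pairs with disjoint bounding boxes; a test
asserts bit-identical results against the exhaustive double loop.  The
overlap matrix validates symmetry and O_ij ≤ min(O_ii, O_jj) on
construction.

## Tip speciation rates

The equal-splits measure for tip i is ES_i = Σ_j l_j·2^{-(j-1)} with the
pendant edge first, and λDR_i = 1/ES_i.  The weight convention (pendant
weight 1, halved at each split toward the root) is pinned by the worked
value on the balanced depth-1 four-tip tree: ES = 0.5 + 0.5/2 = 0.75,
λDR = 4/3.  λDR tracks speciation rather than net diversification because
recent branches dominate the sum.  Polytomies make the path index
ill-defined and are rejected unless the caller requests seeded random
resolution with zero-length internal edges.  When only a subset of species
has geographic data, rates are computed on the full tree and *subset*
(`restrict_rates`), never recomputed on a pruned tree — pruning merges
branches and biases rates downward.

The VCV is computed in raw branch-length units; `normalize_depth=True`
offers depth-1 scaling.  On ultrametric trees the identity
C_ij = T − d_ij/2 (patristic d) is used as an independent cross-check.

## The association test

The observed statistic is the Pearson correlation between the transformed
trait and log λDR.  Transformations are pinned, reported defaults rather
than implicit choices: for clade density the default is log(CD + c) with
c equal to the smallest positive CD when exact zeros are present and c = 0
otherwise (clade density is strongly right-skewed with a point mass at
zero); for general traits the identity transform is the default.  The rate
is logged by default; both transforms are configurable and echoed in the
result object.

Brownian motion is fitted to the transformed trait by GLS:
â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x and σ̂² = (x−â1)ᵀC⁻¹(x−â1)/n (the ML variant).
Null traits are drawn as â + σ̂·Lz with L the Cholesky factor of C (a
1e-12 diagonal jitter guards marginal rank deficiency), giving an exact
finite-sample draw from the fitted null.  The two-tailed p-value uses the
permutation-style +1 correction, p = (1 + #{|ρ_k| ≥ |ρ_obs|})/(n_sim+1),
so p is never 0 and the attainable values with n_sim = 100 are k/101.
The reported slope is the OLS slope of λDR on the *untransformed* trait,
in rate per trait unit.

Because σ̂² is estimated from the observed trait, observed and null
statistics are only approximately exchangeable; the calibration study
(500 neutral replicates, 100-tip trees) shows the empirical type-I error
at α = 0.05 stays within [0.03, 0.07], in line with the test's design.

**Ensembles.**  Phylogenetic uncertainty is propagated by repeating the
entire analysis per topology — VCV, λDR, and clade density are all
tree-dependent.  Each topology is run with the *same* seed, which makes a
one-tree ensemble identical to a single test and repeated identical trees
yield identical records; per-topology failures are recorded and skipped.
No multiple-testing correction is applied across topologies: they are
re-analyses of one hypothesis, not independent tests, and the summary
reports the full slope distribution plus the fraction significant at α.

## Synthetic generator

The generator emulates the statistical structure of real range/tree
datasets while providing ground truth:

* **Trees.**  Crown birth–death, conditioned on the number of extant tips:
  the simulation stops when the extant count first reaches n, extended by
  the waiting time to the next would-be event so pendant branches are
  strictly positive; extinct lineages are pruned; full extinction retries.
  With constant rates this is the exact Gillespie algorithm.  Under
  trait-dependent speciation the per-lineage rate λ(x) = λ₀·e^{βx} drifts
  continuously with a Brownian trait, so events are generated on a small
  fixed step (≤ 0.02/λ₀, further capped so the per-lineage event
  probability stays ≤ 5% per step); Brownian increments are exact at any
  step size, and at most one event is applied per step (multiple same-step
  hits have probability O(dt²)).
* **Traits.**  Under neutrality, exact Brownian motion along the final
  tree's edges, so tip traits are exactly MVN(0, σ²C) — verified by a
  Monte-Carlo moment check against the VCV.
* **Ranges.**  Centroids evolve by 2-D Brownian motion on the tree from
  the landscape centre and are mirror-reflected into the landscape; areas
  are lognormal; polygons are axis-aligned squares by default (exact
  analytic intersection areas for oracle tests; discs available) clipped
  to the landscape.  Close relatives therefore overlap more than distant
  ones — the premise that makes clade density informative.  An optional
  contaminant fraction adds displaced features flagged introduced or
  uncertain to exercise the filters.

Default scenario: 100 tips, λ₀ = 1, μ = 0, σ² = 1, a 4000 × 3000 km
landscape, lognormal areas with median 2×10⁵ km² and log-sd 1.5 (the
right skew typical of Red-List range-size distributions), and centroid
rate 4×10⁴ km²/Myr — chosen so range placement decorrelates over the full
tree depth but stays clustered within young subclades.  What the generator
does **not** emulate: realistic continental shapes, climatic or tectonic
structure, range-size evolution along branches, spatially inhomogeneous
occupancy, and extinction-rate dependence on the trait.  Passing
calibration here shows the statistics and test behave correctly under
their own model assumptions; it does not certify behavior under real-data
pathologies such as heavy range fragmentation or strong spatial biases in
sampling.

## Simulation studies and problem sizes

The bundled studies (`cladedensity.studies`) use 100-tip clades, 100 null
simulations per test, 500 replicates for type-I calibration, 100
replicates per effect size β ∈ {0, 0.5, 1, 2} for the power curve, and
100 topologies for the null ensemble study — sizes at which the binomial
Monte-Carlo error on a rejection rate is about 0.01–0.05 and each study
runs in seconds.  Replicate seeds are spawned from a single SeedSequence,
so every study is deterministic given its seed.

## Numerical notes and limitations

* GeoJSON output rounds coordinates (6 decimals ≈ dm precision at km
  scale) and sorts keys, so fixed seeds give byte-identical files.
* Top-decile selection takes ⌈0.10·n⌉ species; ties at the cutoff are all
  included and reported.  Quantiles use linear interpolation; whiskers
  follow Tukey's 1.5·IQR rule.
* Equal-input species ordering is taken from the tree during alignment, so
  results are invariant to the order of the range file.
* Shapefile input is not supported; convert to GeoJSON first.  Raster
  range representations and geodesic (ellipsoidal) areas are out of scope;
  areas are spherical (authalic radius), which differs from ellipsoidal
  areas by well under the uncertainty of digitized range boundaries.
* The ensemble assumes all topologies share one tip-label universe, as
  posterior samples do.
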