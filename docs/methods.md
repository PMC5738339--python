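# Methods

This note documents the statistical model, the conventions and defaults,
the numerical choices, and the known limitations of the `lsctp` package.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The LSCTP statistic

For a cohort of *n* subjects whose cortical thickness maps live on one
shared triangle mesh, the local similarity of cortical thickness profiles
at vertex *v* is defined by

1. collecting the window `W(v) = { u : ‖x_u − x_v‖ ≤ d/2 }` for a window
   diameter *d* (mm);
2. extracting each subject's thickness profile over `W(v)` — a vector of
   `|W(v)|` values;
3. computing the Pearson correlation `r_ij` for every unordered subject
   pair (there are `n(n−1)/2`), and
4. averaging on the Fisher-z scale: `LSCTP(v) = tanh( mean_ij atanh r_ij )`.

The statistic is reported on the *r* scale, the scale on which maps are
thresholded and colored.  It is invariant to subject order and to
positive affine rescaling of any subject's thickness (a Pearson
property), both of which are asserted by tests.

**Exclusion rule.**  A vertex is excluded when (a) at least one subject
has a thickness of exactly zero anywhere in its window — zero is the one
and only missingness code, marking non-cortex such as the medial wall;
(b) the window holds fewer than 3 vertices (the smallest count that
yields a nondegenerate correlation); or (c) some subject's windowed
profile is constant without containing zeros, an edge case counted
separately in the exclusion log.  Because windows grow with *d*, the
excluded set is nested upward in diameter; multi-diameter analyses
therefore harmonize all maps to the largest diameter's inclusion mask
before comparison.

**Window metric.**  Windows use chordal (straight-line) distance on the
coordinates of the designated analysis mesh, with radius `d/2`.  On a
100 mm registration sphere the chordal/geodesic discrepancy is below 1%
for diameters up to 32 mm; a graph-geodesic mode exists per query.  Note
that window "mm" are mesh-coordinate mm — on a registration sphere they
are not cortical mm.  This is a property of analysing on the sphere (the
mesh on which inter-neighbor geometry, and hence the per-window degrees
of freedom, is near-constant), and is documented rather than corrected.

**Fisher clamp.**  `|r|` is clipped to `1 − 1e−7` before `atanh`;
identical profiles (r = 1 exactly) occur in synthetic data and would
otherwise produce infinite z values.  The clamp bounds a single vertex's
LSCTP at ≈ 0.99999998.

## Mesh smoothness and nearest-neighbor smoothing

The effective smoothness (FWHM) of a surface map is estimated from local
differences:

    FWHM = dv · sqrt( −2 ln 2 / ln(1 − var(ds) / (2 var(s))) )

with `dv` the mean edge length (mm), `var(ds)` the population variance of
value differences across mesh edges (orientation fixed low-index →
high-index), and `var(s)` the population variance of the vertex values.
Only edges with both endpoints inside the analysis mask contribute, so
medial-wall zeros cannot inflate the estimate.  Degenerate regimes:
`var(ds) ≥ 2 var(s)` (white noise or rougher) yields FWHM = 0;
`var(ds) = 0` (constant field) yields an infinite-FWHM sentinel that is
serialized as a `constant_field` flag, never as a float infinity.
Variances use the population (divide-by-n) convention throughout; the
formula only uses their ratio, so the convention cancels when applied
consistently.

One smoothing iteration replaces every vertex value by the unweighted
mean over the vertex **and** its 1-ring neighbors.  Self-inclusion is
deliberate: it guarantees stability (no oscillation on bipartite-like
structures) and matches common surface-smoothing practice.  The masked
variant averages only in-mask neighbors and leaves out-of-mask vertices
untouched; an in-mask vertex with no in-mask neighbor keeps its value.

**Calibration.**  Applied to white noise on a dense near-regular sphere,
N iterations produce `FWHM ≈ 1.55 · dv · sqrt(N)` as measured by the
estimator above (`scripts/acceptance.py` recomputes this constant).  The
value has a simple origin: the 7-point kernel (self + 6 neighbors at
distance `dv`) has per-axis variance `(3/7)·dv²` per iteration, giving
`2·sqrt(2 ln 2 · 3/7) ≈ 1.54` in the Gaussian limit.  The classical rule
of thumb `FWHM ≈ 1.25 · √N` is consistent with this *in millimetres on a
mesh with ≈ 0.8 mm vertex spacing* (1.55 × 0.8 ≈ 1.25); in dv units the
constant is ≈ 1.55, not 1.25.  Because the constant is dimensionless in
dv units, the number of iterations needed to reach a target smoothness is
mesh-independent when targets are estimated on the same mesh being
smoothed — `smooth_to_target` exploits exactly this, and a test asserts
that a rescaled copy of a mesh yields the same iteration count (±1).

`smooth_to_target` iterates until the estimated FWHM first reaches the
target and returns the iteration count minimizing `|FWHM(N) − target|`,
ties toward smaller N; an unreachable target raises an error carrying the
best FWHM achieved.

## Monte-Carlo null and critical thresholds

Null maps are built per replicate by independently shuffling each
subject's thickness values within the gray-matter mask (a uniform
permutation — spatial structure is destroyed, the value multiset is
preserved).  Because real thickness data have intrinsic spatial
smoothness that shuffling removes, the default pipeline re-smooths each
shuffled map to that subject's true-data FWHM before computing null LSCTP
maps; unsmoothed nulls produce markedly lower (too liberal) critical
values, and the test suite asserts the strict ordering
`threshold(smoothed) > threshold(unsmoothed)` at matched p and diameter.

Null values are pooled globally — across vertices and replicates — into
one empirical distribution per window diameter, matching a design that
reports a single critical LSCTP per window size; per-vertex nulls at
extreme tail probabilities would require orders of magnitude more
replicates.  The critical value at tail probability *p* uses the plus-one
permutation convention: the smallest observed value *t* with
`(#{null > t} + 1) / (n_null + 1) ≤ p`.  A request below the resolution
`1/(n_null + 1)` returns the maximum null value flagged unresolvable (the
CLI refuses to threshold in that case).

Seeds follow a splittable counter scheme
`SeedSequence(base_seed, spawn_key=(replicate, subject))`, making every
per-subject shuffle independent and the whole pipeline exactly
reproducible from one base seed; replicate seeds are recorded in the
output provenance.

## Window-size selection

Stage one computes LSCTP maps over a list of primary diameters (default
schedule 2–31 mm inclusive, 30 maps; the schedule is explicit and
recorded in output metadata).  Stage two maps the local SD of each LSCTP
map within a second sliding window (population SD over included window
members; windows with fewer than 2 included members are undefined) and
averages the defined values per primary diameter.  Undefined cells are
excluded from averages, never zero-filled — zero-filling would bias the
selection toward large windows.  The table reports the argmax primary
diameter per SD diameter; the final window choice is meant to combine the
table with visual inspection of the maps.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes: a
cohort on one shared sphere, nonnegative thickness with zeros marking the
medial wall, spatially smooth fields, and regions where subjects share a
common profile.  Inside a region of strength ρ,

    t_s(v) = base + sd · ( sqrt(ρ)·c(v) + sqrt(1−ρ)·e_s(v) )

with one common field *c* and independent per-subject fields *e_s*, all
nearest-neighbor-smoothed white noise standardized to zero mean and unit
variance.  The sqrt mixing makes ρ the expected inter-subject profile
correlation — the directly recoverable ground-truth quantity (recovery at
n = 42 within sampling error is an acceptance test).  Defaults: base
thickness 2.5 mm and field sd 0.5 mm (typical cortical values); 10
smoothing iterations for the fields; values clipped at ≥ 0.1 mm *before*
medial zeros are applied, so zero stays unambiguous as the missingness
code.  An optional separate smoothness for the idiosyncratic fields
(`idio_smooth_iterations`) lets the shared structure be coarse while
subject noise is fine-grained; in that regime LSCTP rises with window
size (small windows see mostly idiosyncratic variation) and ρ is the
large-window limit.

Spheres are midpoint-subdivided icosahedra (`10·4^s + 2` vertices)
projected to a chosen radius.  The convenience radius
`fsaverage_like_radius(s) = 100 · 2^(s−7)` reproduces the vertex density
of the standard 163842-vertex, 100 mm registration sphere at any
subdivision level (mean edge length ≈ 0.944 mm), so window diameters in
mm mean the same thing at desk scale as at full scale.  The test suite
and acceptance script use subdivisions 2–4 (162–2562 vertices) for cohort
analyses and 6–7 (40962–163842) for geometry and smoothing calibration;
these sizes were chosen as the smallest at which the tested quantities
are stable.

**What the generator does *not* emulate** — and hence what passing tests
do not show about real data: folded cortical geometry (no dv contrast
between a registration sphere and an anatomical surface), inter-subject
registration error, spatially varying thickness means or variances, and
measurement artifacts beyond additive Gaussian-like variation.  One
consequence is documented here because it is easy to misread: with
smoothed-Gaussian shared fields, the *smallest* windows give the crispest
LSCTP maps (a smooth field still carries shared gradient texture at fine
scales), so the local-SD window-selection table peaks at the smallest
primary diameter on synthetic cohorts.  On real data the fine scales are
additionally decorrelated across subjects by residual alignment error,
which plausibly moves the peak to intermediate diameters; simulating
alignment error is out of scope for the generator.

## Conventions and I/O

Vertex indices are 0-based everywhere; plain-text label files may declare
another base in a header (`# index-base: 1`).  Thickness and coordinates
are mm; no unit conversion is applied.  NaN on input is an error, never a
missingness code; derived statistic maps may opt in to NaN as an explicit
"undefined here" marker.  FreeSurfer binary surfaces (triangle magic
`0xFFFFFE`), curv/morph files (`0xFFFFFF`), and ASCII labels are read and
written via nibabel behind the package's I/O layer, with documented
plain-text fallbacks (ASCII surface, one-value-per-line morph, index-list
label, subjects × vertices TSV cohort); all paths are accepted gzipped.
LSCTP maps export as morph (excluded vertices written as 0) + companion
inclusion label + TSV.  The CLI mirrors the library, writes a JSON
provenance record (parameters, seeds, version) beside every output, and
uses exit codes 0/1/2/3 for success/usage/data/numerical errors.

## Known limitations

- Hemispheres are analysed one mesh at a time; pooling left/right is left
  to the caller.
- Exact geodesic windows, covariate adjustment, weighted correlations,
  cluster-extent or FDR inference, and spin-test (rotation) nulls are out
  of scope; the null is a global single-threshold permutation design.
- The FWHM estimator assumes an approximately Gaussian autocorrelation
  and near-uniform edge lengths; on strongly irregular meshes the mm
  value inherits the local dv, which is why the dimensionless `fwhm/dv`
  is always reported alongside.
- At very small windows (≲ 3 vertices beyond the minimum) pairwise
  correlations are extremely noisy and the Fisher clamp makes individual
  z values heavy-tailed; interpret small-diameter maps accordingly.
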