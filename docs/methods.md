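# Methods

This note records the model, the numerical choices, and the design of the
synthetic data, at the level of detail a user needs to judge what the
package's results do and do not show.

## The flow model

An object is a triangle mesh, normalized so its vertex centroid is at the
origin and its maximum vertex radius is 1; all flow values are therefore in
object-radius units and comparable across objects. Conventions are fixed
package-wide: right-handed coordinates, vertical axis +y, camera on +z
looking at the origin, image x right / y up; positive azimuth rotates the
object counter-clockwise seen from above. The default camera is
orthographic with unit image scale, which makes the symmetry laws below
exact; a pinhole camera at distance d (object radii, d > 1) is available
and converges to the orthographic limit as d → ∞.

Point correspondence between two poses of the same object is the identity
on vertex indices — posing is a rigid rotation that preserves vertex order.
The dissimilarity between azimuths a and b is computed in four steps:

1. visibility in pose a and in pose b, per vertex (below);
2. matched set = vertices visible in both (no interpolation or imputation
   for unmatched vertices — they simply do not contribute);
3. per-matched-vertex image displacement, projection of pose b minus
   projection of pose a;
4. the scalar: mean of the pooled absolute horizontal and vertical
   displacement components (`L1-components`, default), or the mean
   Euclidean displacement length (`L2-length`). The two differ by a bounded
   factor (L2 ≥ L1 always); every analysis runs under either, selected by a
   flag, and neither is treated as uniquely correct. Absolute units are not
   meaningful — only relative quantities (gradients, slopes, ranges,
   correlations) are interpreted.

The flow curve evaluates this between each grid viewpoint i·5° and its
neighbour (i+1)·5°, giving 72 circular values. Derived predictors:

* gradient at view i: circular central difference
  (f[i+1] − f[i−1]) / (2·step), in flow units per degree. A forward
  difference is available for sensitivity checks. Comparisons between
  cardinal and non-cardinal views use |gradient|, because cardinal views
  sit at curve extrema where the signed gradient crosses zero.
* segment slope between a base view and a ±5/10/15° offset view:
  (f[base+offset] − f[base]) / |offset|.
* range: max − min of the curve, a per-object irregularity summary.

## Visibility

A vertex is visible when the ray from it toward the camera, with the origin
pulled back toward the camera by 1e-6 of the bounding radius (so the faces
meeting at the vertex cannot shadow it), intersects no mesh triangle
strictly in front of it. Intersection is Möller–Trumbore with two
documented constants: rays within |det| ≤ 1e-12 of parallel to a triangle's
plane do not intersect it, and the barycentric inclusion test carries a
slack of 1e-9. The slack matters: a ray crossing an edge shared by two
triangles sits exactly on the boundary of both tests, and without slack
rounding noise decides whether either triangle reports the hit — grid
meshes produce such rays *systematically* (a back vertex's ray crosses
front edges at exactly shared ring heights). With the slack, both triangles
report the hit and occlusion is decided robustly. The orthographic path
prefilters ray–triangle pairs by projected bounding box (exact and
conservative — it only skips pairs that provably cannot intersect) with
x-strip binning for speed; the perspective path tests all pairs with a
finite ray length. A deliberately naive per-vertex reference implementation
in the test suite reproduces the vectorized model to 1e-9 on random meshes.

## Statistical machinery

* Exclusions: trials outside the 300–5000 ms reaction-time window are
  dropped; participants below 75% correct on the priming task or the main
  task lose all trials. Main-task accuracy counts 0° trials as correct when
  answered "same" and |rotation| ≥ 10° trials when answered "different";
  5° trials are near threshold and are not scored. Both rules are evaluated
  on the input set and applied jointly, so the outcome is order-independent.
* Psychometric tables pool ±k rotations into |k| by default (unpooled
  available). Cells with no trials are absent, never zero. The cardinal
  axis effect for an object is the difference, cardinal minus non-cardinal,
  of (P_different(5°) − P_different(0°)) / 5 — per-degree units. Only the
  0°→5° segment is used: larger offsets approach ceiling and wash out
  between-object differences in sensitivity.
* The factorial model (performance ~ rotation level × axis type × image
  set) is a feasible GLS: iterate (weighted LS fit → per-group residual
  variances → refit) to convergence, for each candidate residual-variance
  grouping (homoscedastic, per axis type, per rotation level, per cell);
  the grouping with the lowest AIC (ML likelihood, k = p + #groups) wins.
  Wald F-tests (df1 = 1 under sum-to-zero coding with a centered numeric
  rotation term) are marginal, Type-III-style tests. Group variances used
  in the Wald covariance carry an N/(N−p) correction with model df
  allocated proportionally across groups, which makes the homoscedastic
  case reproduce OLS ANOVA exactly; the AIC uses the ML variances. The
  analysis unit is the participant × object × axis × level proportion:
  keeping objects separate leaves real between-object spread in every
  variance group. Pooling over objects produces near-zero-variance cells at
  floor/ceiling whose weights dominate the fit and, because a linear
  rotation-level term cannot follow a saturating psychometric function,
  turn misfit into spurious effects. A null simulation (heteroscedastic
  groups, 1000 replicates) calibrates the type-I error of each F-test to
  ≈5%.
* Small-sample toolbox: paired t with Cohen's D = |mean d| / sd(d); simple
  regression with the overall F on (1, n−2) df; Wilcoxon signed-rank with
  exact two-sided p by full sign-assignment enumeration for n ≤ 12 (ties
  handled by average ranks) and a tie-corrected, continuity-corrected
  normal approximation otherwise; effect size r = |z|/√n. Two-sided tests
  throughout, α = 0.05.

## Front judgements

Responses are snapped to the 5° grid (stimuli only exist at grid views).
Circular summaries: mean resultant length R̄ ∈ [0, 1] and the circular mode
with 5° bins centered on the grid (ties go to the lowest angle). Familiar
objects with a veridical front exclude responses farther than 45° (circular
distance); novel objects are never excluded by this rule. The substantive
comparison takes, per object, the *set* of distinct grid views any retained
participant called "front" versus its complement, the mean |gradient| over
each, and a paired Wilcoxon across objects. Set semantics make the result
invariant to duplicate choices; an object whose participants covered all 72
views has an empty complement and is dropped (flagged in the output). The
"gradient" here means the absolute central difference — front views
sit at curve extrema where the signed gradient changes sign, so signed
means would cancel.

## Synthetic data: what it emulates, and what it does not

Meshes come from three families — superquadrics (smooth, regular),
extruded rounded polygons (prism-like), and spherical blobs with seeded
low-order angular perturbations (irregular, "novel-like"). Symmetries are
imposed by construction: the radial basis is restricted to the
symmetry-respecting subspace (cos(mφ) terms for mirror symmetry, m ≡ 0 mod
n for n-fold symmetry), the longitude count is a multiple of the symmetry
order, and for mirror-without-rotational symmetry the quad triangulation
itself is made mirror-equivariant (split diagonals flip across the mirror
plane; the two plane-straddling quad columns are centroid-split). Three
further meshing rules keep visibility numerically well-posed: longitude
columns are half-offset, the longitude count n_phi satisfies
72/gcd(72, n_phi) even, and every finished mesh is twisted by half a grid
step (2.5°) about the vertical — together these guarantee no feature
direction (vertex column, prism-face normal, mirror plane, long axis) is
ever exactly edge-on at a grid azimuth, where visibility would be decided
by rounding noise. Consequences: generated mirror planes sit at azimuth
2.5°, so the mirror law for curves reads f(a) = f(−a − 5° − 5°), i.e.
values[i] = values[(−i−2) mod 72]; n-fold periodicity and this identity
hold to ~1e-14. Elongation stretches the (pre-twist) z axis and breaks
n-fold symmetry for n > 2, so exact rotational-symmetry checks use
elongation 1.

The regular 13-object suite is a one-factor stimulus family: one
superquadric shape (exponents 1.0, 0.9), mirror-symmetric, with bimodal
elongations (1.05–1.3 and 2.2–3.4) emulating an everyday-object set of
round-ish items and elongated ones. The single manipulated factor makes
curve contrast vary widely and systematically, which is what the
cardinal-axis parameter-recovery analyses need. The novel suite is ten
perturbed blobs with varying symmetry and elongation.

Simulated observers respond "different" with probability
guess + (1 − guess − lapse)(1 − exp(−(d/α)^β)), where d is the model
dissimilarity accumulated along the rotation path from base to offset view
(sum of the intervening curve steps; a direct pairwise variant is
available). Defaults: guess 0.05, lapse 0.02, β = 2.2, and α calibrated to
1.3× the median single-step flow of the curves being simulated. This
places the group psychometric means near 0.05/0.5/0.9/0.97 at the four
rotation levels — the 5° offset is the one hard above-floor discrimination
— while the individual-observer β is steeper than the apparent steepness
of a group-mean curve, which is flattened by averaging over objects and
axes with different dissimilarities. Reaction times are lognormal
(median 800 ms, σ_log 0.35), so the exclusion rules lose well under 5% of
trials. The discrimination design derives from each curve: front at the
global maximum, back at the local maximum nearest its antipode, and
non-cardinal views 45° from the cardinal views (midway between a cardinal
axis and a side axis); each participant sees each condition twice
(trials_per_cell = 2). Front choices are drawn over grid views with weight
exp(−|gradient|/(T·mean|gradient|)), T = 0.25, times a 2× bonus at local
curve extrema.

One master seed fans out to per-component child seeds (SeedSequence over a
CRC-32 of a stage label), so every stage reruns bit-identically and stages
can be rerun independently.

What the generator does **not** emulate: pixel rendering (lighting,
texture, self-shadowing are irrelevant to the vertex-based model and are
absent), photographic stimuli, familiarity, memory or response-bias
dynamics, between-participant sensitivity differences, and any dependence
of responses on anything but the model dissimilarity. Passing recovery
tests therefore show that the pipeline correctly extracts the signatures
the generator plants at realistic sizes and noise levels — they cannot
show that human observers actually use these computations.

## Problem sizes and determinism

Default analyses use 13 regular objects × 4 base views × 7 rotation levels
× 50 participants × 2 trials (36,400 trials), 10 novel objects × 50 front
choices, meshes of ~350 vertices, and a 72 × 5° viewpoint grid. Recovery
rates are estimated over 200 replicate experiments; GLS null calibration
over 1000. Symmetry checks use a ~2,200-vertex sphere (the flow-curve
ripple of a rotationally symmetric shape is silhouette-sampling noise and
shrinks with longitude count; at this density the coefficient of variation
is just under 1%) and 250-vertex prisms. All tests and the acceptance
script are fully seeded.

## Known limitations

* Visibility is exact ray casting per vertex, not a z-buffer; meshes with
  millions of faces would need a spatial index beyond the current
  bounding-box prefilter.
* Only rotations about the vertical axis are modelled; correspondence by
  vertex identity does not extend to non-rigid deformation.
* The L1-components default weights horizontal and vertical displacement
  equally and ignores direction; the colour-coded direction structure of
  flow fields is exportable per vertex but not analysed.
* The FGLS variance-structure search is limited to the four named
  groupings; arbitrary variance functions (e.g. power-of-mean) are out of
  scope.
* Exact Wilcoxon enumeration is O(2^n) and capped at n = 12; larger samples
  use the normal approximation.
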