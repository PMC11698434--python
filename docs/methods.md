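# Methods

## Coordinate conventions

All modules share image coordinates: origin at the top-left corner,
x = column, y = row, y increasing downward. Landmark files (TPS and CSV) and
JSON annotations store `(x, y)` pairs in this frame. Because wings are imaged
without recording the body side, configurations are brought to a single
handedness before shape analysis: the landmark outline loop (anterior
landmarks in pair order, posterior landmarks back) is traced and any
configuration with negative signed (shoelace) area is reflected about y. The
Procrustes alignment additionally permits improper rotations, so an
unrecorded wing side can never inflate disparity.

## Pairwise Procrustes disparity

Two configurations with identical label order are compared by (i) centering
each at its centroid, (ii) scaling each to unit root-sum-of-squares size,
(iii) finding the orthogonal map (rotation or reflection) and scale for the
second that minimize the sum of squared distances to the first. The minimized
sum is the disparity: dimensionless, symmetric in its arguments, zero exactly
for similarity-equivalent shapes. The implementation delegates to
`scipy.spatial.procrustes`; the test suite checks it against an independent
brute-force oracle that scans rotation angle on a dense grid (plus golden-
section refinement and both reflection branches) with the analytic optimal
scale per angle.

Cohorts are compared exhaustively: all n₁ × n₂ ordered cross pairs (the
reference taken from the first cohort; disparity symmetry makes the order
immaterial, but it is fixed for reproducibility), or all n(n−1)/2 unordered
within-cohort pairs. Mean aligned shapes are arithmetic means of the aligned
matrices over all pairs; per-landmark displacement between the two means is
Euclidean, and a landmark is flagged when its displacement strictly exceeds
twice the mean displacement (strict inequality, so a set of equal
displacements flags nothing).

## AP axis, symmetrization, symmetry scores

For a paired landmark set (anterior label iA ↔ posterior label iP), the AP
axis is the line through the midpoints of the two designated axis pairs
(pairs 2 and 5 — the landmark pairs on veins L2 and L5 — in the default
10-point scheme). Validation rejects configurations with missing pair labels
or coincident axis midpoints before any geometry runs.

The *anteriorized* wing replaces each posterior landmark iP with the
reflection of iA across the AP axis; the *posteriorized* wing is the
converse. Three properties are enforced and tested:

- the axis is always computed from the **original** configuration, never the
  symmetrized one;
- label order is preserved, so Procrustes correspondence is label-wise;
- reflection is an isometric involution, making symmetrization idempotent
  per side, and the symmetrized wing is exactly mirror-symmetric about the
  original axis (all pair midpoints lie on it).

The symmetry scores of a wing are the disparities to its own anteriorized and
posteriorized images. Both are zero iff the wing is mirror-symmetric, both
are invariant under similarity transforms of the wing, and with no landmark
noise the score increases strictly with the generator's asymmetry factor.

## Disc-pattern geometry

A pattern channel (z-stack or 2-D projection) is reduced to a binary
footprint:

1. maximum-intensity projection (optionally per block of g planes; the
   overlap analysis uses g = 5);
2. background subtraction: the mean of a user-annotated 30 × 30 px square
   region outside the pattern is subtracted, negatives clamped to zero;
3. threshold at a fixed fraction of the maximum intensity (default 0.20,
   strict `>`, taken after background subtraction on the projected image) —
   the threshold is relative, so the mask is invariant to intensity rescaling;
4. cleanup: connected components below 64 px removed (optionally keeping only
   the largest; ties broken by first label in scan order), then a 5 × 5 mean
   filter re-thresholded at 0.5 smooths edges. The cleanup operators and
   parameters are deliberate choices — the simplest morphology + blur
   combination — and all are exposed in `RunConfig`.

Pattern elongation is measured by a direct algebraic least-squares conic fit
(the `scikit-image` ellipse model: deterministic, non-iterative) to the
convex-hull vertices of the footprint. The fit is normalized so a ≥ b
(rotating θ by π/2 when swapped) and reported with the eccentricity
e = √(1 − b²/a²). On exact on-ellipse points the fit recovers parameters to
~1e−6; through the full raster-hull pipeline, eccentricity of a 200 × 120 px
phantom is recovered within 0.02 and is rotation- and translation-invariant
to about 0.01 (pixelation is the only error source). The same fit applied to
≥ 5 manually clicked hinge-pouch fold points gives a reporter-independent
pouch ellipse.

Two-channel colocalization is summarized by counting pixels set in both
masks and dividing by the nominal pixel area of one nucleus (default 200 px);
the estimate is reported fractionally, not rounded, because the division
defines an estimate rather than a count.

## Intervein region partition

Vein polylines (manual click points between intervein-marker domains),
ordered anterior → posterior, partition the footprint. Each polyline's
terminal segments are extended to beyond the image diagonal so clicks need
not reach the pattern edge. A pixel's side relative to a vein is the sign of
the cross product between the local direction of the nearest polyline segment
and the vector to the pixel; the pixel's region index is the number of veins
it lies strictly posterior to. Consequences, all tested:

- the partition is exact — every foreground pixel belongs to exactly one
  region, so relative areas always sum to 1;
- pixels exactly on a vein line are assigned to the anterior region
  (deterministic sub-pixel tie-break);
- densifying a polyline with collinear points changes nothing.

Anterior/posterior orientation of each vein is inferred from the positions of
the other veins (the later veins lie posterior); veins whose mutual positions
contradict the given order raise an error naming the vein. For a single vein
the posterior side is the right-hand side of the polyline as digitized.

Region areas are pixel counts (relative to total foreground for pattern-based
tables, or to the true ellipse area πab for the hinge-pouch variant, where
the fitted ellipse is rasterized first; the rasterization/true-area mismatch
is below 1 % at pouch scale). A shoelace `polygon_area` (validated through
`shapely`, rejecting self-intersections) covers manually outlined adult-wing
region polygons.

## Gated two-sample testing and power

Every cohort comparison runs one decision tree at significance level
α = 0.05: Shapiro–Wilk on each group (validity range 3 ≤ n ≤ 5000 enforced
with a warning outside); if both p > α, Levene's test chooses between the
pooled-variance and Welch t-tests (equal variance iff Levene p > α);
otherwise a two-sided Mann–Whitney U test. The report records every gate
p-value so the branch is a pure function of recorded values. Groups with zero
variance are returned flagged `degenerate` with no p-value — a constant score
distribution (e.g. cohorts of identical wings) makes both the normality gate
and a t-test meaningless.

Power for the t-branch is the exact noncentral-t power
(`statsmodels.stats.power.TTestIndPower`), cross-checked in the tests against
a quadrature oracle that integrates the chi-square mixing density directly.
For the Mann–Whitney branch no closed form exists, so power is Monte-Carlo:
`reps` (default 10 000) pairs of samples of size n from unit-variance normals
separated by the stated shift, counting two-sided rejections at α. The
sampling model is a deliberate choice — the simplest faithful Monte-Carlo
design for a location alternative; a bootstrap-from-observed-samples mode is
available but not the default. The estimate is bit-identical under a fixed
seed, its size under the null matches α (0.05 ± 0.01 at 20 000 reps), and at
moderate effects it agrees with the analytic normal approximation at
ARE-adjusted effective sample size (3/π · n) to within 0.05.

## Synthetic data: what it emulates, what it does not

**Wing cohorts** start from a fixed, exactly mirror-symmetric 10-point
template (pairs 1–5, AP axis on the x-axis, canonical handedness, published
as `wingsym.synthetic.TEMPLATE_COORDS`). Asymmetry is injected by displacing
posterior landmarks outward from their mirror positions by
`asym × weight_i × |y_i|`, with weights (0.2, 0.3, 0.5, 0.75, 1.0) rising
toward pair 5 — mimicking a posterior-compartment growth defect concentrated
at the posterior margin. Landmark noise is isotropic Gaussian per coordinate,
expressed as a fraction of the template's centroid size (default **0.002**).
That default was fixed by characterizing the symmetry score's noise floor:
the score is quadratic in noise through all 20 coordinates but carries signal
in only the five posterior landmarks, so noise above ~0.5 % of centroid size
drowns a 10–20 % outward displacement. At 0.002 the bundled two-cohort
experiment (n = 50 per group, asym 0.2 vs 0.1) detects the symmetry
difference in ≈100 % of replicates; the mapping from `asym` to expected
disparity is documented empirically by the monotonicity tests, not claimed
analytically.

**Disc phantoms** are two-channel images: channel 1 a filled ellipse of known
semi-axes (hence exact eccentricity) at intensity 200 plus Gaussian noise
(default sd 5); channel 2 a bright field with dark stripes (half-width 4 px)
perpendicular to the major axis at the stated fractions of its extent,
emulating an intervein marker whose inverse binarization localizes pro-vein
stripes. Ground-truth region counts are computed by binning in-ellipse pixels
on their exact major-axis coordinate — a code path independent of the
analysis modules, keeping recovery tests non-circular. Default geometry
(512 × 512 px, a = 200, b = 120 → e = 0.8, vein fractions 0.2/0.4/0.6/0.8)
matches the scale of a late-larval wing disc imaged at ordinary confocal
resolution.

Neither generator attempts photorealism: no staining gradients, no epithelial
folds in the pattern channel, no curved veins, no segmentation ambiguity at
the pattern border. Passing recovery tests therefore demonstrates the
correctness of the geometry and statistics on well-posed inputs, not
robustness to poor staining or annotation error in real micrographs — those
enter through the manual annotations, which this package treats as given.

## Problem sizes and determinism

The bundled experiments use the canonical cohort sizes (52 × 20 wings for
pairwise comparison; 50 per group × 100 replicates for the detection
experiment; 10–20 k Monte-Carlo replicates for power), which run in seconds
to a couple of minutes on one CPU. All stochastic steps take explicit integer
seeds; pipelines rerun with the same inputs and seed write byte-identical
CSV output.

## Known limitations

- Landmark identity is the user's responsibility: anatomical definitions of
  the margin/vein landmark sets and the 26-point extended pairing must be
  supplied as labels and a `PairedScheme`; nothing is auto-detected.
- The vein-side classifier assumes reasonably smooth, roughly parallel
  polylines; strongly re-entrant veins could mis-assign pixels near sharp
  bends (the nearest-segment rule is local).
- The hinge-pouch variant rasterizes the fitted ellipse, so its region
  fractions inherit ~1 % pixelation error; the pattern-based partition is
  exact by construction.
- Mann–Whitney power assumes a pure location shift of normals unless the
  bootstrap mode is used; heavy-tailed alternatives will differ.
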