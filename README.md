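# wingsym

Landmark morphometrics and image geometry for quantifying **anterior–posterior
(AP) asymmetry** of insect wings and of wing-disc expression patterns.

Developmental biologists comparing a control cohort of *Drosophila* wings with
a genetically perturbed one need more than total wing area: they need to know
*where* shape changed, and whether the perturbation made wings more or less
mirror-symmetric about the AP axis. `wingsym` provides the complete analysis
chain for that question:

- **Pairwise Procrustes comparison** of labelled landmark configurations
  (margin or vein landmark sets): each configuration is centered, scaled to
  unit centroid size, and optimally rotated (reflections allowed), and the
  residual sum of squared distances — the *disparity* `d` — measures shape
  difference. Cohorts are compared exhaustively (all n₁ × n₂ pairs), averaged
  aligned shapes are computed, and landmarks displaced more than twice the
  mean displacement are flagged.
- **AP-symmetry scoring by symmetrization.** For a wing with paired landmarks
  (iA ↔ iP), the AP axis is the line through the midpoints of pairs 2 and 5.
  Reflecting the anterior landmarks across this axis and substituting them for
  their posterior partners yields the *anteriorized* wing (the *posteriorized*
  wing is the converse). The Procrustes disparities
  d(wing, anteriorized) and d(wing, posteriorized) are per-wing asymmetry
  scores: 0 for a perfectly symmetric wing.
- **Disc-pattern geometry.** An expression-pattern image is reduced to a
  binary footprint (max z-projection, background subtraction from an annotated
  ROI, threshold at 20 % of the maximum intensity, morphological cleanup). Its
  elongation is the eccentricity e = √(1 − b²/a²) of the least-squares ellipse
  fitted to the footprint's convex hull, and vein click-point polylines
  partition the footprint into intervein regions (M-L2 … L5-M) whose relative
  areas are reported exactly (pixel-conserving partition).
- **Gated statistics.** Every two-cohort comparison runs Shapiro–Wilk on each
  group, then either Levene + t-test (equal/unequal variance) or a two-sided
  Mann–Whitney U test, at α = 0.05; power is computed by noncentral-t for the
  t-branch and by Monte-Carlo simulation for the Mann–Whitney branch.
- **Synthetic generators with exact ground truth** (wing cohorts with a
  controllable asymmetry factor; two-channel disc phantoms with known
  eccentricity and region fractions) validate every step end to end.

## Worked example

```python
import numpy as np
from wingsym import SYM10_SCHEME, cohort_symmetry_comparison, pairwise_disparities
from wingsym.synthetic import WingGenParams, generate_wing_cohort

control = generate_wing_cohort(
    WingGenParams(n=52, asym=0.2, seed=1, cohort="control", name="control"))
impaired = generate_wing_cohort(
    WingGenParams(n=20, asym=0.1, seed=2, cohort="impaired", name="impaired"))

cross = pairwise_disparities(control, impaired)
within = pairwise_disparities(control)
print(f"cross-cohort comparisons: {len(cross)}")
print(f"median disparity: within={np.median(within.values):.6f}  "
      f"cross={np.median(cross.values):.6f}")

comp = cohort_symmetry_comparison(control, impaired, SYM10_SCHEME)
med = comp.scores.groupby("cohort")["d_anteriorized"].median()
print(f"median anteriorized score: control={med['control']:.6f}  "
      f"impaired={med['impaired']:.6f}")
t = comp.anteriorized_test
print(f"gated test: {t.test_used}, p = {t.p_value:.3g}")
```

prints

```
cross-cohort comparisons: 1040
median disparity: within=0.000116  cross=0.000206
median anteriorized score: control=0.000163  impaired=0.000098
gated test: t_equal_var, p = 0.000306
```

The 52 × 20 design yields 1040 cross-cohort disparities. Cross-cohort pairs
are farther apart in shape space than within-control pairs (the perturbation
changed shape), and the impaired cohort — generated with half the asymmetry
factor — is significantly closer to its own symmetrized images: it is more
AP-symmetric, exactly the property the score is built to detect.

The same analyses are available from the shell:

```sh
wingsym simulate-wings --n 52 --asym 0.2 --seed 1 --out control.csv
wingsym simulate-wings --n 20 --asym 0.1 --cohort impaired --seed 2 --out impaired.csv
wingsym wings-analyze --control control.csv --impaired impaired.csv --out results/
wingsym simulate-discs --n 8 --seed 3 --out-dir discs/
wingsym discs-analyze --images discs/ --out results/
wingsym power --test mwu --effect 0.5 --n 50 --seed 0
```

## Documentation

`docs/methods.md` describes the models, the geometry, the numerical choices
and the synthetic-data generators in detail, including what the phantoms do
and do not emulate about real micrographs.
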