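# Methods

## Problem and scope

The package quantifies the concavity geometry of lumbar endplate
surfaces (L4 superior/inferior, L5 superior/inferior, S1 superior) from
triangulated meshes, classifies each endplate-plane into four
morphological types, and computes the cohort statistics used to compare
the resulting distributions and depths between groups.  CT acquisition,
segmentation and mesh repair are upstream of the package: input is an
STL surface of a single, already-isolated endplate, in millimetres, with
a declared anatomical frame (default +x toward patient left, +y
anterior, +z superior; STL itself carries neither units nor axes).

## Profile extraction

A profile is the intersection of the mesh with the plane through the
mesh centroid orthogonal to the lateral axis (sagittal) or the AP axis
(coronal).  Per-triangle intersection segments are computed directly:
vertices within 1e-9 mm of the plane count as on-plane; a triangle
exactly coplanar with the plane contributes its two longest edges, an
edge lying in the plane is contributed once (duplicates from the two
adjacent triangles are removed by quantized deduplication), and point
contacts are dropped.  Segments are chained into polylines by endpoint
matching within 1e-6 mm — the same tolerance used to merge duplicate
vertices at STL read time, which is what makes chaining across facet
boundaries possible.  Chaining conserves total intersection length to
1e-9 relative (a tested invariant).  The chain with the greatest
horizontal extent becomes the profile (ties broken by arc length),
ordered posterior→anterior or right→left.

The centroid plane is a package convention: it is deterministic and
testable, whereas placing the plane through the deepest point would make
plane placement depend on the quantity being measured.

## Morphometry

Margin points are the highest profile points within the outer 15% of the
horizontal span at each end (configurable).  A windowed rather than
global maximum keeps a tilted or lipped profile from pulling a "margin"
into the interior.  The chord between the margin points is the diameter
(SD/CD); concavity depth (SCD/CCD) is the maximum perpendicular distance
from the chord to points on its inferior side.  Perpendicular-to-chord
is used in both planes because it is invariant under in-plane rigid
motion; a frame-vertical drop would change under tilt.  Apex-to-margin
lengths (SPL/SAL, CRL/CLL) are straight-line distances.  The plateau
fraction is the chord-projected span of points whose depth is at least
0.9 × the maximum, over the chord length; 0.9 is a package convention
chosen so that a single-apex raised-cosine depression scores ≈ 0.20
while a clipped-plateau depression of plateau fraction 0.4 scores
≈ 0.44, leaving a wide separation around the 0.30 classification
threshold.  Convex or level profiles get depth 0, ratio 1, apex at the
chord midpoint.

### Noise handling

`measure_profile(..., smooth_window=w)` applies a centred w-point moving
average (edge-replicated) to the heights before measurement.  Two raw
estimators are noise-fragile: the pointwise maximum depth is biased
upward by roughly σ·√(2 ln n) (≈ +0.2 mm for 64 points at σ = 0.1 mm),
and the raw argmax apex is unstable on the flat top of a smooth bump,
inflating the asymmetry ratio.  The default window is 1 (identity), so
analytic profiles are measured exactly; the cohort pipeline, the
reliability protocol and the recovery studies use window 5 (~4% of the
profile length), which removes most of both biases and mirrors the
surface-smoothing step of CT reconstruction workflows.

## Classification

Rules are applied in fixed order: depth < 1 mm → flat; plateau fraction
≥ 0.30 → flat-bottomed concave; length ratio ≥ 1.3 → asymmetric concave;
otherwise uniformly concave.  Boundary values go to the concave
(depth = 1.0) and asymmetric (ratio = 1.3) sides.  The plateau rule
precedes the ratio rule because a plateau floor can carry any ratio; the
0.30 plateau threshold operationalizes "flat floor on both sides", for
which no published numeric criterion exists, and is exposed in
`ClassifierConfig` along with the other two thresholds.  A ratio of
exactly 1 (perfect symmetry) is assigned to uniformly concave.

## Synthetic endplates

Each archetype has a closed-form basis B on the chord with B = 0 at the
margins and max 1: a raised-cosine bump with configurable apex offset
(uniform/asymmetric), a clipped raised cosine with a central plateau
(flat-bottom, default plateau fraction 0.4), and the same bump at
sub-millimetre depth (flat).  A surface is the height field
h(x, y) = −(D_sag·B_sag(y) + D_cor·B_cor(x)) over an elliptical plate
(default semi-axes 25 mm AP × 17 mm lateral, a typical lower-lumbar
footprint; the reference cohort publishes no dimensions).  Because the
cross-plane term is constant along each mid-line, each mid-plane profile
realizes its target depth exactly, chord-relative.  The regular
resolution² grid is carried onto the ellipse by the area mapping
(x, y) = (a·p·√(1−q²/2), b·q·√(1−p²/2)), preserving exactly
2·(resolution−1)² triangles while the boundary is the exact ellipse.
Noise is additive Gaussian on vertex heights.

Cohorts draw five endplates per patient.  Per-segment class mixes
default to the reference cohort's observed form distributions; depths
are drawn U(1.15, 3.2) mm for concave classes and U(0.10, 0.85) mm for
flat ones, apex offsets U(0.12, 0.22) of the chord for asymmetric and
|offset| ≤ 0.03 for uniform — all at least 10% clear of the 1 mm and 1.3
decision boundaries so that ground-truth labels are well defined.
Surface noise defaults to 0.05 mm (sub-voxel for 0.75 mm CT slices on
smoothed meshes).  Each endplate's stream derives from
(seed, patient index, segment index), so cohorts are reproducible and
order independent.  The generator does not attempt realistic vertebral
anatomy (no cortical rim, no posterior elements) or CT noise physics:
recovery results bound measurement error of the chain on smooth
plate-like surfaces, not segmentation error on real CT.

## Statistics

* **Pooled t-test** from (n, mean, SD) summaries, with Cohen's d on the
  pooled SD and the t-based 95% CI of the mean difference.  The pooled
  (Student) rather than Welch form is used because the reference tables'
  printed t and d values follow the pooled formulas (verified in tests;
  Welch does not reproduce them).  Note that statistics recomputed from
  2-dp rounded summaries carry an input-rounding uncertainty of up to
  0.01/SE in t, which exceeds half a printed ulp for several rows.
* **Chi-square / Cramér's V**: all-zero rows and columns are removed
  first (otherwise expected counts of 0 make the statistic undefined);
  V = √(χ²/(N·(min(r′,c′)−1))) on the reduced table.
* **Freeman–Halton exact test**: exhaustive recursive enumeration of all
  tables with the observed margins; the two-sided p sums
  multivariate-hypergeometric probabilities ≤ the observed one, with
  1e-12 relative slack to absorb floating-point ties.  The enumeration
  budget (default N ≤ 200) keeps 2×4 tables instantaneous.  On 2×2
  tables the result equals Fisher's exact test (tested against an exact
  rational-arithmetic oracle and scipy).
* **ICC(A,1)** from the two-way ANOVA mean squares:
  (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)); zero between-subject
  variance returns 0 with a warning.  Cross-checked against pingouin.

## Reliability protocol

Human raters are emulated as perturbed measurement passes over 10
sampled patients (50 endplates): each pass draws its own margin-window
fraction (Gaussian jitter, SD 0.015 around 0.15) and adds Gaussian
landmark noise (SD 0.05 mm) to each measured parameter.  Inter-observer
ICC(A,1) compares rater 1 with rater 2; intra-observer compares rater 1
with its repeat pass.  With zero jitter and noise all ICCs are exactly 1;
with noise comparable to the between-endplate spread they drop markedly
(both tested).

## Numerical conventions and edge cases

* Vertex merge and chaining tolerance 1e-6 mm; on-plane tolerance
  1e-9 mm; degenerate-triangle area threshold 1e-9 mm².
* Margin-height ties prefer the outermost point.
* Profiles must be strictly increasing in s; a section that folds back
  is rejected as degenerate rather than silently reordered.
* Printed-value comparisons in tests use half a unit of the last printed
  digit, widened only by the propagated input-rounding bound described
  above.
* Binary STL files are validated against the 84 + 50·n byte layout
  before parsing, so truncation errors name the offending byte offset.

## Problem sizes

Default surfaces are 64×64 grids (7938 triangles).  The recovery studies
use 200-profile grids; the reliability protocol measures 50 endplates ×
3 passes; the ICC simulation uses 50 subjects × 2 raters.  The full test
suite runs in well under a minute, and the reproduction script in a few
seconds.

## Known limitations

* The anatomical frame must be supplied (or defaulted); the package
  cannot infer axes from an STL.
* The centroid cutting plane may miss the deepest point of a strongly
  off-centre depression; depth is then the mid-plane depth, consistent
  with profile-based measurement but not a global 3D maximum.
* SCD is measured perpendicular to the chord, not vertically; on tilted
  profiles these differ, and published protocols are ambiguous between
  the two.
* Classification accuracy is quantified only on synthetic smooth plates;
  segmentation artefacts, osteophytes and cortical-rim irregularities of
  real CT endplates are outside the generator's model.
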