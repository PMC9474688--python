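# Methods

## The measurement model

Every quantity this package computes is an *axial-plane anteversion*: the
signed angle, measured about the superoinferior (SI) axis of a femoral
anatomical frame, between the axial projections of a measured direction and
of the posterior condylar axis (PCA). The frame is built from eight named
landmarks: SI runs from the epicondyle midpoint to the femoral head center,
ML is the lateral→medial posterior-condylar direction orthogonalized
against SI, and AP = SI × ML (anterior positive, right-handed as
(ML, AP, SI)). Anteversion — the medial end of an axis tipped anteriorly —
is positive; retroversion negative. Left hips are mirrored through the
sagittal plane on load so one sign convention serves both sides. The ISB
thigh-frame recommendation motivates the axis roles but does not prescribe
this landmark recipe; the recipe here is a fixed, reproducible convention.

### AM-CT (axial-slice midcortical line)

The femur surface is cut with the axial plane `height` mm proximal to the
lesser-trochanter apex (5 and 10 mm by convention). On the resulting closed
contour, anterior and posterior cortex arcs are the longest contiguous
point runs whose outward normals lie within ±40° of the anterior/posterior
reference; a total-least-squares line (principal axis of the centered arc,
anchored at its centroid) is fitted to each, and the midcortical line is
their angular bisector (co-oriented unit directions summed and
normalized, anchored at the anchor midpoint).

The anterior/posterior reference is, by default, the normal of the
contour's own principal axis, oriented toward +AP. This emulates how a
reader traces the oblique cortical walls of a strongly anteverted neck; for
a section whose long axis is mediolateral it coincides with ±AP, and for
near-isotropic contours (principal-axis ratio < 1.05) it falls back to ±AP.
A fixed ±AP reference (`reference="ap"`) systematically under-reads high
anteversions, because the tangent of any smooth convex contour at its
AP extreme is mediolateral regardless of neck torsion.

Sections can also be taken from a binary pseudo-CT volume: the nearest
axial slice is Gaussian-smoothed (σ = 1 voxel, a sub-voxel boundary
estimate for binarized masks) and the 0.5-level marching-squares iso-contour
is used. At CT-like spacing (0.98 × 0.98 × 1 mm) this path agrees with
direct mesh slicing to well under a degree on generator femurs.

### PSA (stem anteversion)

The implanted stem's neck axis is supplied as data (in practice it would be
segmented from the postoperative scan); PSA is its axial angle against the
frame's ML axis, which equals the axial projection of the PCA by
construction. The round trip through the stem generator is exact to
numerical precision.

### The simulated osteotomy plane, AM-3D and AT-3D

The osteotomy plane passes through the piriformis-fossa center and the
calcar point (the most medial point of the axial section at the cutting
height). A plane needs a third constraint; here it also contains the AP
direction, making the cut anterior–posterior symmetric like a standard neck
cut, with the normal oriented proximally.

Because the plane contains AP, its in-plane axes are forced: one axis *is*
AP, and the other is simultaneously the in-plane projection of ML and of
−SI. In-plane coordinates are therefore u = v × normal (= +AP) and v = the
normalized projection of +SI ("in-plane superior"), so the inferomedial
(calcar) corner of the cut is the −v extreme and the superolateral
(piriformis) corner the +v extreme. Note the consequence: "medial" and
"inferior" cannot name two different margin directions on this plane — the
margins that *are* geometrically distinct are the two ends of the cut. The
3D midcortical line is accordingly the line through the centers of circles
fitted (Kåsa start, geometric Levenberg–Marquardt refinement) to the
contour arcs at those two ends; each arc is the contiguous run of contour
points within a 60° angular window (about the contour centroid) centered on
the extreme point in the margin direction. `fit_margin_circle` accepts
`"medial"`/`"inferior"` for the calcar end and `"superior"`/`"lateral"`
for the piriformis end.

IMI is the line–contour intersection with the smaller v (the inferior
crossing); exact v-ties resolve to larger u — an arbitrary but fixed rule.
The T-line runs from the trochanteric fossa to IMI, oriented like the
midline (lateral → medial), and AT-3D is its axial angle against the PCA.

**Known bias.** On the phantom geometry the oblique cut stretches the
contour along the plane's tilt, so the tip-to-tip midline *over*-reads the
neck azimuth (≈ +12° at 30° of anteversion at the 10 mm height), while
remaining exactly zero for a symmetric femur and strictly monotone in the
generator anteversion through 60°. Clinically the 3D-model measures are
reported as unreliable predictors with large biases of their own (the
midcortical line on 3D models under-reads the stem, the T-line over-reads
it by ~15°); this package treats the 3D measures as the defined geometric
constructions, not as calibrated estimators, and the cohort-level behavior
of all methods is carried by the statistical cohort generator below.

## Statistics

Per (method, height) cell, against PSA, with pairwise-complete deletion:
mean ± SD (n−1), MD = mean(method − PSA) and its SD, a paired two-tailed t
(t = MD/(SD/√n), n−1 df; identical pairs report p = 1, a constant nonzero
shift reports p = 0 with a warning), and Pearson r with its two-tailed p
from t = r√((n−2)/(1−r²)). Reliability is ICC(2,1) — two-way random
effects, absolute agreement, single rater — computed directly from the
two-way ANOVA mean squares, with ICC(3,1) (consistency) available; both
match `pingouin`'s ICC(A,1)/ICC(C,1) to 1e-9 in the tests. Rendered tables
print one decimal and floor p-values below 1e-15 at "0.000"; CSVs keep full
precision. Cells with fewer than 3 complete pairs raise rather than emit
unstable correlations. α = 0.05 throughout.

## The synthetic femur

Real meshes are unavailable, so the generator is the data source, built so
that ground truth is analytic rather than annotated. A femur is one lofted
watertight surface: axial cross-sections stacked along SI, blending
(smoothstep transitions) between a condylar block (ellipse 35 × 27 mm,
rotatable by a condylar-torsion parameter), a 14 mm shaft drifting
laterally toward the hip, an elliptical neck whose axial-section long axis
points along the anteversion azimuth (semi-axes 16 × 11 mm by default), and
a 22 mm head sphere centered on the SI axis. Greater/lesser trochanter
bosses are windowed radial bumps; the piriformis-fossa and
trochanteric-fossa landmarks are evaluated on the same analytic radius
function (the fossa's DDH-like posteriorization slides it along the
surface). The neck–shaft angle (130° default) sets the neck's rise and the
shaft's lateral offset.

Three construction choices matter for testing:

- the ring-sampling azimuths rotate with the neck azimuth, so two specs
  differing only in anteversion have proximal vertices related by exactly
  that rotation;
- quad diagonals alternate between the two theta half-ranges, making the
  triangulation mirror-symmetric, so a zero-anteversion femur with
  symmetric bosses is *exactly* symmetric and all measurements return
  exactly zero on it;
- ring levels are chosen to avoid the 5/10 mm measurement planes, keeping
  mesh–plane intersections generic.

Heights are measured from the lesser-trochanter apex (the bump's most
proximal point), a single well-defined reference exposed as a landmark so
either "base"- or "apex"-anchored conventions can be supplied externally.

The **geometric cohort** draws native anteversion from a truncated normal
(mean 29.8°, SD 17.7°, bounds −10°…70°), sets stem anteversion to the
native value plus N(0, 5°) surgical noise, and jitters sizes (shaft ±1 mm,
neck ±1/±0.8 mm, head ±1.5 mm, neck–shaft ±4°). The **statistical cohort**
draws, per hip, PSA ~ N(29.8, 17.7²) and each method cell from the
bivariate normal implied by its configured mean, SD and correlation with
PSA (conditional construction; methods are conditionally independent given
PSA). The shipped calibration (`data/table2_defaults.yaml`) carries the
28-hip DDH reference cohort's per-method moments and correlations; the
implied difference SDs emerge rather than being set (e.g. AM-CT@5:
√(15.3² + 17.7² − 2·0.86·15.3·17.7) ≈ 9.0 vs the reported 8.8).

What the generator does *not* emulate: cortical-thickness imaging contrast
(surfaces are single boundaries; the endosteal contour type is carried but
unused), Crowe-subtype-specific deformity beyond parameter ranges, metal
artifacts, and segmentation error. Passing tests therefore demonstrate the
correctness and stability of the geometric constructions and statistics on
idealized bone — not clinical accuracy on real CTs.

## Numerical choices

- Mesh–plane contours come from exact edge–plane crossings (trimesh);
  multi-loop sections keep the largest-area loop with a warning.
- Contours are CCW; cortex/margin arcs require ≥ 5 points; cortex-line fits
  reject near-isotropic point sets (axis ratio < 1.05); circle fits reject
  collinear input and interpolate 3 points exactly.
- Degenerate axial projections (axis within ~1e-6 of SI) raise errors
  naming the offending vector; frames reject condylar lines within 0.5° of
  SI.
- Angles live in (−180°, 180°]; internal precision is full double, reports
  round to one decimal.
- Voxelization fills each z-slice by even-odd rasterization of the section
  polygons at voxel centers — exact away from the surface, deterministic,
  and independent of ray-casting backends.
- Simulation sizes in the shipped checks (7-femur sweeps, 10,000-row
  cohorts, 100 × 28 replicates) keep the full suite in the tens of seconds
  while leaving sampling error far below the tested tolerances.

## Known limitations

- The osteotomy-plane margin conventions are this package's
  operationalization of an under-specified manual procedure; alternative
  third-plane constraints or margin pairings yield different (sometimes
  degenerate) AM-3D definitions.
- AM-3D/AT-3D biases on the phantom differ in sign and size from clinical
  reports; only their qualitative ordering (AT-3D > AM-3D, both monotone in
  anteversion) is designed in.
- At 28 hips, sampling spread of a correlation estimate (Fisher-z SD ≈ 0.2)
  exceeds the gaps between the calibrated per-method correlations, so the
  full correlation ordering reproduces in only ~70–80% of simulated
  cohorts; orderings separated by larger gaps (e.g. AM-CT vs AT-3D) are
  stable.
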