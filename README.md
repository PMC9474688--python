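# anteversion

Geometric and statistical pipeline for predicting **postoperative femoral
stem anteversion (PSA)** from proximal-femur landmarks, for orthopaedic
morphometry and surgical-planning research — particularly in developmental
dysplasia of the hip (DDH), where native anteversion can reach 60°.

In cementless total hip arthroplasty the stem's final anteversion is hard to
control, so preoperative landmarks are used to predict it. This package
implements the three landmark measurements used for that prediction, the
reference frame they share, the statistics that compare them, and a
synthetic femur generator that supplies ground truth:

- **AM-CT** — anteversion of the *midcortical line* (the angular bisector of
  total-least-squares lines fitted to the anterior and posterior cortices)
  on an axial CT-style section 5 or 10 mm proximal to the lesser-trochanter
  apex;
- **AM-3D** — anteversion of the midcortical line of a *simulated neck
  osteotomy plane* on the 3D surface model (the line through the centers of
  circles fitted to the inferomedial and superolateral margins of the cut);
- **AT-3D** — anteversion of the *T-line* from the trochanteric fossa to the
  IMI (the intersection of the osteotomy midcortical line with the inferior
  cut margin);
- **PSA** — anteversion of the implanted stem's neck axis.

All four are the signed angle, measured about the superoinferior (SI) axis
in the axial plane of an ISB-style femoral frame, between the measured
direction **d** and the posterior condylar axis (PCA):

    θ = atan2( SI · (p̂ × d̂_⊥),  p̂ · d̂_⊥ )

where `d̂_⊥`, `p̂` are the axial-plane projections of the direction and the
PCA. Anteversion is positive; left hips are mirrored into the right-side
convention on load.

The cohort layer reports, per method and cutting height, mean ± SD, the mean
difference MD = mean(method − PSA) with SD, a paired two-tailed t-test,
Pearson r with its p-value, and rater reliability as ICC(2,1) from the
two-way ANOVA decomposition.

## Worked example

```python
import anteversion as av

# a synthetic DDH-range femur with 30 degrees of native anteversion
mesh, landmarks, truth = av.generate_femur(av.FemurSpec(nfa_deg=30.0))
frame = av.build_femoral_frame(landmarks)

print(av.am_ct(mesh, frame, landmarks, 10.0).angle_deg)   # 30.000
print(av.am_3d(mesh, landmarks, frame, 10.0).angle_deg)   # 42.24
print(av.at_3d(mesh, landmarks, frame, 10.0).angle_deg)   # 67.12

stem = av.generate_stem(av.StemSpec(stem_anteversion_deg=25.0), landmarks)
print(av.psa_from_stem(stem, frame).angle_deg)            # 25.000000000
```

AM-CT recovers the generator's anteversion essentially exactly on this
idealized geometry; the osteotomy-plane measures read high on the same
femur (the oblique cut stretches the contour, see `docs/methods.md`), which
mirrors the clinical finding that the T-line substantially over-reads the
stem's final anteversion.

The same measurements are available from a shell:

```sh
anteversion simulate --mode geometric --n 28 --seed 42 --out-dir cohort/
anteversion measure --mesh cohort/subject001.stl \
    --landmarks cohort/subject001_landmarks.json --method am-ct --height 10
anteversion simulate --mode statistical --n 28 --seed 42 --out-dir stats/
anteversion stats --in stats/cohort.csv --out stats/summary.csv
```

`anteversion stats` prints a per-method table (angle, difference vs PSA,
t-test p, r, Pearson p) in the standard report layout.

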