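# Methods

## Problem and geometry

On an AP pelvic radiograph the circular opening of an implanted acetabular
cup projects to an ellipse. Under parallel-ray projection of a circle of
radius r whose opening-plane normal n makes angle u with the film plane,
the projected ellipse has semi-major axis a = r and semi-minor axis
b = r·sin u, with the major axis perpendicular to the in-film component of
n. Two planar readings follow:

- radiographic anteversion `u = arcsin(b/a)` (McLaren), and
- Liaw's trigonometric anteversion `arcsin(tan βp)`, where βp is the angle
  at a major-axis endpoint between the major axis and the chord to the
  adjacent minor-axis endpoint, so `tan βp = b/a`.

The two are the same function of the axis ratio (`tan(arctan x) = x`); the
βp construction exists because βp can be read with a protractor off two
drawn chords. The cup inclination (abduction) w is the acute angle between
the major axis and the pelvic horizontal — the trans-teardrop line.

Coordinates: raster convention, x right, y down, angles of image lines in
[0, 180) against the x-axis. Ellipses are stored by center, semi-axes
(constructor swaps axes and rotates by 90° if given b > a, keeping
βp ≤ 45° by construction) and major-axis orientation. Rim overlays are
drawn as a closed 64-sided polygon sampled at uniform parametric angle,
the traditional drawing scheme for this measurement; at n = 64 the polygon
area differs from πab by < 0.3%.

## Standardization for patient positioning

A planar reading depends on how the pelvis was positioned: tilt θ (about
the transverse, trans-teardrop axis) and axial rotation φ (about the
craniocaudal axis) change the projected ellipse. All 3D work happens in a
*measured-side frame*: e1 along the trans-teardrop line toward the
measured acetabulum, e2 superior, e3 anterior. The forward pose is
`R = R_e2(φ) · R_e1(θ)` (tilt applied first); θ > 0 moves the superior
direction anteriorly. The φ sign convention is per-side, which keeps every
formula side-agnostic.

**Pose from landmarks.** The 3D segment from the symphysis upper pole (SP)
to the sacrococcygeal junction (SCJ) has calibrated length `ssd` and, in
the standardized reference position, sits in the midsagittal plane at
projected height `neutral_v` above SP, giving the reference vector
`(0, neutral_v, −d)` with depth `d = sqrt(ssd² − neutral_v²)` (SCJ
posterior to SP). Its projected displacements, decomposed in the
trans-teardrop frame with the sign conventions *h positive toward the
measured acetabulum* and *v positive superior*, are

    v = neutral_v·cos θ + d·sin θ          (independent of φ)
    h = sin φ · (neutral_v·sin θ − d·cos θ)

so θ is recovered from v alone (as `arcsin(v/ssd) − arcsin(neutral_v/ssd)`)
and φ from h given θ. The tilt equation has two solutions; the default
branch keeps the smaller |θ| (small tilts are the common clinical case),
with a config switch for the other branch. Inputs with h² + v² > ssd² are
rejected as inconsistent with the calibrated ssd. Given the consistency
precheck, the φ equation always has a real solution on the default branch;
the no-solution guard is defensive numerics.

**Un-rotating the cup axis.** From a film we take u and w off the fitted
ellipse, rebuild the cup-axis unit vector in film coordinates — in-plane
component `cos u` perpendicular to the measured major axis and pointing
toward the measured acetabulum, out-of-plane component `sin u` anterior —
apply `R_e1(−θ)·R_e2(−φ)`, and report `arcsin` of the anteroposterior
component. At identity pose this returns u exactly.

**Anterior/posterior ambiguity.** A projected ellipse is identical for cup
axis n and −n, so the sign of the out-of-plane component cannot be read
from the ellipse itself. With small anteversion, high inclination and
adverse tilt the projected axis can genuinely point posterior. The
annotation schema therefore carries an optional `apparent_retroversion`
flag (the reading a clinician makes from cross-over and rim cues); the
simulator emits it from ground truth and the measurement honours it,
defaulting to the anteverted appearance. With the flag, noiseless recovery
is exact (to numerical precision ~1e−6°) over anteversion 5–60°,
inclination 30–60°, tilt ±15°, rotation ±10°.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ssd` | 100 length units (px at unit spacing) | calibrated 3D SP–SCJ length; a single AP film only yields projected h, v, so the depth `sqrt(ssd² − h² − v²)` needs the true length. Calibratable per patient from a film designated neutral. |
| `neutral_v` | 30 | projected v in the reference position; defines the reference orientation of the SP–SCJ segment. |
| `tilt_branch` | `min` | which of the two tilt solutions to keep. |
| pixel spacing | 1 (or DICOM PixelSpacing) | h, v, ssd must share units; only ratios enter the trigonometry, so the unit cancels when ssd is calibrated in the same units. |

Angles are reported in degrees everywhere; trigonometry is done in
radians internally.

## Ellipse fitting

Rim points are fitted with the numerically stable direct least-squares
conic fit constrained to an ellipse (Halir–Flusser formulation of the
Fitzgibbon method), after centering/scaling for conditioning. The
ellipse-specific constraint matters because cup rims are typically partial
arcs (the femoral head obscures part of the rim) where an unconstrained
conic fit can return a hyperbola. Arcs below 120° of span trigger a
logged warning — the fit is still returned but its variance grows sharply.
Geometric parameters come from the eigen-decomposition of the quadratic
form; orientation is reported in [0, 180). Exact 64-point inputs are
recovered to ~1e−15 relative error; 1 px Gaussian click noise on a
100×50 px ellipse keeps semi-axes within ~1%.

## Synthetic films: what they do and do not emulate

The simulator provides the study conditions: cohorts sampled uniformly
over anteversion 5–60°, inclination 30–60°, tilt ±15°, rotation ±10°
(typical postoperative cup positions and realistic positioning scatter),
with a default landmark model of teardrops 120 px apart, SP 30 px inferior
and 40 px anterior to the teardrop plane, ssd = 100, neutral_v = 30 —
adult AP-pelvis geometry at roughly 1 px/mm. Human annotation error is
modeled as isotropic Gaussian noise (default 1 px where noise is used) on
every clicked coordinate — landmarks and rim points — never on derived
quantities, since clicking error is exactly what the repeated-SD statistic
quantifies. Repeated-film cohorts fix each patient's cup and redraw pose
and noise per film, emulating serial radiographs of a stable implant.

The projection is orthographic by default; the planar formulas themselves
are stated in parallel-ray terms and clinical source-film distances are
large relative to cup size. A point-source perspective mode
(`source_distance`) exists for sensitivity experiments; at 10⁷ px it
matches the orthographic ellipse to 1e−4 relative. Not modeled:
photorealistic bone texture and scatter, femoral-head occlusion beyond
restricting the rim-point arc span, soft-tissue-dependent landmark
visibility, and anatomic variation of the landmark model between patients.
Passing tests therefore demonstrate the geometric correctness and noise
behaviour of the measurement chain, not clinical reading variability;
clinical RSD values depend on observers and image quality and cannot be
reproduced from synthetic films.

## Statistics

The repeated standard deviation pools within-patient spread:
`RSD = sqrt(Σ_j Σ_i (X_ij − X̄_j)² / Σ_j (n_j − 1))`. Patients with a
single film contribute 0/0 and are skipped (count logged); if no patient
has a repeat, RSD is undefined and an error is raised. The 2×RSD
change threshold is implemented literally as a doubling (the conventional
~95% level under approximate normality; no further distributional claim is
made). Observer agreement uses scipy's paired t-test; zero-variance
differences are flagged degenerate with NaN statistics rather than a
fabricated p-value. p-values print to 3 decimals.

On synthetic repeated cohorts with 1 px noise and free pose, the
radiographic RSD is dominated by positioning scatter (several degrees)
while the standardized RSD reflects mostly click noise propagated through
the fit and pose correction (~1–1.5°); the ordering RSD(standardized) <
RSD(radiographic) holds in every replicate at the default conditions.

## Numerical notes and limitations

- `arcsin` conditioning diverges as b/a → 1 (cup face-on), so ulp-level
  differences in the axis ratio move the angle by up to ~1e−7° there; the
  βp = 45° boundary is handled exactly (tan 45° = 1 analytically).
  Conversely d(arcsin)/dx is flattest near 0, so anteversion precision is
  best for small-to-moderate anteversion.
- Problem sizes in the validation suite — 500-film recovery sweeps, 50
  replicate cohorts of 8 patients × 3 films, 64-point rim annotations —
  were chosen as the smallest sets that exercise the full parameter ranges
  with stable statistics; all complete in seconds.
- Anteversion is reported as a magnitude in [0, 90]; true retroversion
  versus anteversion of the *anatomical* axis is outside what a single AP
  film determines and is left to the `apparent_retroversion` flag plus
  clinical context.
- The pose model uses exactly the three named landmark structures; films
  where symphysis, SCJ, or either teardrop is not identifiable cannot be
  standardized (the planar readings remain available).
- `measure_film` assumes the annotation's rim points and landmarks come
  from the same film and spacing; mixing calibrated and uncalibrated
  lengths invalidates the pose estimate.
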