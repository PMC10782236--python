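# Methods

## The measurement problem

An acetabular cup's opening is a circle of radius `r`. Under a
(near-)parallel x-ray beam along the film normal `z`, a circle with unit
normal `n` projects to an ellipse with semi-major `a = r` and semi-minor
`b = r·|n_z|`, so `arcsin(b/a)` recovers the angle of the cup plane to the
beam — the *planar version* — but not the sign of `n_z`: anteverted and
retroverted cups of equal magnitude are radiographically identical on one
film. On top of that, the pelvis is rarely in a neutral pose: sagittal
flexion (tilt) rotates the cup normal relative to the beam, so the planar
version measured on film is not the anatomical version either.

`cupversion` addresses both problems with landmarks only:

* the **inter-teardrop line** (ITL) is the pelvic horizontal reference;
* the **pelvic radiographic axis** — sacrococcygeal-junction midpoint (SCJ)
  to the upper pole of the pubic symphysis (PS) — is the standardization
  reference whose direction and foreshortening encode the in-plane rotation
  and sagittal flexion of the pelvis.

## Coordinate conventions

Film/pelvic frames: `x` toward the patient's left, `y` superior, `z`
anterior (out of the film, toward the tube). Angles in degrees. The cup
normal for inclination `I`, signed version `V` on side `s` (+1 left, −1
right) is

```
n = ( s·sin I·cos V,  −cos I·cos V,  sin V )
```

(the opening faces infero-laterally; `V > 0` tips it anteriorly). Pose is
applied as `R = Rz(rotation) · Ry(obliquity) · Rx(flexion)`: flexion about
the inter-teardrop axis (positive tips the superior pelvis anteriorly),
obliquity about the vertical axis, rotation an in-plane roll about the beam
axis.

## Ellipse fitting

Rim points are fit by direct least squares on the conic
`Ax² + Bxy + Cy² + Dx + Ey + F = 0` under the constraint `4AC − B² = 1`,
in the numerically stable block form, after centring/scaling the points for
conditioning. The constraint guarantees an ellipse even for noisy short
arcs, which digitized cup rims often are. Exact samples are recovered to
~1e−12 relative; with 0.2 mm isotropic noise on 60 points the semi-axes are
recovered well within 0.5 mm (Monte-Carlo over 100 seeds; worst ≈ 0.17 mm).
A circle has no preferred axis: its orientation is reported as 0° so
results are deterministic. A circular fit also means the cup faces the beam
dead-on; `planar_version` then returns 90° with a warning rather than
raising, leaving the plausibility call to the caller.

## Pose estimation

*Rotation* is the signed angle of the projected pelvic axis from the film
inferior direction; in the forward model this equals the in-plane roll
exactly, independent of flexion (a pure roll turns the axis and the ITL
together, so the axis-vs-ITL-perpendicular angle carries no roll
information — it responds only to out-of-plane obliquity, which this method
does not correct).

*Flexion* cannot be resolved from a single AP film without an anatomical
prior. The prior used: the SCJ→PS axis has a neutral sagittal inclination
`φ0` out of the coronal plane, and its projected length, normalized by the
inter-teardrop distance (the only transverse internal scale unaffected by
flexion), follows

```
axis_ratio(f) = neutral_axis_ratio · cos(f − φ0) / cos(φ0)
```

Inverting the cosine gives two candidates `φ0 ± arccos(·)`; the smaller in
magnitude is reported, which is correct whenever `|flexion| < φ0` (≈ 37°
for the default anatomy — comfortably beyond clinical posing error). A
measured ratio beyond the solvable maximum by more than 5% (relative)
raises an error carrying the clamped value; within tolerance it is clamped.
Both `φ0` and the neutral ratio are derived from the anatomy model's
landmark coordinates, so the prior is always self-consistent and is
configured by moving the landmarks.

## Standardized paired versions

The fitted ellipse constrains the 3D cup normal completely except for the
sign of its out-of-film component: both candidates share the in-film
component (perpendicular to the major axis, magnitude `cos(planar
version)`, oriented laterally toward the operated side) and differ in the
out-of-film component `±sin(planar version)`. Each candidate is rotated
back into the standardized pelvic frame — undo the roll, then the flexion
about the (de-rolled) inter-teardrop axis — and its **standardized
version** is the signed angle of the normal above the standardized coronal
plane (equivalently 90° minus the angle between the normal and the
standardized beam axis). At neutral pose the pair is exactly
`(+planar_version, −planar_version)`.

The pair is reported as `(liaw_v1, liaw_v2) = (larger, smaller)` candidate.
Generically `v1 > 0 > v2` (anteversion/retroversion candidates), but when
pelvic tilt exceeds the cup's version — the boundary is
`tan(flexion)·cos(inclination) = tan(version)` — both candidates
standardize to the same sign. That is a geometric fact, not a failure: it
means the single film already excludes one sign. The type therefore only
enforces `v1 ≥ v2`.

## Two-film decision

The true candidate's standardized value is a property of the cup; the ghost
candidate's value moves with pose. Given two films in different poses, the
rule ranks the cross-film candidate pairs by absolute difference and takes
the most mutually consistent pair: its mean is the final signed version and
its sign the label. When each film's candidates straddle zero this is
exactly the classical comparison — "is the anteversion-assumed difference
or the retroversion-assumed difference smaller?" — and the reported
`delta_ante = |v1₁ − v1₂|` and `delta_retro = ||v2₁| − |v2₂||` are those
two differences. Evaluating all pairings additionally handles the
same-sign-candidate poses above, where the consistent value can migrate
between slots between films.

Tie handling: if the best pair beats the runner-up by ≤ `tie_tol_deg`
(default 0.1°), or the winning mean is within `tie_tol_deg` of zero, the
outcome is **indeterminate** — a first-class result. Two films in identical
poses are by construction indeterminate; a warning is raised whenever the
films' estimated 3D pelvic-axis directions differ by less than
`min_separation_deg` (default 1°). The separation is computed between 3D
axis orientations implied by the pose estimates because the projected axis
*direction* alone is blind to flexion differences (flexion foreshortens the
axis without turning it).

The final angle is the arithmetic mean of the winning pair: symmetric in
the films and unbiased when both films carry equal error.

## The synthetic-data generator

The simulator is the package's validation instrument: a bilaterally
symmetric pelvis (inter-teardrop width 130 mm; SCJ posterosuperior at
(0, 45, −50) mm and PS anteroinferior at (0, −50, 22) mm on the
mid-sagittal plane, giving `φ0 ≈ 37.2°` and a neutral axis ratio ≈ 0.73;
cup radius 25 mm — adult-scale dimensions), a cup-opening circle placed at
the true (inclination, signed version), per-film pose rotations,
orthographic projection, and seeded isotropic Gaussian noise added to the
projected landmarks in film mm (emulating annotation/click error, the
dominant error source for landmark methods). Noise draws depend only on
`(seed, film_index)` — not on the noise level — so noise studies compare
levels with common random numbers and every run is bit-reproducible.
Defaults: 12 rim points (a realistic digitization effort), left side,
noiseless.

What the simulator does **not** emulate: pelvic asymmetry (the
standardization assumes a symmetric pelvis, a known limitation of the
method), beam divergence by default (an optional point-source distance adds
perspective for robustness experiments only), occlusion/partial rim arcs,
and reader-specific systematic bias. Passing tests therefore demonstrate
self-consistency of the measurement model and its noise robustness, not
accuracy on real, possibly asymmetric anatomy.

## Validation studies and sizes

* **Ellipse recovery**: 36–72-cell parameter grids, 60 points per ellipse,
  noiseless → 1e−6 relative recovery (observed ~1e−12).
* **Forward–inverse grid**: inclination {30, 40, 50}° × signed version
  {−25…+25}° in 5° steps × film-1 flexion {−10, 0, +10}° × rotation
  {−5, 0, +5}°; film 2 at flexion +7° and rotation +3° relative to film 1
  (a deterministic, clinically plausible re-positioning). Cells with
  |version| < 3° are simulated but not scored (the sign of a near-zero
  version is not meaningful). Noiseless result: 100% sign accuracy and
  winning-angle error < 1e−7° over 270 scored cells.
* **Noise study**: true version +15°, inclination 40°, films at flexions
  −5°/+8°, noise sd {0, 0.5, 1, 2} mm, 200 replicates per level with
  replicate seeds shared across levels. Misclassification (wrong sign or
  indeterminate) is 0 at sd 0 and non-decreasing in the noise level.

## Known limitations

* Flexion recovery relies on the anatomical prior; a patient whose SCJ→PS
  geometry differs from the model biases the flexion estimate and hence the
  standardized angles (the decision *label* is more robust, since it needs
  only inter-film consistency).
* Out-of-plane obliquity is simulated but not corrected; it contaminates
  the roll estimate through the axis direction.
* Orthographic projection ignores magnification; with a real point source,
  angles are only approximately preserved.
* Version magnitudes near 0° and poses with the cup plane near-parallel to
  the beam are intrinsically degenerate (warnings are raised).
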