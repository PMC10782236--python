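# cupversion

Acetabular cup orientation from plain AP pelvis radiographs — including the
one thing single-film methods cannot do: telling **retroversion** apart from
**anteversion**.

After total hip arthroplasty the cup's orientation (radiographic inclination
and version) is measured on follow-up AP radiographs. The cup opening is a
circle in 3D; on film it projects to an ellipse with semi-axes `a ≥ b`, and
the classic relation

```
planar version = arcsin(b / a)
```

gives the version **magnitude** only: an anteverted cup and its retroverted
mirror image produce the *same* ellipse. `cupversion` implements the
standardized paired-angle approach: each film yields two candidate version
angles — θ assumed positive (anteversion candidate, `liaw_v1`) and θ assumed
negative (retroversion candidate, `liaw_v2`) — referenced to a standardized
pelvic frame built from the inter-teardrop line (the pelvic horizontal) and
the pelvic radiographic axis (sacrococcygeal-junction midpoint → upper pole
of the pubic symphysis). The true candidate is a property of the cup alone;
the ghost candidate drifts with pelvic pose. Comparing **two films taken in
different pelvic poses**, the candidate pair with the *smaller* inter-film
difference is the physically real one, which fixes the sign.

The package works entirely from landmark annotations (no pixels): ≥5 points
on the cup-opening rim, both teardrops, the sacrococcygeal junction and the
pubic symphysis. A built-in forward projector simulates those annotations
from a parameterized 3D pelvis with known ground truth, so the whole
measurement chain is validated end-to-end without any imaging data.

## Worked example: the printed two-film pair

Feeding the decision rule a published pair of film measurements,
(+23.81°, −9.52°) and (+18.86°, −8.56°):

```python
from cupversion import CupMeasurement, decide_version

m1 = CupMeasurement.from_version_pair(23.81, -9.52)
m2 = CupMeasurement.from_version_pair(18.86, -8.56)
d = decide_version(m1, m2)
print(d.delta_ante_deg, d.delta_retro_deg, d.label, d.final_version_deg)
# 4.950000000000003 0.96 retroverted -9.04
```

The retroversion-assumed difference (9.52 − 8.56 = 0.96°) is much smaller
than the anteversion-assumed difference (23.81 − 18.86 = 4.95°), so the cup
is called retroverted, at −9.04° (mean of the consistent pair).

## Worked example: synthetic films with known truth

```console
$ cupversion simulate --version -12 --flexion1 -5 --flexion2 8 \
      --noise-sd 0.3 --seed 11 --out study.json
two synthetic films written to study.json
$ cupversion measure study.json
film 1 (left): inclination=39.37 planar_version=7.70 v1=+3.88 v2=-11.49 (pose: rot=0.17 flex=-4.93)
film 2 (left): inclination=41.12 planar_version=17.98 v1=+23.38 v2=-12.45 (pose: rot=-0.53 flex=7.26)
$ cupversion decide study.json
film 1: v1=+3.88 v2=-11.49 | film 2: v1=+23.38 v2=-12.45
delta_ante=19.50 delta_retro=0.96
label=retroverted final_version_deg=-11.97
```

The simulated cup is truly retroverted at −12°; the two films were taken at
pelvic flexions −5° and +8° with 0.3 mm landmark noise. Note how strongly
the raw planar versions differ between the films (7.70° vs 17.98° — pelvic
tilt at work) while the retroversion candidates agree (−11.49° vs −12.45°):
that agreement is the signal. `cupversion recover-grid` runs the full
validation grid (297 orientation × pose cells) and prints the sign accuracy
and worst winning-angle error.

## Annotation format

JSON, schema version 1, one or more films per file:

```json
{
  "schema_version": 1,
  "films": [
    {
      "left_teardrop": [65.0, 0.0],
      "right_teardrop": [-65.0, 0.0],
      "scj": [0.0, 45.0],
      "ps": [0.0, -50.0],
      "rim_points": [[60.0, 10.0], [48.0, 22.0], [36.0, 10.0], [48.0, -2.0], [56.0, 18.0]],
      "side": "left",
      "scale_mm_per_unit": 1.0
    }
  ],
  "provenance": "free text"
}
```

Coordinates are film units (x toward the patient's left, y superior);
`scale_mm_per_unit` converts to mm. Angles are scale-invariant.

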