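# femnsa — automatic femoral neck-shaft angle measurement

The femoral neck-shaft angle (NSA) — the angle between the long axis of
the femoral neck and the long axis of the femoral shaft — is a key
parameter for diagnosing hip disease (coxa vara / coxa valga) and for
planning total hip arthroplasty.  Manual measurement on radiographs is
poorly repeatable, and 2D projections and 3D reconstructions do not
obviously agree because the fitted neck and shaft axes are usually
*skew* lines in space.

`femnsa` implements two fully automatic NSA measurements on
region-labeled femoral point clouds (head / neck / shaft, coordinates in
mm), of the kind produced by CT reconstruction followed by point-cloud
segmentation:

- **3D method** — fit a sphere to the head points by linear least
  squares (center **c**, radius from the RMS residual); the neck axis is
  the line from the neck centroid **p**ₙ to **c**; the shaft axis joins
  the centroids of the 60–70% and 70–80% slabs of the shaft length; the
  NSA is θ = arccos(**A**·**B** / |**A**||**B**|) between the two axis
  directions.  Because the axes are generally skew, their
  closest-approach distance is reported as a diagnostic.
- **2D method** — simulate the anteroposterior hip radiograph: build the
  plane through the head-sphere center, the neck centroid and the
  centroid of the distal 10% of the shaft (this plane approximately
  contains both axes, counterbalancing femoral anteversion); project all
  points onto it; recover the projected head center with a RANSAC circle
  fit (trial count S = ⌈log(1−P) / log(1−ρᴷ)⌉) on the projected head's
  silhouette; measure the same angle between the in-plane axes.

A parametric synthetic-femur generator with analytically known NSA,
anteversion and neck–shaft axis offset provides exact ground truth, and
an evaluation module supplies the Dice / mean-IoU segmentation metrics,
angle error/accuracy statistics and the two-sample Student's t-test used
to compare measurement methods.

## Worked example

```python
from femnsa import NeckShaftAngleModel
from femnsa.synthetic import FemurSpec, generate_femur

cloud, truth = generate_femur(FemurSpec(nsa_true=126.0, anteversion=12.0, seed=42))
res = NeckShaftAngleModel(cloud).fit(method="both")
print(res.summary())
```

```
Neck-Shaft Angle Measurement
============================================================
specimen: synthetic_seed42    points: 2048
------------------------------------------------------------
method       NSA (deg)  diagnostics
3d             124.875  closest_approach_mm=0.017, head_radius_mm=22.013
2d             124.639  head_circle_radius_mm=22.056, head_circle_inliers=58, head_sphere_radius_mm=22.013
------------------------------------------------------------
|2D - 3D| difference: 0.237 deg
============================================================
```

The femur was generated with a true NSA of 126.0° and surface noise of
0.3125 mm (half a typical CT voxel); both methods land within ~1.1° of
the truth and agree with each other to 0.24°.  `closest_approach_mm`
is the minimal distance between the fitted neck and shaft axes (≈0 here
because the generator placed them coplanar); the head diagnostics show
that the RANSAC circle on the projection recovered the same head radius
as the 3D sphere fit.

The same pipelines are available from the shell:

```sh
femnsa synth --n 5 --seed 7 --nsa 126 --out clouds/      # labeled PLYs + truth manifest
femnsa measure --input clouds/femur_0007.ply --method both --out results/
femnsa eval --csv angles.csv --ref-col nsa_manual --cand-col nsa_3d
```

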