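# ruminant3d

Simulated one-shot multi-depth-camera 3D phenotyping of cattle:
watertight synthetic cow bodies with known ground truth, a simulated
acquisition-and-fusion chain, triangulated-mesh morphometry, published
body-weight prediction equations, and the repeatability /
reproducibility statistics used to validate such devices.

## Who this is for

Morphometric traits of dairy cattle — withers height, hip and buttocks
width, girths, body surface and volume — are increasingly measured by
3D scanners rather than tape and gauge. One-shot devices trigger a
fixed rig of depth cameras simultaneously, fuse the 15 depth images
into a point cloud, reconstruct a watertight mesh and measure the
traits on it. Validating such a pipeline requires animals, a scanner
and a reference device. This package replaces all three with testable
software: a parametric cow-like body whose traits are known
analytically, a camera-physics simulation of the acquisition chain,
and the full measurement-and-statistics stack, so every stage can be
checked against ground truth.

## The measurements and models

Traits are computed from a watertight triangle mesh plus named
anatomical feature points (the "clicked" landmarks of interactive
measurement software): WH (withers height above the ground plane), HW
and WB (hip and pin-bone widths), DL (diagonal length), CD (chest
depth), HG and AC (heart girth and abdominal circumference as
taut-tape convex-hull perimeters of transverse sections), PS/PV
(surface and volume between cutting planes at the shoulder blades and
the rump) and TS/TV (whole-body surface and volume). Mesh volume is
the divergence-theorem sum over triangles; partial bodies are produced
by plane clipping with planar fan caps.

Published linear equations convert partial to total measurements and
predict body weight:

    TV = 1.0704 · PV + 0.015              [m³]
    TS = 1.07   · PS + 0.94               [m²]
    BW = 644·TV + 408·HW + 271·WB − 199   [kg]  (TV in m³, HW/WB in m)

Measurement variability is quantified per trait by the residual SD σ
of a one-way ANOVA with the animal as factor, the coefficient of
variation CV% = 100·σ/mean, and the 95 % repeatability /
reproducibility limit r = 1.96·√2·σ ≈ 2.772·σ; a CV below 4 % is the
conventional quality threshold.

## Worked example

```sh
ruminant3d make-cow --preset adult --resolution 4 \
    --out cow.ply --landmarks lm.csv
ruminant3d measure --mesh cow.ply --landmarks lm.csv --out traits.csv
```

prints

```
wrote cow.ply: 59596 faces, volume 0.7939 m^3
```

and `traits.csv` contains (abridged):

```
trait,value,unit
wh,1.454,m        # withers height
hw,0.593,m        # hip width
cd,0.837,m        # chest depth
ac,2.430,m        # abdominal circumference
ts,6.635,m2       # total surface
tv,0.794,m3       # total volume (793.9 L)
pv,0.598,m3       # partial volume between the cutting planes
```

The default adult preset is calibrated so that a fleet of such animals
reproduces the published adult-cohort means (TV 764 L, TS 7.20 m²,
WH 1.454 m, HW 0.575 m, WB 0.537 m, CD 0.811 m, AC 2.632 m) within
10 %. Feeding the heifer-cohort mean traits to the body-weight
equation gives

```sh
ruminant3d predict-bw --traits heifer_means.csv --out bw.csv
# -> bw_kg = 519.55   (inside the 440-550 kg weigh-scale range)
```

The full study — repeatability and reproducibility panels, a
reference-vs-simulated-device comparison and a body-weight validation
cohort — runs from one config:

```sh
ruminant3d run --out study_out     # writes CSV tables + report.md
```

In Python, the same pieces compose directly:

```python
from ruminant3d import herd, capture, morphometry

params = herd.adult_cow_params()
mesh = herd.make_cow_mesh(params)                 # watertight body
rig = capture.default_rig()                       # 15-camera gantry
fused, cloud = capture.simulate_scan(mesh, rig, seed=0)
traits = morphometry.measure_all(fused, herd.true_landmarks(params))
```

On the default preset the simulated chain (render → 2 mm depth
quantisation → bilateral smoothing → merge → implicit-MLS
reconstruction) recovers the source-mesh volume to well within 3 %.

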