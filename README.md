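# viewflow

Why do some views of an object look special? People discriminate small
rotations best around an object's *cardinal* axes (its front and back), and
when asked to point out "the front" of a shape they have never seen, their
choices are far from random. `viewflow` implements a simple, biologically
plausible account of both phenomena: the cost of telling two views apart is
governed by the **ground-truth optical flow** the rotation would produce in
the image — how far the object's visible surface points travel on the
retina as it turns.

The package is a library for researchers in visual psychophysics and
computational perception. It provides:

* **The flow model.** For a triangulated 3D object at azimuths θ and θ+Δ,
  corresponding surface points are the mesh vertices themselves (posing
  preserves vertex order); a vertex contributes only if it is visible in
  *both* poses (per-vertex ray casting against the mesh); the dissimilarity
  is the mean absolute projected displacement of the matched vertices,

      D(θ, θ+Δ) = mean over matched vertices v of |Π(R_{θ+Δ} v) − Π(R_θ v)|

  with Π orthographic (or pinhole) projection and the mean taken over the
  pooled horizontal and vertical components (a mean-vector-length variant is
  selectable). Evaluating D between each of 72 viewpoints (5° apart) and its
  neighbour gives the circular **optical-flow curve** f(θ); its local
  gradient f′(θ), the segment slopes, and its range max f − min f are the
  behavioural predictors.
* **The discrimination analysis chain**: trial exclusions (reaction-time
  window, 75% performance floor), psychometric tables, the per-object
  **cardinal axis effect** (difference between cardinal and non-cardinal
  axes in the slope of P("different") between 0° and 5° rotations), a
  feasible-GLS factorial model with AIC-selected residual-variance
  structure, and the paired-t / regression / exact-Wilcoxon toolbox that
  links model predictors to behaviour.
* **Circular analysis of "front" judgements**: mean resultant length,
  circular mode, the 45°-tolerance exclusion rule, and the comparison of
  flow-curve |gradient| at chosen-front versus never-chosen viewpoints.
* **A synthetic-data generator**: procedural meshes with controllable
  elongation, mirror symmetry and n-fold rotational symmetry (honoured
  exactly, by construction), plus simulated observers — a Weibull
  psychometric link from model dissimilarity to same/different responses,
  and gradient-weighted front choices — so the entire pipeline runs and is
  testable without any external stimuli.

## A worked example

```python
from viewflow import flow_curve, curve_gradient, curve_range
from viewflow.synthetic import ShapeSpec, design_from_curve, generate_mesh

mesh = generate_mesh(ShapeSpec(family="superquadric", elongation=2.5,
                               resolution=350, seed=11, exponents=(1.0, 0.9)))
curve = flow_curve(mesh)            # 72 values, circular
design = design_from_curve(curve)   # front/back at curve extrema
```

Running `python examples/01_flow_curve_of_a_shape.py` prints:

```
mesh: 360 vertices, 716 faces (unit radius)
flow curve: 72 values in [0.0072, 0.0201] object-radius units per 5° step
curve range (max - min): 0.0129
  front           (cardinal    ) at   355°: flow 0.0201, gradient +0.00000 per degree
  back            (cardinal    ) at   175°: flow 0.0201, gradient -0.00000 per degree
  non-cardinal-1  (non-cardinal) at    40°: flow 0.0150, gradient -0.00018 per degree
  non-cardinal-2  (non-cardinal) at   220°: flow 0.0150, gradient -0.00018 per degree
```

Flow is in object-radius units per 5° step: the end-on (cardinal) views of
this elongated object produce the most image motion per degree of rotation
(hence the best discrimination) while sitting exactly at the flat extrema
of the curve. `python examples/03_discrimination_experiment.py` runs a full
simulated experiment (13 objects × 50 observers) and prints the group
psychometric means, the cardinal axis effect (`mean +0.0288 per degree,
positive for 13/13 objects`) and the regression of per-object effects on
the cardinal/non-cardinal gradient difference
(`F(1,11) = 27.74, p = 0.00027, R^2 = 0.72`).

There is also a thin CLI for batch runs over mesh directories and trial
tables: `viewflow flow-curves`, `exp1-analyze`, `exp2-analyze`, `simulate`,
`full-demo` (see `viewflow --help`).

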