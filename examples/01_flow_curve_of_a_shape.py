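"""Compute the optical-flow curve of a procedurally generated object.

Builds an elongated, mirror-symmetric superquadric, measures the projected
displacement of its visible vertices between each of the 72 viewpoints and
its 5°-rotated neighbour, and reports where the curve peaks and how steep
it is at the labelled views. High flow = views that change a lot when the
object turns (easy to discriminate); near-zero gradient marks the special
front/back views sitting at the curve's extrema.
"""

import numpy as np

from viewflow import curve_gradient, curve_range, flow_curve
from viewflow.synthetic import ShapeSpec, design_from_curve, generate_mesh

mesh = generate_mesh(
    ShapeSpec(family="superquadric", elongation=2.5, mirror_symmetric=True,
              resolution=350, seed=11, exponents=(1.0, 0.9)),
    label="demo-object",
)
print(f"mesh: {mesh.n_vertices} vertices, {mesh.n_faces} faces (unit radius)")

curve = flow_curve(mesh)
design = design_from_curve(curve)
print(f"flow curve: 72 values in [{curve.values.min():.4f}, "
      f"{curve.values.max():.4f}] object-radius units per 5° step")
print(f"curve range (max - min): {curve_range(curve):.4f}")
for name, (idx, axis) in design.items():
    print(f"  {name:15s} ({axis:12s}) at {idx * 5:5.0f}°: "
          f"flow {curve.value_at(idx):.4f}, "
          f"gradient {curve_gradient(curve, idx):+.5f} per degree")
print("cardinal views sit at curve extrema: large flow (high "
      "discriminability) but near-zero gradient (stable under small "
      "viewpoint error).")
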