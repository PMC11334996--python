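"""Independent brute-force reference for the flow model.

Everything here is deliberately written the slow, explicit way — one vertex
at a time, one triangle at a time, scalar Möller–Trumbore, explicit
rotation matrices — sharing no code with the package implementation. The
numerical constants (origin pull-back, determinant cut-off, barycentric
slack) are part of the documented visibility algorithm and are re-declared
here rather than imported.
"""

from __future__ import annotations

import math

import numpy as np

PULLBACK_FRACTION = 1e-6
DET_EPS = 1e-12
BARY_EPS = 1e-9


def rotation_y_deg(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def ray_hits_triangle(origin, direction, v0, v1, v2) -> bool:
    e1 = v1 - v0
    e2 = v2 - v0
    p = np.cross(direction, e2)
    det = float(e1 @ p)
    if abs(det) <= DET_EPS:
        return False
    inv = 1.0 / det
    tvec = origin - v0
    u = float(tvec @ p) * inv
    if u < -BARY_EPS or u > 1.0 + BARY_EPS:
        return False
    q = np.cross(tvec, e1)
    v = float(direction @ q) * inv
    if v < -BARY_EPS or u + v > 1.0 + BARY_EPS:
        return False
    t = float(e2 @ q) * inv
    return t > 0.0


def visible_mask_bruteforce(vertices, faces, azimuth_deg: float) -> np.ndarray:
    """Per-vertex orthographic visibility by explicit ray casting toward +z."""
    rot = rotation_y_deg(azimuth_deg)
    posed = np.array([rot @ v for v in vertices])
    radius = max(math.sqrt(float(v @ v)) for v in vertices)
    eps = PULLBACK_FRACTION * radius
    zdir = np.array([0.0, 0.0, 1.0])
    mask = np.ones(len(vertices), dtype=bool)
    for k, vert in enumerate(posed):
        origin = vert + eps * zdir
        for f in faces:
            if ray_hits_triangle(origin, zdir, posed[f[0]], posed[f[1]], posed[f[2]]):
                mask[k] = False
                break
    return mask


def pairwise_flow_bruteforce(
    vertices, faces, azimuth_a: float, azimuth_b: float, metric: str = "L1-components"
) -> float:
    """Mean projected displacement of the vertices visible in both poses."""
    vis_a = visible_mask_bruteforce(vertices, faces, azimuth_a)
    vis_b = visible_mask_bruteforce(vertices, faces, azimuth_b)
    rot_a = rotation_y_deg(azimuth_a)
    rot_b = rotation_y_deg(azimuth_b)
    contributions = []
    for k in range(len(vertices)):
        if not (vis_a[k] and vis_b[k]):
            continue
        pa = rot_a @ vertices[k]
        pb = rot_b @ vertices[k]
        dx = pb[0] - pa[0]
        dy = pb[1] - pa[1]
        if metric == "L1-components":
            contributions.append(abs(dx))
            contributions.append(abs(dy))
        else:
            contributions.append(math.hypot(dx, dy))
    if not contributions:
        raise ValueError("no matched vertex")
    return float(np.mean(contributions))
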