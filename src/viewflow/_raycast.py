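"""Batched Möller–Trumbore ray–triangle occlusion testing.

The visibility rule used throughout the flow model: a vertex is visible when
the ray from the vertex toward the camera, with its origin pulled back
toward the camera by ``PULLBACK_FRACTION`` of the mesh bounding radius (to
avoid self-intersection with the faces meeting at that vertex), hits no
triangle strictly in front of it. Constants are part of the documented
algorithm so that an independent re-implementation can reproduce decisions
bit-for-bit.
"""

from __future__ import annotations

import numpy as np

# origin pull-back toward the camera, as a fraction of the bounding radius
PULLBACK_FRACTION = 1e-6
# |det| below this means ray parallel to triangle plane: no intersection
DET_EPS = 1e-12
# barycentric inclusion slack: a ray crossing an edge shared by two
# triangles sits exactly on the boundary of both tests and can otherwise
# fall into the numerical crack between them (declared a miss by both);
# inflating each triangle by this much guarantees at least one hit. Grid
# meshes hit this case systematically: rays from back vertices cross front
# edges at exactly shared ring heights.
BARY_EPS = 1e-9

# cap on the V x F broadcast size before chunking over rays (memory guard)
_CHUNK_ELEMS = 8_000_000


def _any_hit_chunk(
    origins: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    t_max: np.ndarray | None,
) -> np.ndarray:
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0

    # pvec: (R, F, 3); broadcasting rays against all triangles at once
    pvec = np.cross(directions[:, None, :], e2[None, :, :])
    det = np.einsum("fk,rfk->rf", e1, pvec)
    ok = np.abs(det) > DET_EPS
    inv_det = np.where(ok, det, 1.0)
    inv_det = 1.0 / inv_det

    tvec = origins[:, None, :] - v0[None, :, :]
    u = np.einsum("rfk,rfk->rf", tvec, pvec) * inv_det
    ok &= (u >= -BARY_EPS) & (u <= 1.0 + BARY_EPS)

    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("rk,rfk->rf", directions, qvec) * inv_det
    ok &= (v >= -BARY_EPS) & (u + v <= 1.0 + BARY_EPS)

    t = np.einsum("fk,rfk->rf", e2, qvec) * inv_det
    ok &= t > 0.0
    if t_max is not None:
        ok &= t < t_max[:, None]
    return ok.any(axis=1)


def any_hit_along_z(
    origins: np.ndarray, triangles: np.ndarray, n_bins: int = 64
) -> np.ndarray:
    """:func:`any_hit` specialized to rays along +z (orthographic camera).

    Rays along +z keep their (x, y) fixed, so a triangle whose projected
    bounding box excludes the ray's (x, y) provably cannot intersect it.
    Rays are binned into x strips and each strip tests only the triangles
    whose x extent reaches it — an exact, conservative prefilter that
    changes no decision, only skips impossible pairs.
    """
    origins = np.asarray(origins, float)
    n_rays = len(origins)
    if n_rays == 0 or len(triangles) == 0:
        return np.zeros(n_rays, dtype=bool)
    tri_x = triangles[:, :, 0]
    tri_min_x, tri_max_x = tri_x.min(axis=1), tri_x.max(axis=1)
    xs = origins[:, 0]
    lo = min(xs.min(), tri_min_x.min())
    hi = max(xs.max(), tri_max_x.max())
    if hi <= lo:
        edges = np.array([lo - 1.0, hi + 1.0])
        n_bins = 1
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    ray_bin = np.clip(np.searchsorted(edges, xs, side="right") - 1, 0, n_bins - 1)
    z_dir = np.array([0.0, 0.0, 1.0])
    out = np.zeros(n_rays, dtype=bool)
    for b in range(n_bins):
        ridx = np.flatnonzero(ray_bin == b)
        if not len(ridx):
            continue
        tsel = (tri_max_x >= edges[b]) & (tri_min_x <= edges[b + 1])
        if not tsel.any():
            continue
        dirs = np.broadcast_to(z_dir, (len(ridx), 3))
        out[ridx] = _any_hit_chunk(origins[ridx], dirs, triangles[tsel], None)
    return out


def any_hit(
    origins: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    t_max: np.ndarray | None = None,
) -> np.ndarray:
    """True per ray iff it intersects any triangle with ``0 < t < t_max``.

    ``origins``/``directions``: (R, 3); ``triangles``: (F, 3, 3).
    """
    origins = np.asarray(origins, float)
    directions = np.asarray(directions, float)
    n_rays, n_tris = len(origins), len(triangles)
    if n_rays == 0 or n_tris == 0:
        return np.zeros(n_rays, dtype=bool)
    out = np.empty(n_rays, dtype=bool)
    step = max(1, _CHUNK_ELEMS // max(1, n_tris))
    for lo in range(0, n_rays, step):
        hi = lo + step
        out[lo:hi] = _any_hit_chunk(
            origins[lo:hi],
            directions[lo:hi],
            triangles,
            None if t_max is None else t_max[lo:hi],
        )
    return out
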