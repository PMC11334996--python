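"""Triangle meshes, the viewpoint grid, and the camera model.

Coordinate conventions, fixed package-wide:

* right-handed world coordinates; the **vertical axis is +y**;
* the camera sits on the **+z** axis looking at the origin;
* image axes: x to the right, y up;
* positive azimuth rotates the *object* counter-clockwise when seen from
  above (the right-hand rotation about +y), equivalently the camera
  clockwise around the object.

A pose of an object is fully described by one azimuth angle about the
vertical axis; vertex order is preserved under posing, which is what gives
the point correspondence the flow model needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateMeshError,
    MeshFormatError,
    ProjectionError,
    ValidationError,
)

__all__ = [
    "TriangleMesh",
    "Camera",
    "ViewpointGrid",
    "PoseView",
    "load_mesh",
    "save_obj",
    "normalize_mesh",
    "rotation_about_vertical",
    "pose_view",
    "pose_vertices",
    "project",
]

# relative area below which a face is considered degenerate and dropped
_AREA_EPS = 1e-12


@dataclass(frozen=True)
class TriangleMesh:
    """A triangulated surface: ``vertices`` (n, 3) float, ``faces`` (m, 3) int.

    Vertices not referenced by any face are allowed (they act as probe
    points for visibility queries); faces act as occluders.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError(f"vertices must be (n, 3); got {v.shape}")
        if f.size and (f.ndim != 2 or f.shape[1] != 3):
            raise ValidationError(f"faces must be (m, 3); got {f.shape}")
        f = f.reshape(-1, 3)
        if not np.isfinite(v).all():
            raise ValidationError("non-finite vertex coordinate")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            bad = f[(f < 0) | (f >= len(v))][0]
            raise ValidationError(
                f"face index {int(bad)} out of range [0, {len(v)})"
            )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def bounding_radius(self) -> float:
        return float(np.linalg.norm(self.vertices, axis=1).max())


@dataclass(frozen=True)
class Camera:
    """Projection model.

    ``orthographic`` drops z after scaling; ``perspective`` is a pinhole at
    ``(0, 0, distance)`` looking at the origin, with the image plane scaled
    so that points in the z=0 plane project identically to the orthographic
    camera (hence perspective → orthographic as ``distance`` → ∞).
    ``distance`` is in normalized object-radius units and must exceed 1 so
    the camera sits outside the unit bounding sphere.
    """

    mode: str = "orthographic"
    distance: float | None = None
    image_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("orthographic", "perspective"):
            raise ValidationError(f"unknown camera mode {self.mode!r}")
        if self.image_scale <= 0:
            raise ValidationError("image_scale must be > 0")
        if self.mode == "perspective":
            if self.distance is None or not self.distance > 1:
                raise ValidationError(
                    "perspective camera needs distance > 1 (object-radius units)"
                )

    @property
    def position(self) -> np.ndarray:
        if self.mode != "perspective":
            raise ValidationError("orthographic camera has no finite position")
        return np.array([0.0, 0.0, float(self.distance)])


@dataclass(frozen=True)
class ViewpointGrid:
    """Circular grid of azimuths: ``n_views`` views every ``step_deg`` degrees."""

    n_views: int = 72
    step_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.n_views < 3:
            raise ValidationError("need n_views >= 3")
        if not math.isclose(self.n_views * self.step_deg, 360.0):
            raise ValidationError(
                f"n_views * step_deg must be 360, got {self.n_views * self.step_deg}"
            )

    def azimuths(self) -> np.ndarray:
        return np.arange(self.n_views) * self.step_deg

    def azimuth_of(self, index: int) -> float:
        return (index % self.n_views) * self.step_deg

    def index_of(self, azimuth_deg: float) -> int:
        """Nearest grid index for an angle (used to snap responses)."""
        return int(round((azimuth_deg % 360.0) / self.step_deg)) % self.n_views


def rotation_about_vertical(azimuth_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about +y by ``azimuth_deg`` degrees."""
    if not np.isfinite(azimuth_deg):
        raise ValidationError("azimuth must be finite")
    a = math.radians(azimuth_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass(frozen=True)
class PoseView:
    """An azimuth together with its rotation matrix (azimuth 0 = identity)."""

    azimuth_deg: float
    rotation: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rotation is None:
            object.__setattr__(
                self, "rotation", rotation_about_vertical(self.azimuth_deg)
            )


def pose_view(azimuth_deg: float) -> PoseView:
    return PoseView(azimuth_deg % 360.0)


def pose_vertices(mesh: TriangleMesh | np.ndarray, azimuth_deg: float) -> np.ndarray:
    """Rigidly rotate vertices about the vertical axis; order is preserved.

    Preserved vertex order is the point correspondence between poses: vertex
    i at one azimuth and vertex i at another are the same surface point.
    """
    verts = mesh.vertices if isinstance(mesh, TriangleMesh) else np.asarray(mesh, float)
    if azimuth_deg == 0.0:
        return verts.copy()
    rot = rotation_about_vertical(azimuth_deg)
    return verts @ rot.T


def project(points: np.ndarray, camera: Camera) -> np.ndarray:
    """Project 3D points to image coordinates (n, 2).

    Orthographic: ``(x, y) * image_scale``. Perspective: pinhole at
    ``(0, 0, d)``; image point = ``(x, y) * image_scale * d / (d - z)``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValidationError(f"points must be (n, 3); got {pts.shape}")
    if camera.mode == "orthographic":
        return pts[:, :2] * camera.image_scale
    d = float(camera.distance)  # type: ignore[arg-type]
    depth = d - pts[:, 2]
    if np.any(depth <= 0):
        raise ProjectionError("point at or behind the perspective camera plane")
    return pts[:, :2] * (camera.image_scale * d / depth)[:, None]


def normalize_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """Center the vertex centroid at the origin and scale the maximum vertex
    radius to 1, so flow values are in object-radius units for every object."""
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    r = np.linalg.norm(v, axis=1).max()
    if r <= 0 or not np.isfinite(r):
        raise DegenerateMeshError("all vertices coincide; cannot normalize")
    return replace(mesh, vertices=v / r)


# ---------------------------------------------------------------------------
# Readers / writer: minimal OBJ (v/f records, 1-based) and ASCII PLY.
# Indices are normalized to the single internal 0-based convention; quads and
# larger convex polygons are fan-triangulated; zero-area faces are dropped.
# ---------------------------------------------------------------------------


def _fan(indices: list[int], line_no: int) -> list[tuple[int, int, int]]:
    if len(indices) < 3:
        raise MeshFormatError(f"line {line_no}: face with {len(indices)} vertices")
    return [(indices[0], indices[i], indices[i + 1]) for i in range(1, len(indices) - 1)]


def _parse_obj(text: str) -> tuple[np.ndarray, np.ndarray]:
    verts: list[list[float]] = []
    faces: list[tuple[int, int, int]] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        tokens = raw.split("#", 1)[0].split()
        if not tokens:
            continue
        kind = tokens[0]
        if kind == "v":
            if len(tokens) < 4:
                raise MeshFormatError(f"line {line_no}: vertex needs 3 coordinates")
            try:
                verts.append([float(t) for t in tokens[1:4]])
            except ValueError as exc:
                raise MeshFormatError(f"line {line_no}: bad coordinate: {exc}") from exc
        elif kind == "f":
            try:
                idx = [int(t.split("/", 1)[0]) for t in tokens[1:]]
            except ValueError as exc:
                raise MeshFormatError(f"line {line_no}: bad face index: {exc}") from exc
            if any(i == 0 for i in idx):
                raise MeshFormatError(f"line {line_no}: OBJ indices are 1-based")
            # negative OBJ indices count back from the current vertex list
            idx0 = [i - 1 if i > 0 else len(verts) + i for i in idx]
            faces.extend(_fan(idx0, line_no))
        # v-normals, texcoords, groups, materials are irrelevant here
    return np.asarray(verts, float).reshape(-1, 3), np.asarray(faces, np.int64).reshape(-1, 3)


def _parse_ply(text: str) -> tuple[np.ndarray, np.ndarray]:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError("line 1: not a PLY file (missing 'ply' magic)")
    n_vert = n_face = 0
    vert_props: list[str] = []
    in_vertex_element = False
    body_start = None
    for line_no, raw in enumerate(lines[1:], start=2):
        tokens = raw.split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            if tokens[1] != "ascii":
                raise MeshFormatError(f"line {line_no}: only ascii PLY is supported")
        elif tokens[0] == "element":
            in_vertex_element = tokens[1] == "vertex"
            if tokens[1] == "vertex":
                n_vert = int(tokens[2])
            elif tokens[1] == "face":
                n_face = int(tokens[2])
        elif tokens[0] == "property" and in_vertex_element and tokens[1] != "list":
            vert_props.append(tokens[-1])
        elif tokens[0] == "end_header":
            body_start = line_no
            break
    if body_start is None:
        raise MeshFormatError("missing end_header")
    try:
        ix, iy, iz = (vert_props.index(ax) for ax in "xyz")
    except ValueError as exc:
        raise MeshFormatError("vertex element lacks x/y/z properties") from exc

    body = [ln for ln in lines[body_start:] if ln.split()]
    if len(body) < n_vert + n_face:
        raise MeshFormatError(
            f"expected {n_vert + n_face} body lines, found {len(body)}"
        )
    verts = np.empty((n_vert, 3))
    for i in range(n_vert):
        tokens = body[i].split()
        try:
            verts[i] = [float(tokens[ix]), float(tokens[iy]), float(tokens[iz])]
        except (ValueError, IndexError) as exc:
            raise MeshFormatError(f"vertex record {i}: {exc}") from exc
    faces: list[tuple[int, int, int]] = []
    for i in range(n_face):
        tokens = body[n_vert + i].split()
        count = int(tokens[0])
        if len(tokens) < count + 1:
            raise MeshFormatError(f"face record {i}: truncated index list")
        faces.extend(_fan([int(t) for t in tokens[1 : count + 1]], i))
    return verts, np.asarray(faces, np.int64).reshape(-1, 3)


def _drop_degenerate_faces(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    if not len(faces):
        return faces
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    extent = float(np.ptp(verts, axis=0).max()) or 1.0
    return faces[area2 > _AREA_EPS * extent**2]


def load_mesh(path: str | Path, format: str | None = None) -> TriangleMesh:
    """Read an OBJ or ASCII-PLY mesh.

    The format is inferred from the suffix unless given explicitly. Indices
    are converted to the internal 0-based convention, polygonal faces are
    fan-triangulated and zero-area faces removed.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply"):
        raise ValidationError(f"unsupported mesh format {fmt!r}")
    text = path.read_text()
    verts, faces = (_parse_obj if fmt == "obj" else _parse_ply)(text)
    if len(verts) == 0:
        raise MeshFormatError(f"{path.name}: no vertices found")
    mesh = TriangleMesh(verts, faces, label=path.stem)  # validates index range
    return replace(mesh, faces=_drop_degenerate_faces(mesh.vertices, mesh.faces))


def save_obj(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh as Wavefront OBJ (v/f records, 1-based indices)."""
    with open(path, "w") as fh:
        if mesh.label:
            fh.write(f"o {mesh.label}\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")
        for a, b, c in mesh.faces + 1:
            fh.write(f"f {a} {b} {c}\n")
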