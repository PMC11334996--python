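"""Optical-flow dissimilarity between object poses and the flow curve.

The model scores how different two views of an object look by how far its
surface points travel in the image when the object rotates from one view to
the other:

1. corresponding points are the mesh vertices themselves (posing preserves
   vertex order, so correspondence is the identity);
2. a vertex contributes only if it is visible (not occluded by the mesh)
   in *both* poses — the matched mask;
3. each matched vertex's 2D image displacement is the projection of its
   position in the second pose minus the first;
4. the dissimilarity is the mean of the absolute horizontal and vertical
   displacement components pooled together (``L1-components``, default) or
   the mean Euclidean displacement length (``L2-length``).

Evaluating step 4 between each grid viewpoint and its 5°-rotated neighbour
around the full circle yields the *flow curve*: 72 values, circular, whose
local gradient and range are the behavioural predictors used downstream.
Low gradient magnitude marks the perceptually special (cardinal) views that
sit at the peaks and troughs of the curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _raycast
from .errors import NoOverlapError, ValidationError
from .mesh_scene import Camera, TriangleMesh, ViewpointGrid, pose_vertices, project

__all__ = [
    "FlowField",
    "FlowCurve",
    "CurvePredictors",
    "METRICS",
    "visible_vertex_mask",
    "pairwise_flow",
    "flow_curve",
    "curve_gradient",
    "curve_gradients",
    "segment_slope",
    "curve_range",
    "curve_predictors",
]

METRICS = ("L1-components", "L2-length")


@dataclass(frozen=True)
class FlowField:
    """Per-vertex image displacements between two poses of one object.

    ``displacements`` has a row per mesh vertex; rows where ``matched`` is
    False are NaN (the vertex was occluded in at least one pose and does not
    enter the dissimilarity).
    """

    displacements: np.ndarray  # (n, 2), NaN where not matched
    visibility_a: np.ndarray  # (n,) bool
    visibility_b: np.ndarray  # (n,) bool

    @property
    def matched(self) -> np.ndarray:
        return self.visibility_a & self.visibility_b

    def to_frame(self) -> pd.DataFrame:
        """Per-vertex table for export/visualization."""
        return pd.DataFrame(
            {
                "vertex": np.arange(len(self.displacements)),
                "dx": self.displacements[:, 0],
                "dy": self.displacements[:, 1],
                "visible_a": self.visibility_a,
                "visible_b": self.visibility_b,
                "matched": self.matched,
            }
        )


@dataclass(frozen=True)
class FlowCurve:
    """Circular sequence of view-to-next-view dissimilarities.

    ``values[i]`` is the flow from grid view i to view i+1 (indices wrap).
    """

    values: np.ndarray
    grid: ViewpointGrid = field(default_factory=ViewpointGrid)
    label: str = ""
    metric: str = "L1-components"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != self.grid.n_views:
            raise ValidationError(
                f"curve length {v.shape} != grid n_views {self.grid.n_views}"
            )
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValidationError("curve values must be finite and >= 0")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    def value_at(self, index: int) -> float:
        return float(self.values[index % len(self)])

    def azimuths(self) -> np.ndarray:
        return self.grid.azimuths()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "object": self.label,
                "view_index": np.arange(len(self)),
                "azimuth_deg": self.azimuths(),
                "flow_value": self.values,
                "metric": self.metric,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "object": self.label,
                    "metric": self.metric,
                    "n_views": self.grid.n_views,
                    "step_deg": self.grid.step_deg,
                    "values": self.values.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FlowCurve":
        frame = frame.sort_values("view_index")
        n = len(frame)
        grid = ViewpointGrid(n_views=n, step_deg=360.0 / n)
        label = str(frame["object"].iloc[0]) if "object" in frame else ""
        metric = str(frame["metric"].iloc[0]) if "metric" in frame else "L1-components"
        return cls(frame["flow_value"].to_numpy(float), grid, label, metric)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FlowCurve":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class CurvePredictors:
    """Curve-derived behavioural predictors for a set of labelled viewpoints."""

    label: str
    gradient_at: dict[int, float]
    abs_gradient_at: dict[int, float]
    segment_slope: dict[tuple[int, float], float]
    range: float


def _camera_directions(posed: np.ndarray, camera: Camera) -> tuple[np.ndarray, np.ndarray | None]:
    """Unit directions from each vertex toward the camera, and max ray length."""
    if camera.mode == "orthographic":
        dirs = np.zeros_like(posed)
        dirs[:, 2] = 1.0
        return dirs, None
    delta = camera.position[None, :] - posed
    dist = np.linalg.norm(delta, axis=1)
    return delta / dist[:, None], dist


def visible_vertex_mask(
    mesh: TriangleMesh, azimuth_deg: float, camera: Camera = Camera()
) -> np.ndarray:
    """Boolean mask of vertices not occluded by the mesh in the given pose.

    A ray is cast from each vertex toward the camera, its origin pulled back
    toward the camera by ``1e-6`` of the bounding radius; the vertex is
    visible iff no triangle intersects the ray strictly before the camera.
    """
    if mesh.n_vertices == 0:
        raise ValidationError("empty mesh")
    posed = pose_vertices(mesh, azimuth_deg)
    if not len(mesh.faces):
        return np.ones(mesh.n_vertices, dtype=bool)
    dirs, dist = _camera_directions(posed, camera)
    eps = _raycast.PULLBACK_FRACTION * mesh.bounding_radius()
    origins = posed + eps * dirs
    if camera.mode == "orthographic":
        occluded = _raycast.any_hit_along_z(origins, posed[mesh.faces])
    else:
        occluded = _raycast.any_hit(origins, dirs, posed[mesh.faces], dist - eps)
    return ~occluded


def pairwise_flow(
    mesh: TriangleMesh,
    azimuth_a: float,
    azimuth_b: float,
    camera: Camera = Camera(),
    metric: str = "L1-components",
) -> tuple[FlowField, float]:
    """Flow field and scalar dissimilarity between two poses.

    Raises :class:`NoOverlapError` when no vertex is visible in both poses —
    the mean is undefined there, and silently returning 0 would make two
    completely non-overlapping views look identical.
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")
    vis_a = visible_vertex_mask(mesh, azimuth_a, camera)
    vis_b = visible_vertex_mask(mesh, azimuth_b, camera)
    matched = vis_a & vis_b
    if not matched.any():
        raise NoOverlapError(
            f"no vertex visible in both poses ({azimuth_a}°, {azimuth_b}°)"
        )
    proj_a = project(pose_vertices(mesh, azimuth_a)[matched], camera)
    proj_b = project(pose_vertices(mesh, azimuth_b)[matched], camera)
    disp = np.full((mesh.n_vertices, 2), np.nan)
    disp[matched] = proj_b - proj_a
    if metric == "L1-components":
        value = float(np.mean(np.abs(disp[matched])))
    else:
        value = float(np.mean(np.linalg.norm(disp[matched], axis=1)))
    return FlowField(disp, vis_a, vis_b), value


def flow_curve(
    mesh: TriangleMesh,
    grid: ViewpointGrid = ViewpointGrid(),
    camera: Camera = Camera(),
    metric: str = "L1-components",
) -> FlowCurve:
    """Dissimilarity from each grid view to its rotated neighbour, circularly.

    Visibility and projection are computed once per grid view and shared by
    the two segments that view participates in.
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")
    if mesh.n_vertices < 4 or mesh.n_faces < 4:
        raise ValidationError(
            "flow curve needs a mesh with >= 4 vertices and >= 4 faces"
        )
    n = grid.n_views
    vis = np.empty((n, mesh.n_vertices), dtype=bool)
    proj = np.empty((n, mesh.n_vertices, 2))
    for i in range(n):
        az = grid.azimuth_of(i)
        vis[i] = visible_vertex_mask(mesh, az, camera)
        proj[i] = project(pose_vertices(mesh, az), camera)
    values = np.empty(n)
    for i in range(n):
        j = (i + 1) % n
        matched = vis[i] & vis[j]
        if not matched.any():
            raise NoOverlapError(f"no matched vertex between views {i} and {j}")
        disp = proj[j][matched] - proj[i][matched]
        if metric == "L1-components":
            values[i] = np.mean(np.abs(disp))
        else:
            values[i] = np.mean(np.linalg.norm(disp, axis=1))
    return FlowCurve(values, grid, label=mesh.label, metric=metric)


def curve_gradient(curve: FlowCurve, index: int) -> float:
    """Signed circular central-difference gradient at a grid view,
    in flow units per degree."""
    n = len(curve)
    if not -n <= index < n:
        raise ValidationError(f"index {index} out of range for {n}-view curve")
    v = curve.values
    return float(
        (v[(index + 1) % n] - v[(index - 1) % n]) / (2.0 * curve.grid.step_deg)
    )


def curve_gradients(curve: FlowCurve) -> np.ndarray:
    """Central-difference gradient at every view (vectorized, circular)."""
    v = curve.values
    return (np.roll(v, -1) - np.roll(v, 1)) / (2.0 * curve.grid.step_deg)


def segment_slope(curve: FlowCurve, base: int, offset_deg: float) -> float:
    """Slope of the curve between a base view and an offset view:
    ``(value[base+offset] − value[base]) / |offset|``."""
    step = curve.grid.step_deg
    if offset_deg == 0:
        raise ValidationError("slope over a zero offset is undefined")
    k = offset_deg / step
    if abs(k - round(k)) > 1e-9:
        raise ValidationError(
            f"offset {offset_deg}° is not a multiple of the {step}° grid step"
        )
    n = len(curve)
    if not -n <= base < n:
        raise ValidationError(f"base index {base} out of range")
    other = (base + int(round(k))) % n
    return float((curve.values[other] - curve.values[base % n]) / abs(offset_deg))


def curve_range(curve: FlowCurve) -> float:
    """max − min of the curve values (a per-object irregularity summary)."""
    return float(curve.values.max() - curve.values.min())


def curve_predictors(
    curve: FlowCurve,
    indices: dict[str, int] | list[int],
    offsets_deg: tuple[float, ...] = (5.0, 10.0, 15.0, -5.0, -10.0, -15.0),
) -> CurvePredictors:
    """Bundle gradient, |gradient|, segment slopes and range for labelled views."""
    idx = list(indices.values()) if isinstance(indices, dict) else list(indices)
    grads = {i: curve_gradient(curve, i) for i in idx}
    return CurvePredictors(
        label=curve.label,
        gradient_at=grads,
        abs_gradient_at={i: abs(g) for i, g in grads.items()},
        segment_slope={
            (i, o): segment_slope(curve, i, o) for i in idx for o in offsets_deg
        },
        range=curve_range(curve),
    )
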