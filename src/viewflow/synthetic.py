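"""Procedural stimuli and simulated observers.

Everything the analysis pipeline consumes can be generated here without any
external download: closed triangle meshes with controllable elongation,
mirror symmetry and n-fold rotational symmetry (spanning smooth, regular
"familiar-like" flow curves and irregular "novel-like" ones), same/different
trial tables produced by a psychometric observer whose probability of
responding "different" rises monotonically with the model-predicted
dissimilarity, and front-choice angles concentrated where the flow-curve
gradient is small.

Symmetries are honoured *by construction*: the radial profile of a shape is
built from a basis restricted to the symmetry-respecting subspace (only
``cos(mφ)`` terms for mirror symmetry about the x = 0 plane, only harmonics
with m a multiple of n for n-fold symmetry) and the longitude grid count is
a multiple of n, so the generated vertex set maps onto itself under the
symmetry — flow-curve periodicity then holds to floating-point accuracy
rather than to a meshing tolerance.

Reproducibility: one master seed fans out to per-component child seeds via
``child_seed(master, label)`` (a CRC-32 of the label mixed into a
``SeedSequence``), so individual stages can be re-run independently yet
bit-identically.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .discrimination import ROTATION_LEVELS, TRIAL_COLUMNS
from .errors import ValidationError
from .flow_model import FlowCurve, curve_gradients
from .mesh_scene import TriangleMesh, normalize_mesh, rotation_about_vertical

__all__ = [
    "ShapeSpec",
    "ObserverModel",
    "FrontSamplerSpec",
    "child_seed",
    "child_rng",
    "generate_mesh",
    "familiar_like_suite",
    "novel_like_suite",
    "design_from_curve",
    "accumulated_dissimilarity",
    "p_different",
    "simulate_discrimination",
    "simulate_front_responses",
    "simulate_null_factorial",
]

FAMILIES = ("superquadric", "extruded-polygon", "perturbed-blob")

#: Global half-grid-step twist applied to every generated mesh (degrees);
#: the mirror plane of mirror-symmetric shapes sits at this azimuth.
MESH_TWIST_DEG = 2.5


def child_seed(master_seed: int, label: str) -> np.random.SeedSequence:
    """Deterministic per-component seed derived from the master seed."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])


def child_rng(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, label))


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one procedural object.

    ``elongation`` stretches the shape along the horizontal z axis (the
    camera axis at azimuth 0°), so azimuths 0°/180° are the end-on, cardinal
    views. ``n_fold_symmetry`` > 1 makes the shape invariant under rotation
    by 360°/n about the vertical axis; ``mirror_symmetric`` makes it
    invariant under x → −x.
    """

    family: str = "superquadric"
    elongation: float = 1.5
    mirror_symmetric: bool = True
    n_fold_symmetry: int = 1
    resolution: int = 350
    seed: int = 0
    #: superquadric roundness exponents (latitude, longitude); None draws
    #: them from the seed. Fix them to build one-factor stimulus families.
    exponents: tuple | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"family must be one of {FAMILIES}")
        if self.elongation < 1:
            raise ValidationError("elongation must be >= 1")
        if self.n_fold_symmetry < 1:
            raise ValidationError("n_fold_symmetry must be >= 1")
        if self.resolution < 50:
            raise ValidationError("resolution must be >= 50")
        if self.exponents is not None:
            e1, e2 = self.exponents
            if not (e1 > 0 and e2 > 0):
                raise ValidationError("exponents must be positive")


@dataclass(frozen=True)
class ObserverModel:
    """Psychometric link from model dissimilarity d to P("different").

    P("different" | d) = guess + (1 − guess − lapse) · (1 − exp(−(d/α)^β)),
    a Weibull with floor ``guess`` (false alarms at d = 0) and ceiling
    1 − lapse. ``alpha`` is the dissimilarity scale, in flow units; when
    None it is calibrated at simulation time from the curves being
    simulated (see :func:`calibrate_alpha`), which reproduces the shape of
    the reported group psychometric curves: hardest above-floor
    discrimination at 5°, approaching ceiling at 15°. ``beta`` is the
    steepness of an *individual* observer; the group-mean curve is flatter
    because it mixes conditions with different dissimilarities.
    """

    alpha: float | None = None
    beta: float = 2.2
    guess: float = 0.05
    lapse: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alpha is not None and not self.alpha > 0:
            raise ValidationError("alpha must be > 0")
        if not self.beta > 0:
            raise ValidationError("beta must be > 0")
        if not 0 <= self.guess < 0.5:
            raise ValidationError("guess must be in [0, 0.5)")
        if not 0 <= self.lapse < 0.1:
            raise ValidationError("lapse must be in [0, 0.1)")
        if self.guess + self.lapse >= 1:
            raise ValidationError("guess + lapse must be < 1")


@dataclass(frozen=True)
class FrontSamplerSpec:
    """How simulated observers pick a "front": weight ∝
    exp(−|gradient|/(T·mean|gradient|)) with a multiplicative bonus at local
    curve extrema. T → 0 concentrates all mass on the flattest viewpoint."""

    temperature: float = 0.25
    extremum_bonus: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValidationError("temperature must be > 0")
        if not self.extremum_bonus > 0:
            raise ValidationError("extremum_bonus must be > 0")


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------


def _grid_counts(resolution: int, n_fold: int) -> tuple[int, int]:
    """Latitude/longitude counts hitting ~resolution vertices.

    The longitude count is a multiple of the symmetry order (and of 4), and
    is additionally chosen so that no half-offset longitude column ever
    falls on the 5° viewpoint grid modulo 180° (equivalently,
    n_phi / gcd(n_phi, 36) is even). Columns exactly aligned with the view
    plane at a grid azimuth put whole vertex columns into razor-edge
    ray–triangle configurations whose visibility is decided by rounding
    noise; keeping columns off the grid keeps every decision well-margined.
    """
    n_phi = max(12, int(round(math.sqrt(2.0 * resolution))))
    unit = int(np.lcm(4, n_fold))
    n_phi = max(unit, unit * round(n_phi / unit))
    while (72 // math.gcd(72, n_phi)) % 2 != 0:
        n_phi += unit
    n_theta = max(4, int(round(resolution / n_phi)) + 1)
    return n_theta, n_phi


def _phi_columns(n_phi: int) -> np.ndarray:
    """Half-offset longitude samples, symmetric about the x=0 mirror plane."""
    return 2 * np.pi * (np.arange(n_phi) + 0.5) / n_phi


def _radial_surface_mesh(
    rho: np.ndarray,
    theta: np.ndarray,
    phi: np.ndarray,
    label: str,
    mirror_faces: bool = False,
) -> TriangleMesh:
    """Closed UV mesh from a radial profile rho[(n_theta−1), n_phi] on
    interior latitudes plus pole radii appended as rho_top, rho_bottom.

    With ``mirror_faces`` the triangulation itself is made equivariant
    under the x → −x mirror: quad split diagonals flip orientation across
    the mirror plane, and the two quad columns the plane cuts through are
    split into four triangles about their centroid (which lies on the
    plane). Plain quad splits leave a triangulation that is *not* the
    mirror image of itself, and for non-planar quads that asymmetry leaks
    into grazing-ray visibility.
    """
    n_t = len(theta)
    n_p = len(phi)
    rho_rings, rho_top, rho_bot = rho
    st, ct = np.sin(theta)[:, None], np.cos(theta)[:, None]
    x = rho_rings * st * np.sin(phi)[None, :]
    y = rho_rings * ct * np.ones_like(phi)[None, :]
    z = rho_rings * st * np.cos(phi)[None, :]
    ring_verts = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    top = np.array([[0.0, rho_top, 0.0]])
    bottom = np.array([[0.0, -rho_bot, 0.0]])
    verts_list = [top, ring_verts, bottom]
    n_fixed = 2 + len(ring_verts)

    def rv(i: int, j: int) -> int:  # ring vertex index
        return 1 + i * n_p + (j % n_p)

    all_verts = np.vstack(verts_list)
    extra: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []
    # quad columns bisected by the mirror plane (self-mapped under j -> n_p-2-j)
    straddling = {(n_p - 2) // 2, n_p - 1}
    for j in range(n_p):  # top fan
        faces.append((0, rv(0, j), rv(0, j + 1)))
    for i in range(n_t - 1):
        for j in range(n_p):
            a, b = rv(i, j), rv(i, j + 1)
            c, d = rv(i + 1, j), rv(i + 1, j + 1)
            if mirror_faces and j in straddling:
                centroid = all_verts[[a, b, c, d]].mean(axis=0)
                x_idx = n_fixed + len(extra)
                extra.append(centroid)
                faces += [(a, c, x_idx), (c, d, x_idx), (d, b, x_idx), (b, a, x_idx)]
            elif mirror_faces and j > (n_p - 2) // 2:
                faces += [(a, c, d), (a, d, b)]
            else:
                faces += [(a, c, b), (b, c, d)]
    last = n_fixed - 1
    for j in range(n_p):
        faces.append((last, rv(n_t - 1, j + 1), rv(n_t - 1, j)))
    if extra:
        all_verts = np.vstack([all_verts, np.asarray(extra)])
    return TriangleMesh(all_verts, np.asarray(faces, np.int64), label=label)


def _superquadric_rho(theta, phi, e1: float, e2: float) -> np.ndarray:
    ny = np.cos(theta)[:, None] * np.ones_like(phi)[None, :]
    sx = np.sin(theta)[:, None] * np.sin(phi)[None, :]
    sz = np.sin(theta)[:, None] * np.cos(phi)[None, :]
    inner = (np.abs(sz) ** (2 / e2) + np.abs(sx) ** (2 / e2)) ** (e2 / e1)
    f = inner + np.abs(ny) ** (2 / e1)
    return f ** (-e1 / 2)


def _blob_rho(
    theta, phi, rng: np.random.Generator, mirror: bool, n_fold: int
) -> np.ndarray:
    """Seeded low-order angular perturbation of a sphere, restricted to the
    symmetry-respecting subspace. Terms with m > 0 vanish at the poles."""
    tt = theta[:, None]
    pp = phi[None, :]
    rho = np.ones((len(theta), len(phi)))
    for m in range(0, 7):
        if m % max(1, n_fold) != 0:
            continue
        for q in range(0, 4):
            if m == 0 and q == 0:
                continue
            amp = 0.45 / (1.0 + m + q)
            c = rng.normal(0.0, amp)
            psi = 0.0 if (mirror or m == 0) else rng.uniform(0, 2 * np.pi)
            lat = np.cos(q * tt) if m == 0 else np.sin(tt) * np.cos(q * tt)
            rho += c * lat * np.cos(m * pp + psi)
    return np.clip(rho, 0.25, None)


def _polygon_radius(phi: np.ndarray, rng, mirror: bool, n_fold: int) -> np.ndarray:
    if n_fold >= 3:
        half = np.pi / n_fold
        local = np.mod(phi, 2 * half) - half
        # support function of the regular n-gon, blended 20% toward the
        # circle: corners stay but edges gain curvature, so no mesh face is
        # exactly flat (flat faces go edge-on at some azimuth and their
        # vertex visibility becomes a coin flip)
        r = 0.8 * np.cos(half) / np.cos(local) + 0.2
    else:
        r = np.ones_like(phi)
        for k in range(max(2, n_fold), 6):
            if k % max(1, n_fold) != 0:
                continue
            psi = 0.0 if mirror else rng.uniform(0, 2 * np.pi)
            r = r + rng.normal(0.0, 0.25 / k) * np.cos(k * phi + psi)
    return np.clip(r, 0.3, None)


def _extruded_polygon_mesh(spec: ShapeSpec, rng, label: str) -> TriangleMesh:
    n_theta, n_phi = _grid_counts(spec.resolution, spec.n_fold_symmetry)
    n_levels = max(2, n_theta - 1)
    phi = _phi_columns(n_phi)
    r = _polygon_radius(phi, rng, spec.mirror_symmetric, spec.n_fold_symmetry)
    height = rng.uniform(0.9, 1.5)
    ys = np.linspace(height / 2, -height / 2, n_levels)
    rings = np.stack(
        [
            np.broadcast_to(r * np.sin(phi), (n_levels, n_phi)),
            ys[:, None] * np.ones(n_phi)[None, :],
            np.broadcast_to(r * np.cos(phi), (n_levels, n_phi)),
        ],
        axis=-1,
    ).reshape(-1, 3)
    top = np.array([[0.0, height / 2, 0.0]])
    bottom = np.array([[0.0, -height / 2, 0.0]])
    verts = np.vstack([top, rings, bottom])

    def rv(i, j):
        return 1 + i * n_phi + (j % n_phi)

    faces = []
    for j in range(n_phi):
        faces.append((0, rv(0, j), rv(0, j + 1)))
    for i in range(n_levels - 1):
        for j in range(n_phi):
            a, b = rv(i, j), rv(i, j + 1)
            c, d = rv(i + 1, j), rv(i + 1, j + 1)
            faces.append((a, c, b))
            faces.append((b, c, d))
    last = len(verts) - 1
    for j in range(n_phi):
        faces.append((last, rv(n_levels - 1, j + 1), rv(n_levels - 1, j)))
    return TriangleMesh(verts, np.asarray(faces, np.int64), label=label)


def sphere_mesh(resolution: int = 2200, label: str = "sphere") -> TriangleMesh:
    """Unit UV sphere through the same meshing machinery (incl. the grid
    twist). The longitude count is biased high because the flow curve's
    residual ripple for a rotationally symmetric shape comes from how
    finely the silhouette is sampled in longitude."""
    n_phi = max(12, 4 * round(math.sqrt(4.0 * resolution) / 4))
    while (72 // math.gcd(72, n_phi)) % 2 != 0:
        n_phi += 4
    n_theta = max(4, int(round(resolution / n_phi)) + 1)
    theta = np.pi * np.arange(1, n_theta) / n_theta
    phi = _phi_columns(n_phi)
    rings = np.ones((n_theta - 1, n_phi))
    mesh = _radial_surface_mesh((rings, 1.0, 1.0), theta, phi, label)
    verts = mesh.vertices @ rotation_about_vertical(MESH_TWIST_DEG).T
    return normalize_mesh(TriangleMesh(verts, mesh.faces, label=label))


def generate_mesh(spec: ShapeSpec, label: str = "") -> TriangleMesh:
    """Build a closed, normalized triangle mesh honouring the requested
    symmetry flags exactly; deterministic for a fixed seed.

    Note: elongation > 1 is a stretch along z and therefore breaks n-fold
    symmetry for n > 2; combine n_fold_symmetry > 2 with elongation 1 when
    exact rotational symmetry is wanted.
    """
    rng = np.random.default_rng(spec.seed)
    label = label or f"{spec.family}-{spec.seed}"
    if spec.family == "extruded-polygon":
        mesh = _extruded_polygon_mesh(spec, rng, label)
    else:
        n_theta, n_phi = _grid_counts(spec.resolution, spec.n_fold_symmetry)
        theta = np.pi * np.arange(1, n_theta) / n_theta
        phi = _phi_columns(n_phi)
        if spec.family == "superquadric":
            if spec.exponents is not None:
                e1, e2 = map(float, spec.exponents)
            else:
                e1 = rng.uniform(0.7, 1.4)
                e2 = rng.uniform(0.7, 1.4)
            rings = _superquadric_rho(theta, phi, e1, e2)
            rho_top = float(_superquadric_rho(np.array([0.0]), phi[:1], e1, e2)[0, 0])
            rho_bot = rho_top
        else:  # perturbed-blob
            rings = _blob_rho(theta, phi, rng, spec.mirror_symmetric, spec.n_fold_symmetry)
            pole = _blob_rho(
                np.array([0.0, np.pi]),
                phi[:1],
                np.random.default_rng(spec.seed),
                spec.mirror_symmetric,
                spec.n_fold_symmetry,
            )
            rho_top, rho_bot = float(pole[0, 0]), float(pole[1, 0])
        mesh = _radial_surface_mesh(
            (rings, rho_top, rho_bot),
            theta,
            phi,
            label,
            # exact n-fold invariance needs rotation-consistent diagonals,
            # which conflicts with the mirror-equivariant split; rotational
            # symmetry wins when both are requested
            mirror_faces=spec.mirror_symmetric and spec.n_fold_symmetry == 1,
        )
    verts = mesh.vertices.copy()
    if spec.elongation != 1.0:
        verts[:, 2] *= spec.elongation
    # Twist the finished shape by half a grid step about the vertical axis:
    # combined with the half-offset longitude columns this keeps every
    # feature direction (columns, prism-face normals, the mirror plane, the
    # long axis) off the 5° viewpoint grid, so no face is ever exactly
    # edge-on at a grid view and vertex visibility is never decided by
    # rounding noise. The mirror plane ends up at azimuth +2.5°.
    mesh = TriangleMesh(verts @ rotation_about_vertical(MESH_TWIST_DEG).T,
                        mesh.faces, label=mesh.label)
    return normalize_mesh(mesh)


#: Elongations of the regular object suite: a bimodal everyday-object mix
#: of round-ish items (animals, containers) and elongated ones (vehicles,
#: tools), the two clusters real stimulus sets tend to contain.
FAMILIAR_ELONGATIONS = (
    1.05, 1.1, 1.15, 1.2, 1.25, 1.3,
    2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4,
)

#: Fixed superquadric roundness of the regular suite: one shape family so
#: elongation is the single manipulated stimulus factor.
FAMILIAR_EXPONENTS = (1.0, 0.9)


def familiar_like_suite(
    n_objects: int = 13, master_seed: int = 0, resolution: int = 350
) -> list[tuple[str, TriangleMesh]]:
    """Regular, mirror-symmetric objects with smooth flow curves, emulating
    a recognizable-object stimulus set. One superquadric shape family with
    elongation as the single manipulated factor (bimodal across the suite:
    round-ish and elongated clusters), so curve contrast varies widely and
    systematically across objects."""
    out = []
    base = FAMILIAR_ELONGATIONS
    elongations = [base[i % len(base)] for i in range(n_objects)]
    for i in range(n_objects):
        label = f"familiar-{i:02d}"
        spec = ShapeSpec(
            family="superquadric",
            elongation=float(elongations[i]),
            mirror_symmetric=True,
            n_fold_symmetry=1,
            resolution=resolution,
            seed=int(child_seed(master_seed, label).generate_state(1)[0] % 2**31),
            exponents=FAMILIAR_EXPONENTS,
        )
        out.append((label, generate_mesh(spec, label)))
    return out


def novel_like_suite(
    n_objects: int = 10, master_seed: int = 0, resolution: int = 350
) -> list[tuple[str, TriangleMesh]]:
    """Irregular blob objects with heterogeneous, "novel-like" flow curves;
    symmetry and elongation vary across the suite."""
    out = []
    for i in range(n_objects):
        label = f"novel-{i:02d}"
        spec = ShapeSpec(
            family="perturbed-blob",
            elongation=1.0 + 0.12 * (i % 5),
            mirror_symmetric=(i % 3 == 0),
            n_fold_symmetry=1,
            resolution=resolution,
            seed=int(child_seed(master_seed, label).generate_state(1)[0] % 2**31),
        )
        out.append((label, generate_mesh(spec, label)))
    return out


# ---------------------------------------------------------------------------
# Simulated observers
# ---------------------------------------------------------------------------


def design_from_curve(curve: FlowCurve) -> dict[str, tuple[int, str]]:
    """Base viewpoints for the discrimination design, read off the curve.

    Cardinal views sit at the curve's extrema: front = the global maximum,
    back = the local maximum nearest its antipode. Non-cardinal views sit
    45° from the cardinal views — midway between a cardinal axis and the
    side axis, which is where oblique test views live.
    Returns {base_view: (grid index, axis_type)}.
    """
    v = curve.values
    n = len(v)
    front = int(np.argmax(v))
    # local maxima, circular
    maxima = np.flatnonzero((v >= np.roll(v, 1)) & (v >= np.roll(v, -1)))
    anti = (front + n // 2) % n
    circ = np.minimum(np.abs(maxima - anti), n - np.abs(maxima - anti))
    back = int(maxima[np.argmin(circ)]) if len(maxima) else anti
    if back == front:
        back = anti
    return {
        "front": (front, "cardinal"),
        "back": (back, "cardinal"),
        "non-cardinal-1": ((front + n // 8) % n, "non-cardinal"),
        "non-cardinal-2": ((back + n // 8) % n, "non-cardinal"),
    }


def accumulated_dissimilarity(curve: FlowCurve, base_index: int, offset_deg: float) -> float:
    """Model dissimilarity between a base view and a view ``offset_deg``
    away: the sum of the per-step curve values along the rotation path
    (flow accumulates as the object turns through intervening views)."""
    step = curve.grid.step_deg
    k = offset_deg / step
    if abs(k - round(k)) > 1e-9:
        raise ValidationError(f"offset {offset_deg}° not on the {step}° grid")
    k = int(round(k))
    n = len(curve)
    if k >= 0:
        idx = [(base_index + j) % n for j in range(k)]
    else:
        idx = [(base_index - j) % n for j in range(1, -k + 1)]
    return float(curve.values[idx].sum()) if idx else 0.0


def p_different(d: np.ndarray | float, observer: ObserverModel) -> np.ndarray | float:
    """Weibull psychometric function of model dissimilarity."""
    if observer.alpha is None:
        raise ValidationError("observer.alpha is uncalibrated")
    d = np.asarray(d, float)
    core = 1.0 - np.exp(-((d / observer.alpha) ** observer.beta))
    out = observer.guess + (1.0 - observer.guess - observer.lapse) * core
    return float(out) if out.ndim == 0 else out


def calibrate_alpha(curves: Mapping[str, FlowCurve]) -> float:
    """Dissimilarity scale for a typical observer: 1.3 × the median
    single-step flow across all curves. Together with the default
    individual-observer steepness this puts the group psychometric means
    near 0.05 / 0.5 / 0.9 / 0.97 P("different") at the four rotation
    levels: the 5° offset is the one hard above-floor discrimination, as in
    the behavioural data. (Group means are flatter than any individual
    observer because they average Weibulls with object- and axis-dependent
    dissimilarities.)"""
    pooled = np.concatenate([c.values for c in curves.values()])
    med = float(np.median(pooled))
    if med <= 0:
        raise ValidationError("curves are identically zero; cannot calibrate")
    return 1.3 * med


def simulate_discrimination(
    curves: Mapping[str, FlowCurve],
    observer: ObserverModel = ObserverModel(),
    designs: Mapping[str, Mapping[str, tuple[int, str]]] | None = None,
    n_participants: int = 50,
    trials_per_cell: int = 2,
    image_set: str = "rendered",
    rotation_levels: Sequence[int] = ROTATION_LEVELS,
    rt_log_mean: float = math.log(800.0),
    rt_log_sd: float = 0.35,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a full same/different experiment as a trial table.

    Per trial the observer sees a base view and a view offset by one of the
    signed rotation levels; P("different") follows the Weibull link on the
    accumulated flow dissimilarity, responses are independent Bernoulli and
    reaction times lognormal (so the RT exclusion rules have work to do).
    """
    if designs is None:
        designs = {obj: design_from_curve(c) for obj, c in curves.items()}
    if observer.alpha is None:
        observer = ObserverModel(
            alpha=calibrate_alpha(curves),
            beta=observer.beta,
            guess=observer.guess,
            lapse=observer.lapse,
            seed=observer.seed,
        )
    rng = np.random.default_rng(seed if seed is not None else observer.seed)

    cells = []
    for obj, design in designs.items():
        curve = curves[obj]
        for base_view, (base_idx, axis_type) in design.items():
            for level in rotation_levels:
                d = accumulated_dissimilarity(curve, base_idx, float(level))
                cells.append((obj, axis_type, base_view, level, p_different(d, observer)))
    cell_df = pd.DataFrame(
        cells, columns=["object", "axis_type", "base_view", "rotation_level", "p_diff"]
    )
    c = len(cell_df)
    reps = n_participants * trials_per_cell
    p = np.repeat(cell_df["p_diff"].to_numpy(), reps)
    responses = np.where(rng.random(c * reps) < p, "different", "same")
    rts = rng.lognormal(rt_log_mean, rt_log_sd, size=c * reps)
    participants = np.tile(
        np.repeat([f"sim-{i:03d}" for i in range(n_participants)], trials_per_cell), c
    )
    trials = pd.DataFrame(
        {
            "participant": participants,
            "object": np.repeat(cell_df["object"].to_numpy(), reps),
            "image_set": image_set,
            "axis_type": np.repeat(cell_df["axis_type"].to_numpy(), reps),
            "base_view": np.repeat(cell_df["base_view"].to_numpy(), reps),
            "rotation_level": np.repeat(cell_df["rotation_level"].to_numpy(), reps),
            "response": responses,
            "rt_ms": rts,
        }
    )
    return trials[list(TRIAL_COLUMNS)]


def front_choice_weights(curve: FlowCurve, sampler: FrontSamplerSpec) -> np.ndarray:
    """Choice distribution over grid viewpoints: concentrated where the
    |gradient| is small, boosted at local extrema of the curve."""
    g = np.abs(curve_gradients(curve))
    scale = g.mean()
    if scale > 0:
        w = np.exp(-g / (sampler.temperature * scale))
    else:
        w = np.ones_like(g)  # constant curve: uniform
    v = curve.values
    extremum = ((v >= np.roll(v, 1)) & (v >= np.roll(v, -1))) | (
        (v <= np.roll(v, 1)) & (v <= np.roll(v, -1))
    )
    if np.ptp(v) > 0:
        w = w * np.where(extremum, sampler.extremum_bonus, 1.0)
    return w / w.sum()


def simulate_front_responses(
    curves: Mapping[str, FlowCurve] | FlowCurve,
    sampler: FrontSamplerSpec = FrontSamplerSpec(),
    n_participants: int = 50,
    seed: int | None = None,
) -> pd.DataFrame:
    """One "front" choice per participant per object, drawn from the
    gradient-weighted distribution over grid viewpoints."""
    if isinstance(curves, FlowCurve):
        curves = {curves.label or "object": curves}
    rng = np.random.default_rng(seed if seed is not None else sampler.seed)
    rows = []
    for obj, curve in curves.items():
        w = front_choice_weights(curve, sampler)
        idx = rng.choice(len(curve), size=n_participants, p=w)
        for pid, i in enumerate(idx):
            rows.append(
                {
                    "participant": f"sim-{pid:03d}",
                    "object": obj,
                    "chosen_azimuth_deg": curve.grid.azimuth_of(int(i)),
                }
            )
    return pd.DataFrame(rows)


def simulate_null_factorial(
    n_per_cell: int = 40,
    sigma_by_axis: tuple[float, float] = (1.0, 2.0),
    seed: int | None = None,
) -> pd.DataFrame:
    """Null (no effects) factorial data with axis-dependent variance, for
    calibrating the FGLS type-I error: rotation_level × axis_type ×
    image_set cells, response ~ N(0, σ²(axis))."""
    rng = np.random.default_rng(seed)
    rows = []
    for level in (0, 5, 10, 15):
        for ai, axis in enumerate(("cardinal", "non-cardinal")):
            for iset in ("real", "rendered"):
                rows.append((level, axis, iset, sigma_by_axis[ai]))
    frame = pd.DataFrame(
        rows, columns=["rotation_level", "axis_type", "image_set", "sigma"]
    )
    frame = frame.loc[frame.index.repeat(n_per_cell)].reset_index(drop=True)
    frame["p_different"] = rng.normal(0.0, frame["sigma"].to_numpy())
    return frame.drop(columns="sigma")
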