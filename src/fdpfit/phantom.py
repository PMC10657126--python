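"""Synthetic scan triads with analytically known marginal misfit.

No raw scans of real prostheses are available, so validation runs on
phantoms: a pair of tapered-frustum tooth preparations with a flat 90
degree shoulder on a base plate (the "model"), a two-retainer prosthesis
whose crown margins are displaced from the abutment margins by configurable
per-angle horizontal extension ``delta(theta)`` and vertical gap
``v(theta)``, and the prosthesis seated on the model.  The three datasets
mirror what a chairside scanner produces: abutment scan, prosthesis-alone
scan, seated scan — each expressible in its own coordinate frame via a
rigid pose, each optionally perturbed by Gaussian surface noise along
vertex normals.

The ground-truth absolute marginal discrepancy at azimuth ``theta`` is
``sqrt(delta(theta)**2 + v(theta)**2)`` by construction, defined on the
analytic margin curves before any meshing, so it is exactly invariant to
pose, resolution and noise settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .mesh_io import LandmarkSet, TriangleMesh, make_mesh, write_stl, write_landmarks
from .registration import RigidTransform

#: a per-angle margin function: scalar (constant) or vectorized f(theta_rad)
AngularFn = float | Callable[[np.ndarray], np.ndarray]


def _as_angular_fn(x: AngularFn) -> Callable[[np.ndarray], np.ndarray]:
    if callable(x):
        return lambda t: np.broadcast_to(np.asarray(x(t), dtype=float), np.shape(t)).copy()
    return lambda t: np.full(np.shape(t), float(x))


def _per_retainer(value, n: int) -> list:
    """Expand a shared setting or a per-retainer sequence to length ``n``."""
    if isinstance(value, Sequence) and not isinstance(value, (str, bytes)):
        if len(value) != n:
            raise ValueError(f"expected {n} per-retainer values, got {len(value)}")
        return list(value)
    return [value] * n


@dataclass
class PhantomSpec:
    """Parameters of a synthetic three-unit prosthesis scan triad.

    Geometry is in mm.  ``horizontal_extension`` (signed, + = crown margin
    overextended beyond the preparation margin) and ``vertical_gap`` may be
    scalars, vectorized functions of azimuth (radians), or per-retainer
    sequences of either.  ``cement_gap`` is the designed space between the
    intaglio and the axial walls (design value 0.05 mm).  ``noise_sd``
    emulates scanner error as i.i.d. Gaussian displacement along vertex
    normals, independently per dataset (a 20 um-accurate scanner maps to
    ``noise_sd=0.02``).
    """

    n_retainers: int = 2
    positions: tuple = ((-8.0, 0.0), (8.0, 0.0))
    margin_radius: float = 4.0
    shoulder_width: float = 1.0
    taper_deg: float = 6.0
    prep_height: float = 4.0
    cement_gap: float = 0.05
    horizontal_extension: AngularFn | Sequence = 0.0
    vertical_gap: AngularFn | Sequence = 0.0
    pose_abutment: RigidTransform = field(default_factory=RigidTransform.identity)
    pose_prosthesis: RigidTransform = field(default_factory=RigidTransform.identity)
    pose_seated: RigidTransform = field(default_factory=RigidTransform.identity)
    noise_sd: float = 0.0
    n_theta: int = 192
    n_axial: int = 3
    skirt_depth: float = 2.0
    occlusal_thickness: float = 1.2
    plate_size: tuple = (32.0, 16.0)
    plate_thickness: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.margin_radius <= 0 or self.shoulder_width <= 0:
            raise ValueError("margin_radius and shoulder_width must be positive")
        if self.cement_gap < 0 or self.noise_sd < 0:
            raise ValueError("cement_gap and noise_sd must be non-negative")
        if self.n_theta < 16:
            raise ValueError(
                f"n_theta={self.n_theta} cannot resolve the shoulder; need >= 16"
            )
        if len(self.positions) != self.n_retainers:
            raise ValueError("positions must have one (x, y) entry per retainer")

    # -- per-retainer margin functions ------------------------------------
    def delta_fn(self, index: int) -> Callable[[np.ndarray], np.ndarray]:
        return _as_angular_fn(_per_retainer(self.horizontal_extension, self.n_retainers)[index])

    def v_fn(self, index: int) -> Callable[[np.ndarray], np.ndarray]:
        return _as_angular_fn(_per_retainer(self.vertical_gap, self.n_retainers)[index])

    def true_amd_um(self, index: int, theta: np.ndarray) -> np.ndarray:
        """Ground-truth AMD in micrometres at azimuth(s) ``theta`` (rad)."""
        theta = np.asarray(theta, dtype=float)
        return np.hypot(self.delta_fn(index)(theta), self.v_fn(index)(theta)) * 1000.0

    def center(self, index: int) -> np.ndarray:
        x, y = self.positions[index]
        return np.array([x, y, 0.0])


@dataclass(frozen=True)
class MarginCircle:
    """Analytic margin edge of one preparation: a circle in 3D."""

    center: np.ndarray
    radius: float
    axis: np.ndarray  # unit vector, occlusal direction

    def points(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        u, w = _plane_basis(self.axis)
        return (
            self.center
            + self.radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * w)
        )


def _plane_basis(axis: np.ndarray):
    axis = np.asarray(axis, dtype=float)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ axis) * axis
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


# ---------------------------------------------------------------------------
# lathe construction
# ---------------------------------------------------------------------------

def _lathe(R: np.ndarray, Z: np.ndarray, name: str = "", fix_volume: bool = True):
    """Surface of revolution from per-azimuth profile rows.

    ``R`` and ``Z`` are (n_rows, n_theta) arrays giving the radius and height
    of each profile row at each azimuth sample.  A row whose radii are all
    zero collapses to a single on-axis vertex (a cap apex); such rows may
    only be first or last.  Returns the mesh plus the profile-row index of
    every vertex, which downstream code uses to build region masks.
    """
    n_rows, n_theta = R.shape
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    axis_row = np.all(R == 0.0, axis=1)
    if axis_row[1:-1].any():
        raise ValueError("on-axis profile rows may only be first or last")

    verts: list[np.ndarray] = []
    rows_of_vertex: list[int] = []
    ring_start = np.full(n_rows, -1, dtype=np.int64)  # index of first vertex of row
    for i in range(n_rows):
        ring_start[i] = len(verts)
        if axis_row[i]:
            verts.append(np.array([0.0, 0.0, Z[i].mean()]))
            rows_of_vertex.append(i)
        else:
            ring = np.column_stack((R[i] * cos_t, R[i] * sin_t, Z[i]))
            verts.extend(ring)
            rows_of_vertex.extend([i] * n_theta)

    faces: list[tuple[int, int, int]] = []
    j = np.arange(n_theta)
    j1 = (j + 1) % n_theta
    for i in range(n_rows - 1):
        a_axis, b_axis = axis_row[i], axis_row[i + 1]
        sa, sb = ring_start[i], ring_start[i + 1]
        if a_axis and b_axis:
            raise ValueError("two consecutive on-axis rows")
        if a_axis:  # bottom fan
            faces.extend(zip(np.full(n_theta, sa), sb + j1, sb + j))
        elif b_axis:  # top fan
            faces.extend(zip(sa + j, sa + j1, np.full(n_theta, sb)))
        else:
            faces.extend(zip(sa + j, sa + j1, sb + j1))
            faces.extend(zip(sa + j, sb + j1, sb + j))

    mesh = make_mesh(np.array(verts), np.array(faces), name=name)
    if fix_volume and mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh, np.array(rows_of_vertex)


def _abutment_profile(spec: PhantomSpec):
    """Profile rows (axis-symmetric) for one preparation, margin plane z=0.

    Returns (radii, heights, margin_row, prep_first_row): the skirt runs from
    the base up to the margin ring; shoulder, axial wall and occlusal table
    follow.  The margin ring (shoulder outer edge, radius r at z=0) is the
    AMD landmark.
    """
    r, w = spec.margin_radius, spec.shoulder_width
    h, tan_tap = spec.prep_height, np.tan(np.radians(spec.taper_deg))
    n_ax = max(2, spec.n_axial)
    rows: list[tuple[float, float]] = [(0.0, -spec.skirt_depth)]
    for z in np.linspace(-spec.skirt_depth, 0.0, n_ax + 1):
        rows.append((r, z))
    margin_row = len(rows) - 1
    for rr in np.linspace(r, r - w, n_ax + 1)[1:]:
        rows.append((rr, 0.0))
    for z in np.linspace(0.0, h, 2 * n_ax + 1)[1:]:
        rows.append((r - w - z * tan_tap, z))
    r_top = r - w - h * tan_tap
    rows.append((0.5 * r_top, h))
    rows.append((0.0, h))
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1], margin_row, margin_row


def generate_abutment(
    spec: PhantomSpec,
    index: int,
    rng: np.random.Generator | None = None,
) -> tuple[TriangleMesh, MarginCircle]:
    """Watertight preparation mesh for one retainer plus its analytic margin.

    The mesh lives in the canonical (unposed) frame at the retainer's
    position.  If ``spec.noise_sd > 0``, vertices are displaced along their
    normals by i.i.d. Gaussian noise drawn from ``rng`` (derived from
    ``spec.seed`` when not given).
    """
    radii, heights, _, _ = _abutment_profile(spec)
    R = np.tile(radii[:, None], (1, spec.n_theta))
    Z = np.tile(heights[:, None], (1, spec.n_theta))
    mesh, _ = _lathe(R, Z, name=f"abutment_{index}")
    mesh.vertices += spec.center(index)
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng([spec.seed, 100 + index])
        _apply_surface_noise(mesh, spec.noise_sd, rng)
    circle = MarginCircle(
        center=spec.center(index),
        radius=spec.margin_radius,
        axis=np.array([0.0, 0.0, 1.0]),
    )
    return mesh, circle


def _crown_profiles(spec: PhantomSpec, index: int):
    """(R, Z) per-azimuth profile arrays for one crown, plus the margin row.

    The profile is a closed solid of revolution running from the intaglio
    top centre down the inner wall, across the seat to the margin edge at
    ``(r + delta(theta), v(theta))``, then up the external wall to the
    occlusal table.  The margin edge is a sharp crease between seat and
    external wall, matching the outer edge a feature-edge extractor finds.
    """
    r, w, g = spec.margin_radius, spec.shoulder_width, spec.cement_gap
    h, tan_tap = spec.prep_height, np.tan(np.radians(spec.taper_deg))
    occ = spec.occlusal_thickness
    n_ax = max(2, spec.n_axial)
    theta = np.linspace(0.0, 2.0 * np.pi, spec.n_theta, endpoint=False)
    delta = spec.delta_fn(index)(theta)
    v = spec.v_fn(index)(theta)
    if np.any(delta < -w):
        raise ValueError(
            "horizontal_extension < -shoulder_width: crown margin would fall "
            "inside the shoulder inner edge"
        )
    v_mean = float(v.mean())
    r_wall_top = r - w - h * tan_tap  # abutment wall radius at occlusal table
    z_int_top = v_mean + h + g  # intaglio ceiling
    z_ext_top = h + g + occ  # external occlusal table
    r_margin = r + delta

    rows_R: list[np.ndarray] = []
    rows_Z: list[np.ndarray] = []

    def add(rr, zz):
        rows_R.append(np.broadcast_to(np.asarray(rr, dtype=float), theta.shape).copy())
        rows_Z.append(np.broadcast_to(np.asarray(zz, dtype=float), theta.shape).copy())

    # intaglio: top centre -> ceiling ring -> inner wall -> seat -> margin
    add(0.0, z_int_top)
    add(0.5 * (r_wall_top + g), z_int_top)
    add(r_wall_top + g, z_int_top)
    for z in np.linspace(h, 0.0, 2 * n_ax + 1):
        add(r - w + g - z * tan_tap, v + z)
    for f in np.linspace(0.0, 1.0, n_ax + 1)[1:]:
        add((1 - f) * (r - w + g) + f * r_margin, v)
    margin_row = len(rows_R) - 1
    # external: margin -> wall -> occlusal rim -> table centre
    for f in np.linspace(0.0, 1.0, 2 * n_ax + 1)[1:]:
        add((1 - f) * r_margin + f * (r - 0.3), (1 - f) * v + f * z_ext_top)
    add(0.5 * (r - 0.3), z_ext_top)
    add(0.0, z_ext_top)
    return np.array(rows_R), np.array(rows_Z), margin_row


def _pontic_mesh(spec: PhantomSpec) -> TriangleMesh:
    """Simple bar pontic connecting the retainers (a subdivided box)."""
    import trimesh

    centers = np.array([spec.center(i) for i in range(spec.n_retainers)])
    lo, hi = centers.min(axis=0), centers.max(axis=0)
    span = np.linalg.norm(hi - lo)
    length = max(span - spec.margin_radius, 2.0)
    box = trimesh.creation.box(extents=(length, 4.0, 3.0))
    for _ in range(2):
        box = box.subdivide()
    box = make_mesh(box.vertices, box.faces, name="pontic")
    mid = (lo + hi) / 2.0
    box.vertices += mid + np.array([0.0, 0.0, spec.prep_height / 2.0 + 1.5])
    return box


def _plate_mesh(spec: PhantomSpec) -> TriangleMesh:
    """Base plate standing in for the surrounding dentition model context."""
    import trimesh

    box = trimesh.creation.box(
        extents=(spec.plate_size[0], spec.plate_size[1], spec.plate_thickness)
    )
    for _ in range(3):
        box = box.subdivide()
    box = make_mesh(box.vertices, box.faces, name="plate")
    # plate top sits just below the skirt bottoms: coincident vertices across
    # parts would weld together on STL round trips and shift mask indices
    box.vertices += np.array(
        [0.0, 0.0, -spec.skirt_depth - spec.plate_thickness / 2.0 - 0.05]
    )
    return box


def _skirt_mesh(spec: PhantomSpec, index: int) -> TriangleMesh:
    """Open cervical band of one abutment below the margin (seated context)."""
    n_ax = max(2, spec.n_axial)
    rows = [(0.0, -spec.skirt_depth)]
    for z in np.linspace(-spec.skirt_depth, 0.0, n_ax + 1):
        rows.append((spec.margin_radius, z))
    arr = np.array(rows)
    R = np.tile(arr[:, 0][:, None], (1, spec.n_theta))
    Z = np.tile(arr[:, 1][:, None], (1, spec.n_theta))
    mesh, _ = _lathe(R, Z, name=f"skirt_{index}", fix_volume=False)
    mesh.vertices += spec.center(index)
    return mesh


def generate_prosthesis(
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> tuple[TriangleMesh, list[MarginCircle], dict]:
    """Prosthesis mesh (crowns + bar pontic) in the canonical seated position.

    Returns the mesh, the *nominal* margin circles (radius ``r``, before the
    per-angle displacement — exact crown margin points come from
    :meth:`PhantomSpec.delta_fn` / :meth:`PhantomSpec.v_fn`), and a mask
    dict with ``external`` (crown external surfaces + pontic) and
    ``intaglio`` vertex indices.
    """
    parts: list[TriangleMesh] = []
    external_chunks: list[np.ndarray] = []
    intaglio_chunks: list[np.ndarray] = []
    circles: list[MarginCircle] = []
    offset = 0
    for i in range(spec.n_retainers):
        R, Z, margin_row = _crown_profiles(spec, i)
        crown, rows = _lathe(R, Z, name=f"crown_{i}")
        crown.vertices += spec.center(i)
        external_chunks.append(offset + np.flatnonzero(rows >= margin_row))
        intaglio_chunks.append(offset + np.flatnonzero(rows < margin_row))
        offset += len(crown.vertices)
        parts.append(crown)
        circles.append(
            MarginCircle(spec.center(i), spec.margin_radius, np.array([0.0, 0.0, 1.0]))
        )
    pontic = _pontic_mesh(spec)
    external_chunks.append(offset + np.arange(len(pontic.vertices)))
    parts.append(pontic)
    mesh = _concatenate(parts, name="prosthesis")
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng([spec.seed, 200])
        _apply_surface_noise(mesh, spec.noise_sd, rng)
    masks = {
        "external": np.concatenate(external_chunks),
        "intaglio": np.concatenate(intaglio_chunks),
    }
    return mesh, circles, masks


def _concatenate(parts: list[TriangleMesh], name: str = "") -> TriangleMesh:
    """Order-preserving concatenation (no welding across parts)."""
    verts = np.vstack([p.vertices for p in parts])
    faces = []
    offset = 0
    for p in parts:
        faces.append(p.faces + offset)
        offset += len(p.vertices)
    return make_mesh(verts, np.vstack(faces), name=name)


def _apply_surface_noise(
    mesh: TriangleMesh, sd: float, rng: np.random.Generator
) -> None:
    normals = mesh.vertex_normals.view(np.ndarray)
    mesh.vertices += normals * rng.normal(0.0, sd, size=(len(mesh.vertices), 1))


# ---------------------------------------------------------------------------
# triad assembly
# ---------------------------------------------------------------------------

@dataclass
class ScanDataset:
    """One scan: mesh in its own frame, region masks, landmark stand-ins."""

    mesh: TriangleMesh
    masks: dict[str, np.ndarray]
    landmarks: LandmarkSet
    pose: RigidTransform  # canonical frame -> this dataset's frame


@dataclass
class GroundTruth:
    """Everything the phantom knows exactly, for recovery checks.

    ``amd_um`` holds the per-retainer ground-truth AMD evaluated on a dense
    azimuth grid; ``stage_a``/``stage_b``/``seating`` are the rigid
    transforms a perfect registration would recover.
    """

    angles_deg: np.ndarray
    amd_um: list[np.ndarray]
    mean_amd_um: list[float]
    margin_circles: list[MarginCircle]
    pose_abutment: RigidTransform
    pose_prosthesis: RigidTransform
    pose_seated: RigidTransform
    stage_a: RigidTransform
    stage_b: RigidTransform
    seating: RigidTransform
    seed: int

    def axis_in_abutment_frame(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """True (origin, direction) of retainer ``index`` after posing."""
        c = self.margin_circles[index]
        origin = self.pose_abutment.apply(c.center)
        direction = self.pose_abutment.rotation @ c.axis
        return origin, direction

    def to_dict(self) -> dict:
        return {
            "angles_deg": self.angles_deg.tolist(),
            "amd_um": [a.tolist() for a in self.amd_um],
            "mean_amd_um": self.mean_amd_um,
            "margin_circles": [
                {
                    "center": c.center.tolist(),
                    "radius": c.radius,
                    "axis": c.axis.tolist(),
                }
                for c in self.margin_circles
            ],
            "pose_abutment": self.pose_abutment.to_dict(),
            "pose_prosthesis": self.pose_prosthesis.to_dict(),
            "pose_seated": self.pose_seated.to_dict(),
            "stage_a": self.stage_a.to_dict(),
            "stage_b": self.stage_b.to_dict(),
            "seating": self.seating.to_dict(),
            "seed": self.seed,
        }


@dataclass
class Triad:
    """The three scan datasets of one prosthesis plus ground truth."""

    abutment: ScanDataset
    prosthesis: ScanDataset
    seated: ScanDataset
    ground_truth: GroundTruth
    spec: PhantomSpec


def generate_triad(spec: PhantomSpec) -> Triad:
    """Generate the abutment, prosthesis and seated scans of one phantom.

    Each dataset is expressed in its own frame via the spec's pose offsets
    and receives an independent noise realization.  The seated scan is the
    union of the base plate, the cervical bands of the abutments (the
    context a registration can anchor on) and the seated prosthesis.
    """
    # --- canonical-frame geometry, per-dataset noise streams ---
    rng_ab = np.random.default_rng([spec.seed, 1])
    rng_pr = np.random.default_rng([spec.seed, 2])
    rng_se = np.random.default_rng([spec.seed, 3])

    plate = _plate_mesh(spec)
    n_plate = len(plate.vertices)

    # abutment scan: plate + full preparations
    ab_parts = [plate]
    ab_context = [np.arange(n_plate)]
    ab_prep_masks: dict[str, np.ndarray] = {}
    circles: list[MarginCircle] = []
    offset = n_plate
    for i in range(spec.n_retainers):
        prep, circle = generate_abutment(replace(spec, noise_sd=0.0), i)
        circles.append(circle)
        radii, heights, margin_row, _ = _abutment_profile(spec)
        _, rows = _lathe(
            np.tile(radii[:, None], (1, spec.n_theta)),
            np.tile(heights[:, None], (1, spec.n_theta)),
        )
        ab_context.append(offset + np.flatnonzero(rows <= margin_row))
        ab_prep_masks[f"preparation_r{i}"] = offset + np.flatnonzero(rows >= margin_row)
        offset += len(prep.vertices)
        ab_parts.append(prep)
    ab_mesh = _concatenate(ab_parts, name="abutment_scan")

    # prosthesis scan
    pr_mesh, _, pr_masks = generate_prosthesis(replace(spec, noise_sd=0.0))

    # seated scan: plate + skirts + prosthesis geometry
    se_parts = [plate.copy()]
    se_context = [np.arange(n_plate)]
    offset = n_plate
    for i in range(spec.n_retainers):
        skirt = _skirt_mesh(spec, i)
        se_context.append(offset + np.arange(len(skirt.vertices)))
        offset += len(skirt.vertices)
        se_parts.append(skirt)
    se_prosthesis = offset + np.arange(len(pr_mesh.vertices))
    se_parts.append(pr_mesh.copy())
    se_mesh = _concatenate(se_parts, name="seated_scan")

    # --- noise (independent per dataset), then poses ---
    if spec.noise_sd > 0:
        _apply_surface_noise(ab_mesh, spec.noise_sd, rng_ab)
        _apply_surface_noise(pr_mesh, spec.noise_sd, rng_pr)
        _apply_surface_noise(se_mesh, spec.noise_sd, rng_se)
    ab_mesh.vertices = spec.pose_abutment.apply(ab_mesh.vertices)
    pr_mesh.vertices = spec.pose_prosthesis.apply(pr_mesh.vertices)
    se_mesh.vertices = spec.pose_seated.apply(se_mesh.vertices)

    # --- landmarks (ideal picks; noiseless, posed) ---
    model_lms, pros_lms = _canonical_landmarks(spec)
    ab_landmarks = LandmarkSet(
        spec.pose_abutment.apply(np.array([p for _, p in model_lms])),
        [lab for lab, _ in model_lms],
        frame="abutment_scan",
    )
    pr_landmarks = LandmarkSet(
        spec.pose_prosthesis.apply(np.array([p for _, p in pros_lms])),
        [lab for lab, _ in pros_lms],
        frame="prosthesis_scan",
    )
    seated_all = model_lms[:4] + pros_lms  # plate corners + prosthesis landmarks
    se_landmarks = LandmarkSet(
        spec.pose_seated.apply(np.array([p for _, p in seated_all])),
        [lab for lab, _ in seated_all],
        frame="seated_scan",
    )

    masks_ab = {"context": np.concatenate(ab_context), **ab_prep_masks}
    masks_se = {
        "context": np.concatenate(se_context),
        "prosthesis": se_prosthesis,
    }

    # --- ground truth ---
    angles = np.arange(720) * 0.5
    theta = np.radians(angles)
    amd = [spec.true_amd_um(i, theta) for i in range(spec.n_retainers)]
    gt = GroundTruth(
        angles_deg=angles,
        amd_um=amd,
        mean_amd_um=[float(a.mean()) for a in amd],
        margin_circles=circles,
        pose_abutment=spec.pose_abutment,
        pose_prosthesis=spec.pose_prosthesis,
        pose_seated=spec.pose_seated,
        stage_a=spec.pose_abutment.compose(spec.pose_seated.inverse()),
        stage_b=spec.pose_seated.compose(spec.pose_prosthesis.inverse()),
        seating=spec.pose_abutment.compose(spec.pose_prosthesis.inverse()),
        seed=spec.seed,
    )

    return Triad(
        abutment=ScanDataset(ab_mesh, masks_ab, ab_landmarks, spec.pose_abutment),
        prosthesis=ScanDataset(pr_mesh, pr_masks, pr_landmarks, spec.pose_prosthesis),
        seated=ScanDataset(se_mesh, masks_se, se_landmarks, spec.pose_seated),
        ground_truth=gt,
        spec=spec,
    )


def _canonical_landmarks(spec: PhantomSpec):
    """(model landmarks, prosthesis landmarks) as (label, point) lists.

    The first four model landmarks are the plate's top corners — the shared
    context used to initialize the seated -> abutment alignment.
    """
    sx, sy = spec.plate_size
    z_top = -spec.skirt_depth
    model = [
        ("plate_c0", np.array([-sx / 2, -sy / 2, z_top])),
        ("plate_c1", np.array([sx / 2, -sy / 2, z_top])),
        ("plate_c2", np.array([sx / 2, sy / 2, z_top])),
        ("plate_c3", np.array([-sx / 2, sy / 2, z_top])),
    ]
    pros = []
    z_ext_top = spec.prep_height + spec.cement_gap + spec.occlusal_thickness
    for i in range(spec.n_retainers):
        c = spec.center(i)
        r = spec.margin_radius
        model.append((f"margin_center_r{i}", c.copy()))
        model.append((f"margin0_r{i}", c + np.array([r, 0.0, 0.0])))
        model.append((f"top_r{i}", c + np.array([0.0, 0.0, spec.prep_height])))
        d0 = float(spec.delta_fn(i)(np.array(0.0)))
        v0 = float(spec.v_fn(i)(np.array(0.0)))
        pros.append((f"crown_top_r{i}", c + np.array([0.0, 0.0, z_ext_top])))
        pros.append((f"crown_margin0_r{i}", c + np.array([r + d0, 0.0, v0])))
    centers = np.array([spec.center(i) for i in range(spec.n_retainers)])
    pros.append(
        (
            "pontic_top",
            centers.mean(axis=0)
            + np.array([0.0, 2.0, spec.prep_height / 2.0 + 3.0]),
        )
    )
    return model, pros


def write_triad(triad: Triad, outdir, mode: str = "binary") -> dict:
    """Write the three STLs, landmark files, masks and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, ds in (
        ("abutment", triad.abutment),
        ("prosthesis", triad.prosthesis),
        ("seated", triad.seated),
    ):
        stl = outdir / f"{name}.stl"
        write_stl(ds.mesh, stl, mode=mode)
        lm = outdir / f"{name}.landmarks.txt"
        write_landmarks(ds.landmarks, lm)
        mask = outdir / f"{name}.masks.json"
        mask.write_text(
            json.dumps({k: v.tolist() for k, v in ds.masks.items()})
        )
        paths[name] = {"stl": str(stl), "landmarks": str(lm), "masks": str(mask)}
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(triad.ground_truth.to_dict(), indent=1))
    paths["ground_truth"] = str(gt_path)
    return paths
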