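"""Rigid registration: landmark (multi-point) alignment and ICP best-fit.

The seating of a prosthesis on its abutments is reconstructed from three
scans by two pairwise alignments, each a coarse landmark registration
followed by iterative-closest-point refinement:

* stage A aligns the *seated* scan into the *abutment* scan's frame using a
  region of the model that is unchanged between the two scans (the context
  around the preparations);
* stage B aligns the *prosthesis-alone* scan onto the prosthesis surface
  visible in the seated scan (the external crown/pontic surface).

Composing the two places the separately scanned prosthesis — including its
margin and intaglio, which are hidden once seated — in the abutment frame,
where marginal discrepancies can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import LandmarkSet, TriangleMesh

_ORTHO_TOL = 1e-8


class RegistrationError(RuntimeError):
    """An alignment stage failed (no overlap, or residual above a gate)."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` with rotation in SO(3).

    ``rotation`` is a 3x3 orthonormal matrix with determinant +1 and
    ``translation`` a 3-vector in mm.  Instances are immutable; composition
    and inversion return new transforms.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.abs(R.T @ R - np.eye(3)).max() > _ORTHO_TOL:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- group operations -------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (``other`` is applied first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @staticmethod
    def from_matrix(M) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        return RigidTransform(M[:3, :3], M[:3, 3])

    # -- metrics -----------------------------------------------------------
    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def rotation_angle_to(self, other: "RigidTransform") -> float:
        return self.inverse().compose(other).rotation_angle()

    def translation_distance_to(self, other: "RigidTransform") -> float:
        return float(np.linalg.norm(self.translation - other.translation))

    # -- serialization / sampling -----------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        return RigidTransform(np.array(d["rotation"]), np.array(d["translation"]))

    @staticmethod
    def random(
        rng: np.random.Generator,
        max_rotation_deg: float = 20.0,
        max_translation: float = 10.0,
    ) -> "RigidTransform":
        """Sample a pose with bounded rotation angle and translation norm."""
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(max_rotation_deg) * rng.uniform()
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        t = direction * max_translation * rng.uniform()
        return RigidTransform(R, t)


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` onto ``target``.

    Standard SVD solution of the orthogonal Procrustes problem with the
    determinant correction that forbids reflections.  Requires at least three
    non-collinear correspondences.
    """
    P = np.asarray(source, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError(f"need >= 3 correspondences, got {len(P)}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise ValueError("correspondences are collinear; rotation is underdetermined")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


def landmark_align(source: LandmarkSet, target: LandmarkSet) -> RigidTransform:
    """Coarse multi-point registration from ordered corresponding landmarks."""
    if len(source) != len(target):
        raise ValueError("landmark sets must have equal counts")
    source.require_alignable()
    target.require_alignable()
    return kabsch(source.points, target.points)


@dataclass
class ICPResult:
    """Outcome of an ICP run.

    ``residual_history`` holds the RMS point-to-point residual evaluated at
    each accepted iteration and is non-increasing by construction.
    """

    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool
    residual_history: list[float] = field(default_factory=list)


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, TriangleMesh):
        return obj.vertices.view(np.ndarray)
    pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected a mesh or an (n, 3) point array")
    return pts


def _subsample(points: np.ndarray, n: int) -> np.ndarray:
    if len(points) <= n:
        return points
    idx = np.linspace(0, len(points) - 1, n).astype(np.int64)
    return points[idx]


def icp_refine(
    source,
    target,
    init: RigidTransform | None = None,
    *,
    max_iterations: int = 100,
    tolerance: float = 1e-6,
    trim_fraction: float = 0.0,
    max_correspondence: float | None = None,
    n_samples: int = 20000,
) -> ICPResult:
    """Point-to-point ICP refining ``init`` so ``source`` fits ``target``.

    Correspondences are nearest neighbours of the transformed source points
    in the target point set (mesh vertices when a mesh is given).  The worst
    ``trim_fraction`` of correspondences may be discarded each iteration for
    outlier robustness; ``max_correspondence`` (mm) optionally gates pairs
    entirely.  Iteration stops when the RMS residual improves by less than
    ``tolerance`` mm or after ``max_iterations``.  The reported residual
    history is non-increasing; an iteration that would increase the residual
    terminates the run with the previous best transform.
    """
    src_all = _as_points(source)
    tgt = _as_points(target)
    if len(src_all) == 0 or len(tgt) == 0:
        raise ValueError("empty source or target")
    src = _subsample(src_all, n_samples)
    tree = cKDTree(tgt)
    T = init if init is not None else RigidTransform.identity()
    history: list[float] = []
    converged = False
    iterations = 0
    best_T = T
    for it in range(1, max_iterations + 1):
        iterations = it
        moved = T.apply(src)
        dist, nn = tree.query(moved)
        keep = np.ones(len(src), dtype=bool)
        if max_correspondence is not None:
            keep &= dist <= max_correspondence
            if not keep.any():
                raise RegistrationError(
                    "no overlap: every correspondence exceeds the distance gate"
                )
        if trim_fraction > 0.0:
            kept_d = dist[keep]
            cutoff = np.quantile(kept_d, 1.0 - trim_fraction)
            keep &= dist <= cutoff
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        if history and rms > history[-1]:
            # correspondence switch increased the trimmed objective: stop at best
            converged = True
            break
        history.append(rms)
        best_T = T
        if len(history) >= 2 and history[-2] - history[-1] < tolerance:
            converged = True
            break
        if rms < tolerance:
            converged = True
            break
        step = kabsch(moved[keep], tgt[nn[keep]])
        T = step.compose(T)
    return ICPResult(
        transform=best_T,
        rms=history[-1],
        iterations=iterations,
        converged=converged,
        residual_history=history,
    )


@dataclass
class SeatingResult:
    """Composed seating reconstruction and its two alignment stages."""

    transform: RigidTransform  # prosthesis scan frame -> abutment scan frame
    stage_a: ICPResult  # seated -> abutment
    stage_b: ICPResult  # prosthesis -> seated


def reconstruct_seating(
    abutment_scan: TriangleMesh,
    prosthesis_scan: TriangleMesh,
    seated_scan: TriangleMesh,
    *,
    abutment_context: np.ndarray,
    seated_context: np.ndarray,
    prosthesis_external: np.ndarray,
    seated_prosthesis: np.ndarray,
    landmarks_seated: LandmarkSet | None = None,
    landmarks_abutment: LandmarkSet | None = None,
    landmarks_prosthesis: LandmarkSet | None = None,
    landmarks_seated_prosthesis: LandmarkSet | None = None,
    rms_gate: float | None = None,
    **icp_kwargs,
) -> SeatingResult:
    """Two pairwise alignments reconstructing the virtual 3D seating fit.

    The mask arguments are vertex-index arrays selecting, in each scan, the
    region that anchors the corresponding alignment.  Landmark sets, when
    given, provide the coarse initialization of each ICP stage.  ``rms_gate``
    (mm) rejects a stage whose refined RMS residual stays above it.
    """
    for name, mask in (
        ("abutment_context", abutment_context),
        ("seated_context", seated_context),
        ("prosthesis_external", prosthesis_external),
        ("seated_prosthesis", seated_prosthesis),
    ):
        if np.size(mask) == 0:
            raise ValueError(f"mask '{name}' is empty")

    init_a = None
    if landmarks_seated is not None and landmarks_abutment is not None:
        init_a = landmark_align(landmarks_seated, landmarks_abutment)
    stage_a = icp_refine(
        seated_scan.vertices.view(np.ndarray)[np.asarray(seated_context)],
        abutment_scan.vertices.view(np.ndarray)[np.asarray(abutment_context)],
        init=init_a,
        **icp_kwargs,
    )
    if rms_gate is not None and stage_a.rms > rms_gate:
        raise RegistrationError(
            f"stage A (seated -> abutment) rms {stage_a.rms:.6f} mm exceeds gate {rms_gate}"
        )

    init_b = None
    if landmarks_prosthesis is not None and landmarks_seated_prosthesis is not None:
        init_b = landmark_align(landmarks_prosthesis, landmarks_seated_prosthesis)
    stage_b = icp_refine(
        prosthesis_scan.vertices.view(np.ndarray)[np.asarray(prosthesis_external)],
        seated_scan.vertices.view(np.ndarray)[np.asarray(seated_prosthesis)],
        init=init_b,
        **icp_kwargs,
    )
    if rms_gate is not None and stage_b.rms > rms_gate:
        raise RegistrationError(
            f"stage B (prosthesis -> seated) rms {stage_b.rms:.6f} mm exceeds gate {rms_gate}"
        )

    return SeatingResult(
        transform=stage_a.transform.compose(stage_b.transform),
        stage_a=stage_a,
        stage_b=stage_b,
    )
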