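"""Triangle-mesh and landmark input/output.

Every scan dataset in the pipeline is an indexed triangle surface held in a
:class:`trimesh.Trimesh`.  STL files carry no units; this package interprets
all coordinates as millimetres and reports marginal discrepancies in
micrometres.  STL stores one vertex triple per facet, so meshes are welded on
load (exact-duplicate merge at a small tolerance) — edge-adjacency analysis
downstream requires shared vertex indices.

Landmark files replace the interactive point picking of a desktop reverse
engineering workflow: plain text, one point per line ``label x y z``, with
``#`` comments.
"""

from __future__ import annotations

import io
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

#: canonical in-memory mesh container for the whole package
TriangleMesh = trimesh.Trimesh

#: default vertex-weld tolerance in mm; merges exact duplicates only
DEFAULT_WELD_TOL = 1e-6


class MeshIOError(ValueError):
    """A mesh violates basic structural requirements."""


class STLParseError(MeshIOError):
    """An STL file is structurally malformed."""


def make_mesh(vertices, faces, name: str = "") -> TriangleMesh:
    """Build a validated mesh without any automatic processing.

    Raises :class:`MeshIOError` on empty input, non-finite coordinates,
    out-of-range face indices or degenerate faces (repeated vertex index).
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if vertices.size == 0 or faces.size == 0:
        raise MeshIOError("empty mesh: a mesh needs at least one face")
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise MeshIOError(f"vertices must be (n, 3), got {vertices.shape}")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshIOError(f"faces must be (m, 3), got {faces.shape}")
    if not np.isfinite(vertices).all():
        raise MeshIOError("non-finite vertex coordinates")
    if faces.min() < 0 or faces.max() >= len(vertices):
        raise MeshIOError("face index out of range")
    if _degenerate_mask(faces).any():
        raise MeshIOError("degenerate face (repeated vertex index)")
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.metadata["name"] = name
    return mesh


def _degenerate_mask(faces: np.ndarray) -> np.ndarray:
    return (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )


def weld_vertices(mesh: TriangleMesh, tol: float = DEFAULT_WELD_TOL) -> TriangleMesh:
    """Merge vertices that coincide within ``tol`` mm into shared indices.

    Vertices are snapped onto a grid of pitch ``tol`` for grouping; the
    representative coordinate is the first original vertex of each group and
    representatives keep their original relative order, so geometry is
    untouched, welding is idempotent, and an already-welded mesh round-trips
    with identical vertex indices.  Faces that collapse to fewer than three
    distinct vertices are dropped.
    """
    v = mesh.vertices.view(np.ndarray)
    keys = np.round(v / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)  # restore original ordering of representatives
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    first = first[order]
    inverse = rank[inverse]
    faces = inverse[mesh.faces]
    faces = faces[~_degenerate_mask(faces)]
    if len(faces) == 0:
        raise MeshIOError("welding collapsed every face")
    return make_mesh(v[first], faces, name=mesh.metadata.get("name", ""))


def read_stl(path, weld_tol: float = DEFAULT_WELD_TOL) -> TriangleMesh:
    """Read a binary or ASCII STL file and return a welded mesh.

    A binary file whose declared facet count disagrees with its length raises
    :class:`STLParseError` naming the byte offset of the count field.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 15:
        raise STLParseError(f"{path}: too short to be an STL file")
    looks_ascii = data.lstrip()[:5].lower() == b"solid"
    binary_consistent = False
    if len(data) >= 84:
        (n_facets,) = struct.unpack_from("<I", data, 80)
        binary_consistent = len(data) == 84 + 50 * n_facets
    if not looks_ascii and not binary_consistent:
        if len(data) < 84:
            raise STLParseError(
                f"{path}: truncated binary STL, header+count need 84 bytes, got {len(data)}"
            )
        raise STLParseError(
            f"{path}: facet count {n_facets} declared at byte offset 80 implies "
            f"{84 + 50 * n_facets} bytes, file has {len(data)}"
        )
    try:
        mesh = trimesh.load(io.BytesIO(data), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - wrap any decoder failure
        raise STLParseError(f"{path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshIOError(f"{path}: empty mesh")
    welded = weld_vertices(mesh, tol=weld_tol)
    welded.metadata["name"] = path.stem
    return welded


def write_stl(mesh: TriangleMesh, path, mode: str = "binary") -> None:
    """Write ``mesh`` as STL; ``mode`` is ``"binary"`` or ``"ascii"``."""
    if mode not in ("binary", "ascii"):
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    if len(mesh.faces) == 0 or len(mesh.vertices) == 0:
        raise MeshIOError("refusing to write an empty mesh")
    file_type = "stl" if mode == "binary" else "stl_ascii"
    out = mesh.export(file_type=file_type)
    Path(path).write_bytes(out.encode() if isinstance(out, str) else out)


@dataclass(frozen=True)
class ValidationReport:
    """Structural summary of a mesh; informative only, never mutates."""

    n_vertices: int
    n_faces: int
    n_degenerate_faces: int
    n_nonmanifold_edges: int
    n_boundary_edges: int
    n_components: int
    watertight: bool

    def to_dict(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "n_faces": self.n_faces,
            "n_degenerate_faces": self.n_degenerate_faces,
            "n_nonmanifold_edges": self.n_nonmanifold_edges,
            "n_boundary_edges": self.n_boundary_edges,
            "n_components": self.n_components,
            "watertight": self.watertight,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def validate_mesh(mesh: TriangleMesh) -> ValidationReport:
    """Count degenerate faces, non-manifold and boundary edges, components."""
    faces = mesh.faces.view(np.ndarray)
    n_degen = int(_degenerate_mask(faces).sum())
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    n_nonmanifold = int((counts > 2).sum())
    n_boundary = int((counts == 1).sum())
    nv = len(mesh.vertices)
    adj = coo_matrix(
        (np.ones(len(uniq)), (uniq[:, 0], uniq[:, 1])), shape=(nv, nv)
    )
    n_comp_all, labels = connected_components(adj, directed=False)
    used = np.zeros(nv, dtype=bool)
    used[faces.ravel()] = True
    n_components = len(np.unique(labels[used])) if used.any() else 0
    return ValidationReport(
        n_vertices=nv,
        n_faces=len(faces),
        n_degenerate_faces=n_degen,
        n_nonmanifold_edges=n_nonmanifold,
        n_boundary_edges=n_boundary,
        n_components=n_components,
        watertight=bool(n_boundary == 0 and n_nonmanifold == 0 and n_degen == 0),
    )


@dataclass
class LandmarkSet:
    """Ordered 3D points standing in for interactively picked positions.

    ``frame`` names the dataset whose coordinate system the points live in
    (e.g. ``"abutment_scan"``).  For rigid alignment a set must contain at
    least three non-collinear points in corresponding order.
    """

    points: np.ndarray
    labels: list[str] = field(default_factory=list)
    frame: str = ""

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("landmark points must be (n, 3)")
        if not self.labels:
            self.labels = [f"p{i}" for i in range(len(self.points))]
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, labels) -> "LandmarkSet":
        """Select points by label, in the order given."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        idx = [index[lab] for lab in labels]
        return LandmarkSet(self.points[idx], list(labels), self.frame)

    def is_collinear(self, tol: float = 1e-9) -> bool:
        c = self.points - self.points.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        scale = max(s[0], 1.0)
        return bool(len(s) < 2 or s[1] <= tol * scale)

    def require_alignable(self) -> None:
        if len(self) < 3:
            raise ValueError(f"need >= 3 landmarks for alignment, got {len(self)}")
        if self.is_collinear():
            raise ValueError("landmarks are collinear; rigid alignment is degenerate")


def read_landmarks(path, frame: str = "") -> LandmarkSet:
    """Parse a ``label x y z`` text file (``#`` starts a comment)."""
    labels, pts = [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'label x y z', got {raw!r}")
        labels.append(parts[0])
        pts.append([float(x) for x in parts[1:]])
    if not pts:
        raise ValueError(f"{path}: no landmarks found")
    return LandmarkSet(np.array(pts), labels, frame=frame or Path(path).stem)


def write_landmarks(lms: LandmarkSet, path) -> None:
    lines = [f"# frame: {lms.frame}"]
    for lab, p in zip(lms.labels, lms.points):
        lines.append(f"{lab} {p[0]:.9f} {p[1]:.9f} {p[2]:.9f}")
    Path(path).write_text("\n".join(lines) + "\n")
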