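"""Margin-line extraction: sharp feature edges chained into closed loops.

A preparation finished with a 90 degree shoulder meets its axial wall and
its cervical surface along sharp creases; the crown margin is likewise a
crease (or an open boundary) between the intaglio and the external surface.
"Edge sharpening" is realized here as the classic dihedral-angle operator:
an interior mesh edge is a feature edge when its two adjacent faces deviate
from coplanar by more than a threshold; boundary edges always count.
Feature edges are chained into polylines, closed chains become candidate
margin loops, and the margin itself is selected as the outermost closed
loop within an axial band around the expected margin height.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh_io import TriangleMesh


class MarginNotFoundError(RuntimeError):
    """No closed loop qualifies as the margin in the requested band."""


class MarginAmbiguityError(RuntimeError):
    """Two candidate loops are radially indistinguishable."""


@dataclass
class MarginLoop:
    """Ordered 3D polyline of a (candidate) margin edge.

    ``closed`` loops implicitly connect the last point back to the first;
    the closing point is not duplicated.
    """

    points: np.ndarray
    closed: bool
    source: str = ""
    retainer_id: int | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("loop points must be (n, 3)")
        if len(self.points) < 2:
            raise ValueError("a loop needs at least 2 points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def segment_lengths(self) -> np.ndarray:
        p = self.points
        nxt = np.roll(p, -1, axis=0) if self.closed else p[1:]
        cur = p if self.closed else p[:-1]
        return np.linalg.norm(nxt - cur, axis=1)

    @property
    def length(self) -> float:
        return float(self.segment_lengths().sum())

    def transformed(self, transform) -> "MarginLoop":
        return MarginLoop(
            transform.apply(self.points), self.closed, self.source, self.retainer_id
        )


def detect_feature_edges(
    mesh: TriangleMesh, dihedral_deg: float = 30.0
) -> np.ndarray:
    """Return (n, 2) vertex-index pairs of sharp and boundary edges.

    An interior edge is sharp when the angle between its adjacent face
    normals exceeds ``dihedral_deg`` (i.e. the dihedral deviates from pi by
    more than the threshold).  The mesh must be welded so that adjacency is
    expressed through shared vertex indices.
    """
    threshold = np.radians(dihedral_deg)
    out = [np.empty((0, 2), dtype=np.int64)]
    if len(mesh.face_adjacency) > 0:
        sharp = mesh.face_adjacency_angles > threshold
        out.append(mesh.face_adjacency_edges[sharp].astype(np.int64))
    uniq, counts = np.unique(mesh.edges_sorted.view(np.ndarray), axis=0, return_counts=True)
    out.append(uniq[counts == 1].astype(np.int64))  # boundary edges
    edges = np.vstack(out)
    if len(edges) == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.sort(edges, axis=1), axis=0)


def branch_vertices(edges: np.ndarray) -> np.ndarray:
    """Vertices where more than two feature edges meet (chains split here)."""
    if len(edges) == 0:
        return np.empty(0, dtype=np.int64)
    verts, counts = np.unique(edges.ravel(), return_counts=True)
    return verts[counts > 2]


def chain_edges_to_loops(
    edges: np.ndarray,
    vertices: np.ndarray,
    gap_close: float = 0.0,
    source: str = "",
    max_turn_deg: float = 60.0,
    min_stitch_points: int = 3,
) -> list[MarginLoop]:
    """Chain shared-endpoint edges into ordered polylines.

    At a branch vertex (more than two incident feature edges) the walk
    continues along the *straightest* unused edge, provided the turn stays
    below ``max_turn_deg``; otherwise the chain ends there.  On clean
    meshes this reduces to ordinary chaining split at branches (a crease
    meeting another at a right angle never continues through it), while on
    noisy scans it traces a margin crease straight through the short
    spurious stubs that surface noise hangs onto it.  Cycles become closed
    loops; open chains are kept and flagged.

    When ``gap_close`` > 0, open chains of at least ``min_stitch_points``
    points whose endpoints lie within that distance (mm) are stitched
    together, and a chain whose own endpoints meet within the gap is
    closed — a minimal repair for fragmented feature edges.
    """
    vertices = np.asarray(vertices, dtype=float)
    if len(edges) == 0:
        return []
    min_cos = np.cos(np.radians(max_turn_deg))
    adjacency: dict[int, list[int]] = defaultdict(list)
    for ei, (a, b) in enumerate(edges):
        adjacency[int(a)].append(ei)
        adjacency[int(b)].append(ei)
    used = np.zeros(len(edges), dtype=bool)

    def _edge_dir(v_from: int, ei: int) -> tuple[int, np.ndarray]:
        a, b = int(edges[ei][0]), int(edges[ei][1])
        v_to = b if a == v_from else a
        d = vertices[v_to] - vertices[v_from]
        n = np.linalg.norm(d)
        return v_to, (d / n if n > 0 else d)

    def walk(v: int, ei: int, start: int) -> list[int]:
        """Follow edges from ``v`` through ``ei``, straightest-first."""
        path = [v]
        prev_dir = None
        while True:
            used[ei] = True
            v, prev_dir = _edge_dir(v, ei)
            path.append(v)
            if v == start:
                return path
            best, best_cos = None, min_cos
            for cand in adjacency[v]:
                if used[cand]:
                    continue
                _, d = _edge_dir(v, cand)
                c = float(prev_dir @ d)
                if c >= best_cos:
                    best, best_cos = cand, c
            if best is None:
                return path
            ei = best

    chains: list[list[int]] = []
    for ei in range(len(edges)):
        if used[ei]:
            continue
        a = int(edges[ei][0])
        forward = walk(a, ei, start=a)
        if forward[0] == forward[-1]:
            chains.append(forward)
            continue
        # extend backwards from the seed vertex along the reverse direction
        back_dir = vertices[a] - vertices[forward[1]]
        n = np.linalg.norm(back_dir)
        back_dir = back_dir / n if n > 0 else back_dir
        backward = [a]
        v, prev_dir = a, back_dir
        while True:
            best, best_cos = None, min_cos
            for cand in adjacency[v]:
                if used[cand]:
                    continue
                _, d = _edge_dir(v, cand)
                c = float(prev_dir @ d)
                if c >= best_cos:
                    best, best_cos = cand, c
            if best is None:
                break
            used[best] = True
            v, prev_dir = _edge_dir(v, best)
            backward.append(v)
        chains.append(backward[::-1][:-1] + forward)

    loops: list[MarginLoop] = []
    open_chains: list[list[int]] = []
    for chain in chains:
        if len(chain) >= 4 and chain[0] == chain[-1]:
            loops.append(MarginLoop(vertices[chain[:-1]], closed=True, source=source))
        else:
            open_chains.append(chain)

    if gap_close > 0.0:
        stitchable = [c for c in open_chains if len(c) >= min_stitch_points]
        rest = [c for c in open_chains if len(c) < min_stitch_points]
        open_chains = _stitch_chains(stitchable, vertices, gap_close) + rest
    for chain in open_chains:
        if len(chain) >= 4 and chain[0] == chain[-1]:
            loops.append(MarginLoop(vertices[chain[:-1]], closed=True, source=source))
        elif (
            gap_close > 0.0
            and len(chain) >= 3
            and np.linalg.norm(vertices[chain[0]] - vertices[chain[-1]]) <= gap_close
        ):
            loops.append(MarginLoop(vertices[chain], closed=True, source=source))
        elif len(chain) >= 2:
            loops.append(MarginLoop(vertices[chain], closed=False, source=source))
    return loops


def _stitch_chains(
    chains: list[list[int]], vertices: np.ndarray, gap: float
) -> list[list[int]]:
    """Greedily join open chains whose endpoints are within ``gap`` mm.

    Endpoint pairs within the gap are matched greedily by increasing
    distance, each endpoint participating in at most one join, so the
    joined structure is a disjoint set of paths and cycles of chains; the
    merged polylines are then read off by traversal.  A cycle comes back
    as an open polyline whose ends meet within the gap, which the caller
    closes.
    """
    from scipy.spatial import cKDTree

    chains = [list(c) for c in chains]
    k = len(chains)
    if k < 2:
        return chains
    ends = np.array(
        [vertices[c[e]] for c in chains for e in (0, -1)]
    )  # endpoint e of chain i at index 2*i + e
    pairs = cKDTree(ends).query_pairs(gap, output_type="ndarray")
    if len(pairs) == 0:
        return chains
    dist = np.linalg.norm(ends[pairs[:, 0]] - ends[pairs[:, 1]], axis=1)
    partner = np.full(2 * k, -1, dtype=np.int64)
    for a, b in pairs[np.argsort(dist)]:
        if partner[a] >= 0 or partner[b] >= 0 or a // 2 == b // 2:
            continue
        partner[a], partner[b] = b, a

    merged: list[list[int]] = []
    visited = np.zeros(k, dtype=bool)

    def emit(start_chain: int, start_end: int) -> list[int]:
        """Walk chain-to-chain from the given endpoint, flipping as needed."""
        seq: list[int] = []
        ci, entry = start_chain, start_end
        while True:
            visited[ci] = True
            body = chains[ci] if entry == 2 * ci else chains[ci][::-1]
            seq.extend(body if not seq else (body[1:] if seq[-1] == body[0] else body))
            exit_ep = 2 * ci + 1 if entry == 2 * ci else 2 * ci
            nxt = partner[exit_ep]
            if nxt < 0 or visited[nxt // 2]:
                return seq
            ci, entry = nxt // 2, nxt

    for i in range(k):
        if visited[i]:
            continue
        free = [e for e in (2 * i, 2 * i + 1) if partner[e] < 0]
        if free:  # path: start from a free endpoint
            merged.append(emit(i, free[0]))
        else:  # cycle of chains: start anywhere
            merged.append(emit(i, 2 * i))
    return merged


def _axial_height(points: np.ndarray, origin, direction) -> np.ndarray:
    return (points - np.asarray(origin)) @ np.asarray(direction)


def _radial_distance(points: np.ndarray, origin, direction) -> np.ndarray:
    rel = points - np.asarray(origin)
    h = rel @ np.asarray(direction)
    return np.linalg.norm(rel - np.outer(h, direction), axis=1)


def select_margin_loop(
    loops: list[MarginLoop],
    origin,
    direction,
    band: tuple[float, float],
    min_points: int = 16,
    ambiguity_tol: float = 1e-3,
) -> MarginLoop:
    """Pick the outer margin among candidate loops.

    Considers closed loops with at least ``min_points`` points whose mean
    axial height (along ``direction`` from ``origin``) lies within ``band``
    and returns the one with the greatest mean radial distance from the
    axis — the shoulder's *outer* edge, as opposed to its inner edge or the
    axial-wall crease.  Raises :class:`MarginNotFoundError` when no loop
    qualifies and :class:`MarginAmbiguityError` when the two outermost
    candidates differ by less than ``ambiguity_tol`` mm in mean radius.
    """
    candidates = []
    for loop in loops:
        if not loop.closed or len(loop) < min_points:
            continue
        h = float(_axial_height(loop.points, origin, direction).mean())
        if band[0] <= h <= band[1]:
            r = float(_radial_distance(loop.points, origin, direction).mean())
            candidates.append((r, loop))
    if not candidates:
        raise MarginNotFoundError(
            f"margin not found: no closed loop with mean height in {band}"
        )
    candidates.sort(key=lambda c: c[0], reverse=True)
    if len(candidates) > 1 and candidates[0][0] - candidates[1][0] < ambiguity_tol:
        raise MarginAmbiguityError(
            "two candidate loops have mean radii within "
            f"{ambiguity_tol} mm ({candidates[0][0]:.4f} vs {candidates[1][0]:.4f})"
        )
    return orient_loop_ccw(candidates[0][1], origin, direction)


def orient_loop_ccw(loop: MarginLoop, origin, direction) -> MarginLoop:
    """Order a closed loop counter-clockwise viewed from +``direction``."""
    if not loop.closed:
        return loop
    direction = np.asarray(direction, dtype=float)
    rel = loop.points - np.asarray(origin)
    rel -= np.outer(rel @ direction, direction)
    cross = np.cross(rel, np.roll(rel, -1, axis=0))
    if float((cross @ direction).sum()) < 0:
        return MarginLoop(
            loop.points[::-1].copy(), True, loop.source, loop.retainer_id
        )
    return loop


def resample_loop(loop: MarginLoop, n: int = 720) -> MarginLoop:
    """Arc-length resample a closed loop to exactly ``n`` points."""
    if not loop.closed:
        raise ValueError("resampling is defined for closed loops")
    seg = loop.segment_lengths()
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    pts = np.vstack([loop.points, loop.points[:1]])
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.column_stack(
        [np.interp(targets, s, pts[:, k]) for k in range(3)]
    )
    return MarginLoop(out, True, loop.source, loop.retainer_id)


def smooth_loop(loop: MarginLoop, window: int = 5) -> MarginLoop:
    """Circular moving-average smoothing of a closed loop.

    Damps scanner noise on the extracted polyline; the window should stay
    small relative to the loop so curvature flattening is negligible.
    """
    if window <= 1:
        return loop
    if not loop.closed:
        raise ValueError("smoothing is defined for closed loops")
    if window % 2 == 0:
        window += 1
    half = window // 2
    p = loop.points
    padded = np.vstack([p[-half:], p, p[:half]])
    kernel = np.ones(window) / window
    out = np.column_stack(
        [np.convolve(padded[:, k], kernel, mode="valid") for k in range(3)]
    )
    return MarginLoop(out, True, loop.source, loop.retainer_id)


def loops_near(
    loops: list[MarginLoop], center, max_distance: float
) -> list[MarginLoop]:
    """Filter loops whose centroid lies within ``max_distance`` of a point."""
    center = np.asarray(center, dtype=float)
    return [
        lp for lp in loops if np.linalg.norm(lp.centroid - center) <= max_distance
    ]
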