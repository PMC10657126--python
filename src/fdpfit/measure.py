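"""Absolute marginal discrepancy from paired margin-edge samples.

Each retainer/abutment pair is sampled by a fan of radial half-planes
through the preparation's central axis: 25 axial sections give 50
half-plane curves at 7.2 degree spacing; intersecting both margin loops
with the fan yields 50 abutment points plus 50 crown points (100 in all),
paired by shared azimuth.  The absolute marginal discrepancy (AMD) at an
azimuth is the straight-line 3D distance between the paired points,
reported in micrometres.  A mean AMD below 120 um is conventionally taken
as clinically acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .margins import MarginLoop

#: conventional clinical-acceptability threshold for mean marginal fit (um)
CLINICAL_THRESHOLD_UM = 120.0


@dataclass(frozen=True)
class AxisFrame:
    """Central axis of a retainer/abutment pair plus an azimuth reference.

    ``direction`` points occlusally (away from the margin, toward the
    preparation surface); ``azimuth_ref`` is a unit vector orthogonal to it
    defining theta = 0.
    """

    origin: np.ndarray
    direction: np.ndarray
    azimuth_ref: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        u = np.asarray(self.azimuth_ref, dtype=float).reshape(3)
        if abs(np.linalg.norm(d) - 1) > 1e-8 or abs(np.linalg.norm(u) - 1) > 1e-8:
            raise ValueError("direction and azimuth_ref must be unit vectors")
        if abs(d @ u) > 1e-8:
            raise ValueError("azimuth_ref must be orthogonal to direction")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "azimuth_ref", u)

    @property
    def binormal(self) -> np.ndarray:
        return np.cross(self.direction, self.azimuth_ref)

    def heights(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.origin) @ self.direction

    def radii(self, points: np.ndarray) -> np.ndarray:
        rel = np.asarray(points) - self.origin
        h = rel @ self.direction
        return np.linalg.norm(rel - np.outer(h, self.direction), axis=1)


def estimate_axis(
    loop: MarginLoop,
    surface_points: np.ndarray | None = None,
    reference=(1.0, 0.0, 0.0),
) -> AxisFrame:
    """Axis from a margin loop: centroid + best-fit-plane normal.

    The normal of the loop's best-fit plane (smallest principal component)
    is oriented toward the side containing the centroid of
    ``surface_points`` (the preparation surface — its bulk lies occlusal to
    the margin).  Theta = 0 is the projection of ``reference`` (a fixed
    global axis) onto the margin plane, falling back to +y when the
    reference is parallel to the axis.
    """
    if not loop.closed:
        raise ValueError("axis estimation needs a closed margin loop")
    pts = loop.points
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(s[0], 1e-30)
    if s[1] <= 1e-9 * scale:
        raise ValueError("degenerate loop: best-fit plane undefined")
    direction = vt[2]
    if surface_points is not None and len(surface_points):
        far = np.asarray(surface_points, dtype=float).mean(axis=0)
        if (far - centroid) @ direction < 0:
            direction = -direction
    ref = np.asarray(reference, dtype=float)
    u = ref - (ref @ direction) * direction
    if np.linalg.norm(u) < 1e-6:  # reference parallel to axis: tie-break to +y
        ref = np.array([0.0, 1.0, 0.0])
        u = ref - (ref @ direction) * direction
    u /= np.linalg.norm(u)
    return AxisFrame(centroid, direction, u)


@dataclass(frozen=True)
class SectionFan:
    """Uniform fan of radial half-planes through a central axis.

    ``n_sections`` axial sections produce ``2 * n_sections`` half-planes
    (each section contributes the curve on either side of the axis); at the
    default 25 sections the azimuth spacing is 7.2 degrees.
    """

    axis: AxisFrame
    n_sections: int = 25

    def __post_init__(self):
        if self.n_sections < 8:
            raise ValueError(f"n_sections must be >= 8, got {self.n_sections}")

    @property
    def n_half_planes(self) -> int:
        return 2 * self.n_sections

    @property
    def azimuths_deg(self) -> np.ndarray:
        return np.arange(self.n_half_planes) * (360.0 / self.n_half_planes)

    def half_plane_directions(self) -> np.ndarray:
        """(m, 3) unit in-plane direction of each half-plane."""
        t = np.radians(self.azimuths_deg)
        return (
            np.cos(t)[:, None] * self.axis.azimuth_ref
            + np.sin(t)[:, None] * self.axis.binormal
        )


def build_section_fan(axis: AxisFrame, n_sections: int = 25) -> SectionFan:
    return SectionFan(axis=axis, n_sections=n_sections)


@dataclass
class FanIntersections:
    """Per-azimuth intersection of a margin loop with a section fan."""

    points: np.ndarray  # (m, 3); NaN rows where missing
    missing: np.ndarray  # (m,) bool
    n_ambiguous: int  # azimuths with >1 crossing (outermost kept)

    @property
    def n_valid(self) -> int:
        return int((~self.missing).sum())


def intersect_loop_with_fan(loop: MarginLoop, fan: SectionFan) -> FanIntersections:
    """Intersect a closed margin polyline with every half-plane of a fan.

    Each crossing segment is interpolated linearly.  A loop star-shaped
    about the axis yields exactly one point per azimuth; extra crossings
    keep the outermost point (the AMD landmark is the outer edge) and are
    counted; azimuths with no crossing are marked missing.
    """
    if not loop.closed:
        raise ValueError("fan intersection needs a closed loop")
    axis = fan.axis
    pts = loop.points - axis.origin
    nxt = np.roll(pts, -1, axis=0)
    m = fan.n_half_planes
    out = np.full((m, 3), np.nan)
    missing = np.ones(m, dtype=bool)
    n_ambiguous = 0
    u_all = fan.half_plane_directions()
    d = axis.direction
    for k in range(m):
        u = u_all[k]
        normal = np.cross(d, u)
        s0 = pts @ normal
        s1 = nxt @ normal
        s0 = np.where(s0 == 0.0, 1e-300, s0)  # on-plane vertices: nudge
        s1 = np.where(s1 == 0.0, 1e-300, s1)
        crossing = np.sign(s0) != np.sign(s1)
        if not crossing.any():
            continue
        t = s0[crossing] / (s0[crossing] - s1[crossing])
        p = pts[crossing] + t[:, None] * (nxt[crossing] - pts[crossing])
        side = p @ u
        p = p[side > 0]
        if len(p) == 0:
            continue
        if len(p) > 1:
            n_ambiguous += 1
            h = p @ d
            radii = np.linalg.norm(p - np.outer(h, d), axis=1)
            p = p[np.argmax(radii)][None, :]
        out[k] = p[0] + axis.origin
        missing[k] = False
    return FanIntersections(points=out, missing=missing, n_ambiguous=n_ambiguous)


@dataclass
class AMDProfile:
    """Fifty paired margin points and their distances for one retainer.

    Distances are in micrometres; summary statistics are computed over the
    valid (non-missing) azimuths only, with ``n_missing`` always reported.
    """

    retainer_id: int
    angles_deg: np.ndarray
    abutment_points: np.ndarray
    crown_points: np.ndarray
    distances_um: np.ndarray
    n_missing: int = 0
    n_ambiguous: int = 0

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.distances_um)

    @property
    def mean_um(self) -> float:
        return float(np.nanmean(self.distances_um))

    @property
    def sd_um(self) -> float:
        v = self.distances_um[self.valid]
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0

    @property
    def min_um(self) -> float:
        return float(np.nanmin(self.distances_um))

    @property
    def max_um(self) -> float:
        return float(np.nanmax(self.distances_um))

    def summary(self) -> dict:
        return {
            "retainer_id": self.retainer_id,
            "n_valid": int(self.valid.sum()),
            "n_missing": self.n_missing,
            "n_ambiguous": self.n_ambiguous,
            "mean_um": self.mean_um,
            "sd_um": self.sd_um,
            "min_um": self.min_um,
            "max_um": self.max_um,
        }


def compute_amd(
    abutment_points: np.ndarray,
    crown_points: np.ndarray,
    angles_deg: np.ndarray,
    retainer_id: int = 0,
    n_ambiguous: int = 0,
) -> AMDProfile:
    """Pair margin points by shared azimuth and measure their 3D distance.

    The straight-line Euclidean distance between the abutment margin point
    and the crown margin point at each azimuth, converted mm -> um.  Either
    point missing (NaN) at an azimuth leaves that azimuth missing.
    """
    ab = np.asarray(abutment_points, dtype=float)
    cr = np.asarray(crown_points, dtype=float)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if ab.shape != cr.shape or len(ab) != len(angles_deg):
        raise ValueError("point sets and angles must be index-aligned")
    dist_um = np.linalg.norm(cr - ab, axis=1) * 1000.0
    missing = np.isnan(dist_um)
    if missing.all():
        raise ValueError("all azimuths missing: no valid margin point pairs")
    return AMDProfile(
        retainer_id=retainer_id,
        angles_deg=angles_deg,
        abutment_points=ab,
        crown_points=cr,
        distances_um=dist_um,
        n_missing=int(missing.sum()),
        n_ambiguous=n_ambiguous,
    )


@dataclass(frozen=True)
class AcceptabilityResult:
    acceptable: bool
    mean_um: float
    threshold_um: float
    fraction_exceeding: float


def classify_acceptability(
    profile: AMDProfile, threshold_um: float = CLINICAL_THRESHOLD_UM
) -> AcceptabilityResult:
    """Strictly-below-threshold test of the mean AMD of one retainer.

    Also reports the fraction of valid azimuths individually exceeding the
    threshold, a more local view of the misfit distribution.
    """
    valid = profile.distances_um[profile.valid]
    return AcceptabilityResult(
        acceptable=bool(profile.mean_um < threshold_um),
        mean_um=profile.mean_um,
        threshold_um=threshold_um,
        fraction_exceeding=float((valid > threshold_um).mean()),
    )


def summarize_prosthesis(
    profiles: list[AMDProfile], rule: str = "mean_of_retainers"
) -> float:
    """Reduce per-retainer profiles to one AMD value (um) per prosthesis.

    ``mean_of_retainers`` (default) averages the retainer means with equal
    weight; ``pooled`` averages all valid distances across retainers, which
    weights retainers by their valid azimuth counts.
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    if rule == "mean_of_retainers":
        return float(np.mean([p.mean_um for p in profiles]))
    if rule == "pooled":
        pooled = np.concatenate([p.distances_um[p.valid] for p in profiles])
        return float(pooled.mean())
    raise ValueError(f"unknown rule {rule!r}")


def measure_retainer_amd(
    abutment_loop: MarginLoop,
    crown_loop: MarginLoop,
    axis: AxisFrame,
    n_sections: int = 25,
    retainer_id: int = 0,
) -> AMDProfile:
    """Convenience composition: fan build, dual intersection, AMD.

    Both loops are intersected with the *same* fan built on the abutment's
    axis, so points are paired by shared radial half-plane.
    """
    fan = build_section_fan(axis, n_sections)
    hit_ab = intersect_loop_with_fan(abutment_loop, fan)
    hit_cr = intersect_loop_with_fan(crown_loop, fan)
    return compute_amd(
        hit_ab.points,
        hit_cr.points,
        fan.azimuths_deg,
        retainer_id=retainer_id,
        n_ambiguous=hit_ab.n_ambiguous + hit_cr.n_ambiguous,
    )
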