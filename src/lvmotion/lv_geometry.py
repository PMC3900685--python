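"""Left-ventricular landmark grid, AHA segmentation, and kinematic descriptors.

The acquisition layout modelled here is the two-surface LV cloud: for each
of endocardium and epicardium, 36 horizontal circles of 36 landmarks plus
the apex (1297 landmarks per surface, 2594 in total, 7782 flattened
coordinates).  Landmarks are ordered level-major (base first), then by
meridian, apex last; the endocardial surface precedes the epicardial one.

Descriptors: cavity volume (divergence theorem over the triangulated
surface plus a planar basal cap), ejection fraction, and per-level
rotation / twist / torsion about the long axis (base-ring centroid to
apex; counterclockwise viewed from the apex is positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_LEVELS = 36
DEFAULT_MERIDIANS = 36

BASAL_SEGMENTS = ["BA", "BAS", "BS", "BI", "BP", "BL"]
MIDDLE_SEGMENTS = ["MA", "MAS", "MS", "MI", "MP", "ML"]
APICAL_SEGMENTS = ["AA", "AS", "AI", "AL"]
ALL_SEGMENTS = BASAL_SEGMENTS + MIDDLE_SEGMENTS + APICAL_SEGMENTS


def grid_size(levels: int = DEFAULT_LEVELS, meridians: int = DEFAULT_MERIDIANS) -> int:
    """Landmarks per surface: levels x meridians + 1 apex."""
    return levels * meridians + 1


def build_surface_grid(
    radius: float,
    length: float,
    levels: int = DEFAULT_LEVELS,
    meridians: int = DEFAULT_MERIDIANS,
) -> np.ndarray:
    """Sample a truncated half-ellipsoid surface on the LV grid.

    The surface is a prolate semi-ellipsoid with equatorial radius
    ``radius`` (mm) at the base plane z = 0 and apex at z = ``-length``.
    Level 1 is the base ring; levels advance toward the apex; the apex pole
    is appended as the final landmark.

    Returns an ``(levels*meridians + 1) x 3`` coordinate array.
    """
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    if levels < 2 or meridians < 3:
        raise ValueError("need at least 2 levels and 3 meridians")
    # polar angle from the base plane (theta = pi/2) toward the apex (theta = pi)
    theta = np.pi / 2 + (np.pi / 2) * np.arange(levels) / levels
    phi = 2 * np.pi * np.arange(meridians) / meridians
    st, ct = np.sin(theta), np.cos(theta)
    x = radius * np.outer(st, np.cos(phi))
    y = radius * np.outer(st, np.sin(phi))
    z = length * np.repeat(ct, meridians).reshape(levels, meridians)
    coords = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    apex = np.array([[0.0, 0.0, -length]])
    return np.vstack([coords, apex])


@dataclass
class LVGrid:
    """Two-surface LV landmark cloud: endocardium first, then epicardium."""

    coords: np.ndarray  # (2*(levels*meridians+1)) x 3
    levels: int
    meridians: int

    def __post_init__(self) -> None:
        per = grid_size(self.levels, self.meridians)
        if self.coords.shape != (2 * per, 3):
            raise ValueError(f"expected {2 * per} x 3 coordinates")

    @property
    def per_surface(self) -> int:
        return grid_size(self.levels, self.meridians)

    @property
    def endocardium(self) -> np.ndarray:
        return self.coords[: self.per_surface]

    @property
    def epicardium(self) -> np.ndarray:
        return self.coords[self.per_surface:]

    @property
    def surface_labels(self) -> np.ndarray:
        per = self.per_surface
        return np.asarray(["endocardium"] * per + ["epicardium"] * per, dtype=object)


def build_lv_grid(
    endo_radius: float = 20.0,
    wall_thickness: float = 9.0,
    endo_length: float = 70.0,
    levels: int = DEFAULT_LEVELS,
    meridians: int = DEFAULT_MERIDIANS,
) -> LVGrid:
    """Build the default two-surface grid (2594 landmarks at 36 x 36)."""
    if wall_thickness <= 0:
        raise ValueError("wall thickness must be positive")
    endo = build_surface_grid(endo_radius, endo_length, levels, meridians)
    epi = build_surface_grid(endo_radius + wall_thickness, endo_length + wall_thickness,
                             levels, meridians)
    return LVGrid(coords=np.vstack([endo, epi]), levels=levels, meridians=meridians)


# ---------------------------------------------------------------------------
# AHA 16-segment model
# ---------------------------------------------------------------------------

def assign_aha_segments(levels: int = DEFAULT_LEVELS,
                        meridians: int = DEFAULT_MERIDIANS) -> np.ndarray:
    """AHA 16-segment labels for one surface's landmarks.

    Basal / middle / apical thirds split the levels evenly along the long
    axis; basal and middle rings are divided into six 60-degree sectors,
    apical rings into four 90-degree sectors.  Sector boundaries are
    anchored at meridian 0 (mid-septum by our grid convention).  The apex
    pole is assigned to the apical sector containing meridian 0.

    Returns an object array of length ``levels*meridians + 1``.
    """
    if levels % 3 or meridians % 12:
        raise ValueError("levels must divide by 3 and meridians by 12 for the AHA model")
    third = levels // 3
    labels = np.empty(grid_size(levels, meridians), dtype=object)
    idx = 0
    for lev in range(levels):
        if lev < third:
            ring = BASAL_SEGMENTS
        elif lev < 2 * third:
            ring = MIDDLE_SEGMENTS
        else:
            ring = APICAL_SEGMENTS
        per_sector = meridians // len(ring)
        for mer in range(meridians):
            labels[idx] = ring[mer // per_sector]
            idx += 1
    labels[idx] = APICAL_SEGMENTS[0]  # apex by meridian-0 convention
    return labels


def assign_aha_segments_grid(grid: LVGrid) -> np.ndarray:
    """Segment labels for both surfaces of an :class:`LVGrid`."""
    one = assign_aha_segments(grid.levels, grid.meridians)
    return np.concatenate([one, one])


# ---------------------------------------------------------------------------
# volume and ejection fraction
# ---------------------------------------------------------------------------

def cavity_volume(surface: np.ndarray, levels: int = DEFAULT_LEVELS,
                  meridians: int = DEFAULT_MERIDIANS) -> float:
    """Enclosed volume (ml) of a single-surface grid.

    The surface is closed with a planar polygon fan over the basal ring and
    the signed volume computed by the divergence theorem over the
    triangulated grid (quad strips between levels, apex fan, basal cap).
    Positive for the standard outward orientation; coordinates in mm.
    """
    per = grid_size(levels, meridians)
    pts = np.asarray(surface, dtype=float)
    if pts.shape != (per, 3):
        raise ValueError(f"expected {per} x 3 surface coordinates")
    rings = pts[:-1].reshape(levels, meridians, 3)
    apex = pts[-1]

    total = 0.0
    # strips between consecutive rings, oriented outward (base ring first)
    for lev in range(levels - 1):
        r0, r1 = rings[lev], rings[lev + 1]
        r0n, r1n = np.roll(r0, -1, axis=0), np.roll(r1, -1, axis=0)
        # two triangles per quad: (r0n, r0, r1n) and (r1n, r0, r1)
        t1 = np.einsum("ij,ij->i", np.cross(r0n, r0), r1n)
        t2 = np.einsum("ij,ij->i", np.cross(r1n, r0), r1)
        total += (t1.sum() + t2.sum()) / 6.0
    # apex fan from the last ring
    last = rings[-1]
    lastn = np.roll(last, -1, axis=0)
    total += np.einsum("ij,ij->i", np.cross(lastn, last),
                       np.broadcast_to(apex, last.shape)).sum() / 6.0
    # planar basal cap over the base-ring centroid (opposite orientation)
    base = rings[0]
    basen = np.roll(base, -1, axis=0)
    centroid = base.mean(axis=0)
    total += np.einsum("ij,ij->i", np.cross(base, basen),
                       np.broadcast_to(centroid, base.shape)).sum() / 6.0

    volume_mm3 = total
    if volume_mm3 < 0:
        warnings.warn("negative signed volume: surface orientation appears inverted")
    return volume_mm3 / 1000.0  # mm^3 -> ml


def ejection_fraction(edv: float, esv: float, as_integer: bool = False) -> float:
    """Ejection fraction 100 * (EDV - ESV) / EDV, in percent.

    ``as_integer`` rounds to the nearest whole percent for reporting.
    """
    if edv <= 0:
        raise ValueError("EDV must be positive")
    if not 0 <= esv <= edv:
        raise ValueError("need 0 <= ESV <= EDV")
    ef = min(100.0, max(0.0, 100.0 * (edv - esv) / edv))  # round-off guard
    return float(round(ef)) if as_integer else ef


# ---------------------------------------------------------------------------
# rotation, twist, torsion
# ---------------------------------------------------------------------------

@dataclass
class Kinematics:
    """Per-level rotation about the long axis, plus twist and torsion."""

    level_rotation_deg: np.ndarray  # (levels,)
    twist_deg: float  # apical-level minus basal-level rotation
    torsion_deg_per_mm: float  # twist / long-axis length
    global_rotation_deg: float  # mean over levels
    long_axis_length_mm: float


def _long_axis_frame(surface: np.ndarray, levels: int, meridians: int):
    """Orthonormal frame (e1, e2, axis) with the axis from base centroid to apex."""
    rings = surface[:-1].reshape(levels, meridians, 3)
    base_c = rings[0].mean(axis=0)
    apex = surface[-1]
    axis = apex - base_c
    length = np.linalg.norm(axis)
    if length <= 0:
        raise ValueError("degenerate long axis")
    axis = axis / length
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return base_c, axis, e1, e2, float(length)


def rotation_twist_torsion(
    frame: np.ndarray,
    reference: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    meridians: int = DEFAULT_MERIDIANS,
) -> Kinematics:
    """Angular displacement of each circumferential level relative to a reference frame.

    For every level the rotation is the circular mean of per-landmark
    angular displacements about the reference long axis (base-ring centroid
    to apex), in the plane normal to that axis.  Twist is the apical-level
    minus the basal-level rotation; torsion is twist divided by the
    reference long-axis length.  Counterclockwise viewed from the apex is
    positive.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    per = grid_size(levels, meridians)
    if frame.shape != (per, 3) or reference.shape != (per, 3):
        raise ValueError("frame and reference must share the single-surface grid topology")

    base_c, axis, e1, e2, length = _long_axis_frame(reference, levels, meridians)

    # right-hand-positive angle about the base->apex axis: with e1 x e2 = axis,
    # positive rotation appears counterclockwise viewed from the apex tip.
    def angles(pts: np.ndarray) -> np.ndarray:
        rel = pts - base_c
        return np.arctan2(rel @ e2, rel @ e1)

    ang_f = angles(frame[:-1]).reshape(levels, meridians)
    ang_r = angles(reference[:-1]).reshape(levels, meridians)
    delta = ang_f - ang_r
    # circular mean per level
    rot = np.arctan2(np.sin(delta).mean(axis=1), np.cos(delta).mean(axis=1))
    rot_deg = np.degrees(rot)
    twist = float(rot_deg[-1] - rot_deg[0])
    return Kinematics(
        level_rotation_deg=rot_deg,
        twist_deg=twist,
        torsion_deg_per_mm=twist / length,
        global_rotation_deg=float(np.mean(rot_deg)),
        long_axis_length_mm=length,
    )
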