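"""Homologous-time interpolation and trajectory attributes.

A subject's motion trajectory lives in the PC space of the (shifted)
Procrustes coordinates: each acquired frame contributes one point whose
coordinates are the first three PC scores.  Because subjects differ in
heart rate and frame count, trajectories are resampled at nine
electromechanically homologous times — six events (R peak, end of T wave,
end-systolic volume, mitral-valve opening, end of rapid filling / onset of
diastasis, Q min) plus three midpoints (between events 1-2, 4-5, 5-6) —
via per-subject cubic splines in time.

The nine interpolated points are treated as landmarks of the trajectory
itself, which therefore has a *shape* (after a GPA in which only the six
event points drive the fitted transforms; the three midpoints ride along
passively), a *size* (path length before alignment), and an *orientation*
(the PC1-PC2 angle of the vector from the R-peak point to the
end-systolic-volume point, also before alignment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

from .shape_core import optimal_rotation, pca as _pca, TangentPCA

#: active/passive pattern of the 9-point homologous grid:
#: indices 0,2,3,4,6,8 are the six events; 1,5,7 are passive midpoints.
ACTIVE_MASK = np.array([True, False, True, True, True, False, True, False, True])

EVENT_NAMES = ("r_peak", "t_wave_end", "es_volume", "mv_opening",
               "rapid_filling_end", "q_min")


@dataclass
class EventTimes:
    """Six electromechanical event times (ms) within one acquisition window."""

    r_peak: float
    t_wave_end: float
    es_volume: float
    mv_opening: float
    rapid_filling_end: float
    q_min: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in EVENT_NAMES], dtype=float)

    def __post_init__(self) -> None:
        t = self.as_array()
        if not np.all(np.isfinite(t)):
            raise ValueError("event times must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing")


@dataclass
class HomologousTrajectory:
    """Nine interpolated PC points at homologous times for one subject."""

    subject_id: str
    times: np.ndarray  # (9,)
    points: np.ndarray  # 9 x d (d = 3 by default)
    active_mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.active_mask is None:
            self.active_mask = ACTIVE_MASK.copy()
        self.active_mask = np.asarray(self.active_mask, dtype=bool)
        if self.times.shape != (9,) or self.points.shape[0] != 9:
            raise ValueError("a homologous trajectory has exactly 9 points")
        if self.active_mask.sum() != 6:
            raise ValueError("exactly six active (event) points expected")


@dataclass
class TrajectoryAttributes:
    """Shape (aligned points), size (path length) and PC1-PC2 orientation."""

    subject_id: str
    size: float
    orientation_deg: float


def homologous_time_grid(events: EventTimes) -> np.ndarray:
    """The 9-point homologous time grid for one subject.

    Returns ``{t1, t12, t2, t3, t4, t45, t5, t56, t6}`` where ``t_hk`` is
    the midpoint ``(t_h + t_k) / 2``; strictly increasing by construction.
    """
    t = events.as_array()
    grid = np.array([
        t[0], 0.5 * (t[0] + t[1]), t[1], t[2], t[3],
        0.5 * (t[3] + t[4]), t[4], 0.5 * (t[4] + t[5]), t[5],
    ])
    return grid


def interpolate_pc_scores(times_ms: np.ndarray, scores: np.ndarray,
                          targets: np.ndarray) -> np.ndarray:
    """Cubic-spline interpolation of per-subject PC score curves at target times.

    One not-a-knot cubic spline per PC column through all acquisition
    knots; exact at knots.  Targets must fall inside the acquisition
    window.  With fewer than four frames the interpolation degrades to the
    highest order the data support, with a warning.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != len(times_ms):
        raise ValueError("scores rows must match acquisition times")
    targets = np.asarray(targets, dtype=float)
    if targets.min() < times_ms[0] - 1e-9 or targets.max() > times_ms[-1] + 1e-9:
        raise ValueError(
            f"targets [{targets.min():.1f}, {targets.max():.1f}] ms outside the "
            f"acquisition window [{times_ms[0]:.1f}, {times_ms[-1]:.1f}] ms"
        )
    n = len(times_ms)
    if n >= 4:
        spline = CubicSpline(times_ms, scores, axis=0, bc_type="not-a-knot")
        return spline(targets)
    warnings.warn(f"only {n} frames: falling back to order-{n - 1} interpolation")
    kind = {2: "linear", 3: "quadratic"}[n]
    return interp1d(times_ms, scores, kind=kind, axis=0)(targets)


def trajectory_size(points: np.ndarray) -> float:
    """Path length: sum of Euclidean distances between consecutive PC points.

    Computed on the non-aligned trajectory (before any trajectory GPA).
    """
    pts = np.asarray(points, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def trajectory_orientation(points: np.ndarray) -> float:
    """PC1-PC2 angle (degrees, CCW positive, in (-180, 180]) of the 1 -> 4 vector.

    The vector runs from the first homologous point (R peak) to the fourth
    (end-systolic volume), in the fixed non-aligned PC1-PC2 frame.
    """
    pts = np.asarray(points, dtype=float)
    d = pts[3, :2] - pts[0, :2]
    if np.linalg.norm(d) == 0:
        raise ValueError("points 1 and 4 coincide: orientation undefined")
    ang = float(np.degrees(np.arctan2(d[1], d[0])))
    return 180.0 if ang == -180.0 else ang


@dataclass
class TrajectoryGPAResult:
    """Aligned trajectory shapes and their PCA."""

    aligned: np.ndarray  # n x 9 x d
    consensus: np.ndarray  # 9 x d
    pca: TangentPCA
    subject_ids: list[str]


def _fit_to_consensus(traj: np.ndarray, consensus_active: np.ndarray,
                      active: np.ndarray) -> np.ndarray:
    """Center/scale/rotate a trajectory using only its active points."""
    act = traj[active]
    centroid = act.mean(axis=0)
    centered = traj - centroid
    size = np.linalg.norm(centered[active])
    if size <= 0:
        raise ValueError("degenerate trajectory (active points coincide)")
    scaled = centered / size
    rot = optimal_rotation(scaled[active], consensus_active)
    return scaled @ rot


def trajectory_gpa(trajs: list[HomologousTrajectory] | np.ndarray,
                   n_components: int = 10,
                   tol: float = 1e-10, max_iter: int = 100) -> TrajectoryGPAResult:
    """GPA of 9-point trajectory shapes with passive midpoints.

    Translation, scale, and rotation are estimated from the six active
    (event) points only and then applied to all nine points, so the
    passively appended midpoints never influence the fitted transforms.
    A PCA of the aligned trajectory shapes follows (first ``n_components``
    scores retained for the linear models).
    """
    if isinstance(trajs, np.ndarray):
        pts = np.asarray(trajs, dtype=float)
        ids = [str(i) for i in range(pts.shape[0])]
        active = ACTIVE_MASK.copy()
    else:
        if len(trajs) < 3:
            raise ValueError("need at least three trajectories")
        masks = {tuple(t.active_mask.tolist()) for t in trajs}
        if len(masks) != 1:
            raise ValueError("inconsistent active masks across trajectories")
        pts = np.stack([t.points for t in trajs]).astype(float)
        ids = [t.subject_id for t in trajs]
        active = trajs[0].active_mask
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least three trajectories")

    aligned = np.empty_like(pts)
    # initial consensus: first trajectory reduced by its own active frame
    first = pts[0]
    cons = (first - first[active].mean(axis=0))
    cons = cons / np.linalg.norm(cons[active])
    consensus = cons
    for _ in range(max_iter):
        cons_active = consensus[active]
        for i in range(n):
            aligned[i] = _fit_to_consensus(pts[i], cons_active, active)
        new_consensus = aligned.mean(axis=0)
        new_consensus = new_consensus - new_consensus[active].mean(axis=0)
        new_consensus = new_consensus / np.linalg.norm(new_consensus[active])
        resid = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        if resid < tol:
            break

    flat = aligned.reshape(n, -1)
    tpca = _pca(flat, n_components=min(n_components, n - 1))
    return TrajectoryGPAResult(aligned=aligned, consensus=consensus,
                               pca=tpca, subject_ids=ids)


def trajectory_attributes(traj: HomologousTrajectory) -> TrajectoryAttributes:
    """Size and orientation of one (non-aligned) homologous trajectory."""
    return TrajectoryAttributes(
        subject_id=traj.subject_id,
        size=trajectory_size(traj.points),
        orientation_deg=trajectory_orientation(traj.points),
    )
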