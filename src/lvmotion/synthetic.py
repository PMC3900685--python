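"""Synthetic left-ventricular cycle cohorts with known ground truth.

The generator emulates the characteristics of 3D speckle-tracking
acquisitions of the LV: two-surface landmark clouds (36 circles x 36
points + apex per surface), ~50 ms frame sampling over one cardiac cycle,
heart rates of 59-110 beats/min and healthy ejection fractions of 53-68%,
with volumetric contraction, level-graded twist about the long axis,
optional shear, and isotropic landmark noise below the ~2.5 mm spatial
resolution of the modality.  Inter-individual base-shape variation spans
elongation, wall massiveness and long-axis bending — the kinds of
differences that dominate the static (R-peak) shape PCA of real cohorts.

A pathological *volumetric-overload* mode mimics aortic insufficiency:
inflated volumes and a delayed untwisting that compresses the shape change
between end-systole and mitral-valve opening, which is the trajectory-shape
signature separating such patients from healthy subjects.

The volume curve is a smooth monotone piecewise interpolant parameterized
directly by the six electromechanical event times, so ground-truth events
are exact by construction (end-systolic volume at its minimum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .lv_geometry import build_surface_grid, cavity_volume, grid_size
from .shape_core import LandmarkConfiguration, ShapeSequence
from .trajectory import EventTimes


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults follow the enrolment the generator emulates: 17 healthy + 2
    volumetric-overload subjects, heart rates 59-110 b/min, healthy
    ejection fractions 53-68%, ~50 ms frames, 0.5 mm landmark noise.
    """

    n_healthy: int = 17
    n_pathological: int = 2
    heart_rate_bpm: tuple[float, float] = (59.0, 110.0)
    ejection_fraction_pct: tuple[float, float] = (53.0, 68.0)
    edv_ml: tuple[float, float] = (48.0, 126.0)
    overload_edv_ml: tuple[float, float] = (138.0, 200.0)
    overload_ef_pct: tuple[float, float] = (28.0, 59.0)
    elongation_mean: float = 1.8  # long-axis / radius ratio
    elongation_sd: float = 0.15
    wall_thickness_mean_mm: float = 9.0
    wall_thickness_sd_mm: float = 1.2
    bending_sd_per_mm: float = 3e-4  # long-axis bowing coefficient
    twist_amplitude_deg: tuple[float, float] = (8.0, 18.0)
    shear_amplitude: float = 0.02
    noise_sd_mm: float = 0.5
    frame_interval_ms: float = 50.0
    levels: int = 36
    meridians: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("heart_rate_bpm", "ejection_fraction_pct", "edv_ml",
                     "overload_edv_ml", "overload_ef_pct", "twist_amplitude_deg"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive ordered range")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame interval must be positive")


@dataclass
class GroundTruth:
    """Per-subject generating parameters (exact by construction)."""

    subject_id: str
    pathological: bool
    heart_rate_bpm: float
    edv_ml: float
    esv_ml: float
    ef_pct: float
    twist_amplitude_deg: float
    events: EventTimes
    cycle_ms: float
    elongation: float
    wall_thickness_mm: float
    bending_per_mm: float
    shear_amplitude: float


@dataclass
class SyntheticSubject:
    sequence: ShapeSequence
    events: EventTimes
    truth: GroundTruth


@dataclass
class SyntheticCohort:
    """A full cohort: sequences, events, status labels and ground truth."""

    subjects: list[SyntheticSubject]
    spec: CohortSpec

    @property
    def sequences(self) -> list[ShapeSequence]:
        return [s.sequence for s in self.subjects]

    @property
    def events(self) -> dict[str, EventTimes]:
        return {s.sequence.subject_id: s.events for s in self.subjects}

    @property
    def truths(self) -> dict[str, GroundTruth]:
        return {s.sequence.subject_id: s.truth for s in self.subjects}

    def frames_matrix(self) -> np.ndarray:
        """All frames stacked row-wise, flattened x1,y1,z1,... (deposited layout)."""
        rows = [f.coords.ravel() for s in self.sequences for f in s.frames]
        return np.vstack(rows)

    def frame_subject_labels(self) -> np.ndarray:
        return np.concatenate([
            np.repeat(s.subject_id, s.n_frames) for s in self.sequences
        ])


def _event_times(cycle_ms: float, t_last: float) -> EventTimes:
    """Physiologic event fractions of the cycle, clamped to the acquisition window."""
    t3 = 0.38 * cycle_ms            # end-systolic volume
    t2 = 0.30 * cycle_ms            # end of T wave
    t4 = t3 + 0.06 * cycle_ms       # mitral-valve opening
    t5 = 0.62 * cycle_ms            # end of rapid filling / diastasis onset
    t6 = min(0.93 * cycle_ms, t_last)  # Q min
    if t6 <= t5:
        t5 = 0.5 * (t4 + t6)
    return EventTimes(0.0, t2, t3, t4, t5, t6)


def _volume_curve(events: EventTimes, edv: float, esv: float, cycle_ms: float,
                  pathological: bool) -> PchipInterpolator:
    """Monotone-piecewise cycle volume (ml): ejection, filling, diastasis, atrial kick."""
    sv = edv - esv
    t = events
    v4 = esv + (0.002 if pathological else 0.01) * sv
    knots = np.array([0.0, t.t_wave_end, t.es_volume, t.mv_opening,
                      t.rapid_filling_end, t.q_min, cycle_ms])
    vals = np.array([edv, esv + 0.25 * sv, esv, v4,
                     esv + 0.85 * sv, esv + 0.92 * sv, edv])
    # drop a duplicate knot if q_min was clamped onto the cycle end
    keep = np.concatenate([[True], np.diff(knots) > 1e-9])
    return PchipInterpolator(knots[keep], vals[keep])


def _twist_course(events: EventTimes, cycle_ms: float,
                  pathological: bool) -> PchipInterpolator:
    """Normalized twist time course: peaks at end-systole, releases in diastole.

    Healthy subjects untwist rapidly during isovolumic relaxation (most of
    the release between end-systole and mitral-valve opening); overload
    subjects hold peak twist until after mitral-valve opening, which
    compresses the trajectory's shape change between those two events.
    """
    t = events
    after_mvo = 0.97 if pathological else 0.45
    late = 0.30 if pathological else 0.05
    knots = np.array([0.0, 0.5 * t.es_volume, t.es_volume, t.mv_opening,
                      t.rapid_filling_end, t.q_min, cycle_ms])
    vals = np.array([0.0, 0.6, 1.0, after_mvo, late, 0.0, 0.0])
    keep = np.concatenate([[True], np.diff(knots) > 1e-9])
    return PchipInterpolator(knots[keep], vals[keep])


def _solve_radial_scale(v_ratio: float, axial_coupling: float = 0.35) -> float:
    """Radial scale ``lam`` with coupled axial shortening matching a volume ratio.

    Volume scales as ``lam^2 * lam_z`` with ``lam_z = 1 - axial_coupling *
    (1 - lam)``: contraction is mostly radial with milder long-axis
    shortening, as in the real ventricle.
    """
    f = lambda lam: lam * lam * (1 - axial_coupling * (1 - lam)) - v_ratio
    return brentq(f, 0.2, 1.5, xtol=1e-12)


def _deform_surface(base: np.ndarray, lam: float, axial: float,
                    twist_rad_per_level: np.ndarray, shear: float,
                    levels: int, meridians: int) -> np.ndarray:
    """Apply contraction, per-level twist about z, and shear to a base surface."""
    out = base.copy()
    out[:, 0] *= lam
    out[:, 1] *= lam
    out[:, 2] = base[:, 2] * axial
    # per-landmark twist angle (apex uses the last level's angle)
    per_lm = np.repeat(twist_rad_per_level, meridians)
    ang = np.concatenate([per_lm, [twist_rad_per_level[-1]]])
    c, s = np.cos(ang), np.sin(ang)
    x, y = out[:, 0].copy(), out[:, 1].copy()
    out[:, 0] = c * x - s * y
    out[:, 1] = s * x + c * y
    out[:, 0] += shear * out[:, 2]
    return out


def generate_subject(spec: CohortSpec, subject_seed: int, subject_id: str = "S01",
                     pathological: bool = False) -> SyntheticSubject:
    """Generate one subject's full-cycle sequence, events, and ground truth."""
    rng = np.random.default_rng(subject_seed)
    levels, meridians = spec.levels, spec.meridians

    hr = rng.uniform(*spec.heart_rate_bpm)
    cycle = 60000.0 / hr
    n_frames = int(cycle // spec.frame_interval_ms)
    if n_frames < 6:
        raise ValueError("spec yields fewer than 6 frames per cycle")
    times = np.arange(n_frames) * spec.frame_interval_ms

    if pathological:
        edv = rng.uniform(*spec.overload_edv_ml)
        ef = rng.uniform(*spec.overload_ef_pct)
    else:
        edv = rng.uniform(*spec.edv_ml)
        ef = rng.uniform(*spec.ejection_fraction_pct)
    esv = edv * (1 - ef / 100.0)

    events = _event_times(cycle, times[-1])
    vol = _volume_curve(events, edv, esv, cycle, pathological)
    twist_course = _twist_course(events, cycle, pathological)
    twist_amp = rng.uniform(*spec.twist_amplitude_deg)

    elong = max(1.2, rng.normal(spec.elongation_mean, spec.elongation_sd))
    wall = max(4.0, rng.normal(spec.wall_thickness_mean_mm, spec.wall_thickness_sd_mm))
    bend = rng.normal(0.0, spec.bending_sd_per_mm)

    endo_r = 20.0
    endo = build_surface_grid(endo_r, endo_r * elong, levels, meridians)
    epi = build_surface_grid(endo_r + wall, endo_r * elong + wall, levels, meridians)
    for surf in (endo, epi):
        surf[:, 0] += bend * surf[:, 2] ** 2
    # rescale isotropically so the end-diastolic cavity volume equals EDV
    v_raw = cavity_volume(endo, levels, meridians)
    s = (edv / v_raw) ** (1.0 / 3.0)
    endo *= s
    epi *= s
    v_epi0 = cavity_volume(epi, levels, meridians)
    v_wall = v_epi0 - edv

    # per-level twist profile: clockwise base, counterclockwise apex; the
    # base-to-apex difference equals the twist amplitude exactly
    g = -0.3 + np.arange(levels) / (levels - 1)

    frames = []
    labels = np.asarray(["endocardium"] * grid_size(levels, meridians)
                        + ["epicardium"] * grid_size(levels, meridians), dtype=object)
    for t in times:
        v_t = float(vol(t % cycle))
        w_t = float(twist_course(t % cycle))
        lam_endo = _solve_radial_scale(v_t / edv)
        lam_epi = _solve_radial_scale((v_t + v_wall) / v_epi0)
        # twist angles follow the right-hand convention about the base->apex
        # axis (-z for this grid), so the azimuthal angle is negated
        ang = -np.deg2rad(twist_amp) * g * w_t
        shear = spec.shear_amplitude * w_t
        d_endo = _deform_surface(endo, lam_endo, 1 - 0.35 * (1 - lam_endo),
                                 ang, shear, levels, meridians)
        d_epi = _deform_surface(epi, lam_epi, 1 - 0.35 * (1 - lam_epi),
                                ang, shear, levels, meridians)
        coords = np.vstack([d_endo, d_epi])
        if spec.noise_sd_mm > 0:
            coords = coords + rng.normal(0.0, spec.noise_sd_mm, coords.shape)
        frames.append(LandmarkConfiguration(coords=coords, surface_labels=labels))

    seq = ShapeSequence(subject_id=subject_id,
                        status="pathological" if pathological else "healthy",
                        frames=frames, times_ms=times)
    truth = GroundTruth(
        subject_id=subject_id, pathological=pathological, heart_rate_bpm=hr,
        edv_ml=edv, esv_ml=esv, ef_pct=ef, twist_amplitude_deg=twist_amp,
        events=events, cycle_ms=cycle, elongation=elong, wall_thickness_mm=wall,
        bending_per_mm=bend, shear_amplitude=spec.shear_amplitude,
    )
    return SyntheticSubject(sequence=seq, events=events, truth=truth)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a reproducible cohort (healthy subjects first, then overload)."""
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             ss.spawn(spec.n_healthy + spec.n_pathological)]
    subjects = []
    for i in range(spec.n_healthy):
        subjects.append(generate_subject(spec, seeds[i], f"H{i + 1:02d}", False))
    for j in range(spec.n_pathological):
        subjects.append(generate_subject(spec, seeds[spec.n_healthy + j],
                                         f"P{j + 1:02d}", True))
    return SyntheticCohort(subjects=subjects, spec=spec)
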