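"""End-to-end orchestration of the Procrustes motion analysis.

Two entry points reproduce the analysis sequence:

``run_static_analysis``
    Inter-individual variability: GPA + tangent PCA on every subject's
    first frame (the R-peak, electrophysiologically homologous across
    subjects), retaining the first ten PC scores, with an optional robust
    outlier test on PC1-PC2.

``run_trajectory_pipeline``
    The full motion analysis: common GPA of all frames, the
    Euclidean-eligibility diagnostic, the linear shift, tangent PCA of the
    shifted data, per-subject cubic-spline interpolation of the first
    three PC scores at the nine homologous times, trajectory attributes
    (size, orientation) and trajectory GPA/PCA, followed by the
    inferential battery (attribute-vs-variability permutation models,
    part-whole RV of endo-/epicardium vs the global configuration,
    occupation contrast, robust outliers).

Every report embeds the configuration and seed for provenance, and reruns
with identical inputs are deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import shape_core, stats, trajectory, transport
from .shape_core import ShapeSequence
from .trajectory import EventTimes

log = logging.getLogger("lvmotion")


@dataclass
class AnalysisConfig:
    """Knobs of the analysis, validated up front and echoed in every report."""

    n_components: int = 10
    trajectory_components: int = 3  # PC axes sampling each trajectory's shape
    n_permutations: int = 999
    seed: int = 0
    eligibility_band: tuple[float, float] = (0.98, 1.02)
    eligibility_mode: str = "pairwise"
    outlier_quantile: float = 0.975
    mcd_support_fraction: float = 0.75
    part_whole_rv: bool = True

    def __post_init__(self) -> None:
        if self.n_components < 1 or self.trajectory_components < 1:
            raise ValueError("component counts must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        lo, hi = self.eligibility_band
        if not lo < 1 < hi:
            raise ValueError("eligibility band must bracket 1")
        if not 0.5 <= self.mcd_support_fraction <= 1.0:
            raise ValueError("MCD support fraction must be in [0.5, 1]")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if "eligibility_band" in data:
            data["eligibility_band"] = tuple(data["eligibility_band"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eligibility_band"] = list(d["eligibility_band"])
        return d


def _first_frames(sequences: list[ShapeSequence]):
    return [s.frames[0].coords for s in sequences]


def run_static_analysis(sequences: list[ShapeSequence],
                        config: AnalysisConfig | None = None,
                        outlier_test: bool = True) -> dict:
    """Inter-individual variability at the R peak (first frames).

    GPA + tangent PCA of every subject's first frame; the retained PC
    scores are the inter-individual variability table used as predictors
    in the trajectory linear models.
    """
    config = config or AnalysisConfig()
    t0 = time.perf_counter()
    ids = [s.subject_id for s in sequences]
    emb = shape_core.gpa(_first_frames(sequences), labels=ids)
    tang = shape_core.tangent_project(emb)
    tpca = shape_core.pca(tang, n_components=config.n_components)
    scores = pd.DataFrame(
        tpca.scores, index=ids,
        columns=[f"PC{i + 1}" for i in range(tpca.n_components)])
    report = {
        "config": config.to_dict(),
        "subject_ids": ids,
        "status": {s.subject_id: s.status for s in sequences},
        "scores": scores,
        "variance_explained": tpca.variance_explained.tolist(),
        "embedding": emb,
        "pca": tpca,
    }
    if outlier_test and len(ids) >= 10 and tpca.n_components >= 2:
        out = stats.robust_mahalanobis_outliers(
            tpca.scores[:, :2], quantile=config.outlier_quantile,
            support_fraction=config.mcd_support_fraction, seed=config.seed)
        report["outliers"] = {
            "flagged": [ids[i] for i in np.flatnonzero(out.flags)],
            "squared_distances": dict(zip(ids, out.squared_distances.tolist())),
            "threshold": out.threshold,
        }
    log.info("static analysis: %d subjects in %.2fs", len(ids), time.perf_counter() - t0)
    return report


def _shifted_pc_scores(sequences, config):
    """Common GPA -> eligibility -> linear shift -> tangent PCA of shifted frames."""
    all_frames = [f.coords for s in sequences for f in s.frames]
    labels = np.concatenate([np.repeat(s.subject_id, s.n_frames) for s in sequences])
    emb = shape_core.gpa(all_frames, labels=labels)
    diag = shape_core.eligibility_diagnostic(emb, mode=config.eligibility_mode,
                                             distance="chordal")
    shift = transport.linear_shift(emb, labels, eligibility_band=config.eligibility_band)
    tang = shape_core.tangent_project(shift.embedding)
    tpca = shape_core.pca(tang, n_components=config.n_components)
    return emb, diag, shift, tpca, labels


def _subject_trajectories(sequences, events, tpca_scores, labels, config):
    trajs = []
    d = config.trajectory_components
    for s in sequences:
        ev = events[s.subject_id]
        targets = trajectory.homologous_time_grid(ev)
        scores = tpca_scores[labels == s.subject_id][:, :d]
        pts = trajectory.interpolate_pc_scores(s.times_ms, scores, targets)
        trajs.append(trajectory.HomologousTrajectory(
            subject_id=s.subject_id, times=targets, points=pts))
    return trajs


def _part_whole_rv(sequences, config, n_frames_total):
    """RV of the global shifted PC scores vs endo- and epicardium processed alone."""
    first = sequences[0].frames[0]
    if first.surface_labels is None:
        return None
    out = {}
    global_scores = None
    for part in ("global", "endocardium", "epicardium"):
        if part == "global":
            seqs = sequences
        else:
            mask = first.surface_labels == part
            if not mask.any():
                return None
            seqs = [
                ShapeSequence(
                    subject_id=s.subject_id, status=s.status,
                    frames=[shape_core.LandmarkConfiguration(coords=f.coords[mask])
                            for f in s.frames],
                    times_ms=s.times_ms)
                for s in sequences
            ]
        _, _, _, tpca, _ = _shifted_pc_scores(seqs, config)
        if part == "global":
            global_scores = tpca.scores
        else:
            res = stats.rv_permutation_test(global_scores, tpca.scores,
                                            n_perm=config.n_permutations,
                                            seed=config.seed)
            out[part] = {"rv": res.rv, "p_value": res.p_value}
    return out


def run_trajectory_pipeline(sequences: list[ShapeSequence],
                            events: dict[str, EventTimes],
                            config: AnalysisConfig | None = None) -> dict:
    """Full motion-trajectory analysis of a cohort.

    Linear models (attributes vs inter-individual variability) follow the
    healthy-subjects-only convention; outlier tests run on the full cohort
    so pathological subjects can be screened against the healthy cloud.
    """
    config = config or AnalysisConfig()
    stage = "common GPA / linear shift"
    report: dict = {"config": config.to_dict(), "stage_seconds": {}}
    try:
        t0 = time.perf_counter()
        emb, diag, shift, tpca, labels = _shifted_pc_scores(sequences, config)
        report["stage_seconds"][stage] = time.perf_counter() - t0
        report["eligibility"] = {
            "slope": diag.slope,
            "uncentered_correlation": diag.uncentered_correlation,
            "root_ms_error": diag.root_ms_error,
            "mode": diag.mode,
            "within_band": diag.within_band(config.eligibility_band),
        }
        report["shift_warnings"] = shift.warnings
        report["variance_explained"] = tpca.variance_explained.tolist()

        stage = "homologous-time interpolation"
        t0 = time.perf_counter()
        trajs = _subject_trajectories(sequences, events, tpca.scores, labels, config)
        report["stage_seconds"][stage] = time.perf_counter() - t0

        stage = "trajectory attributes"
        ids = [s.subject_id for s in sequences]
        status = {s.subject_id: s.status for s in sequences}
        sizes = {t.subject_id: trajectory.trajectory_size(t.points) for t in trajs}
        angles = {t.subject_id: trajectory.trajectory_orientation(t.points)
                  for t in trajs}
        tgpa = trajectory.trajectory_gpa(trajs, n_components=config.n_components)
        attr_table = pd.DataFrame({
            "subject_id": ids,
            "status": [status[i] for i in ids],
            "size": [sizes[i] for i in ids],
            "orientation_deg": [angles[i] for i in ids],
        }).set_index("subject_id")
        tshape = pd.DataFrame(
            tgpa.pca.scores, index=ids,
            columns=[f"trajPC{i + 1}" for i in range(tgpa.pca.n_components)])
        report["attributes"] = attr_table
        report["trajectory_shape_scores"] = tshape
        report["trajectories"] = trajs
        report["trajectory_gpa"] = tgpa

        stage = "inter-individual variability"
        static = run_static_analysis(sequences, config, outlier_test=True)
        report["static"] = static

        stage = "linear models"
        t0 = time.perf_counter()
        healthy = [i for i in ids if status[i] == "healthy"]
        hmask = np.array([status[i] == "healthy" for i in ids])
        inter = static["scores"].loc[healthy].to_numpy()
        models = {}
        if len(healthy) > inter.shape[1] + 1:
            models["trajectory_shape~inter_individual"] = asdict(
                stats.permanova_regression(tshape.loc[healthy].to_numpy(), inter,
                                           n_perm=config.n_permutations,
                                           seed=config.seed))
            models["orientation~inter_individual"] = asdict(
                stats.permanova_regression(
                    attr_table.loc[healthy, ["orientation_deg"]].to_numpy(), inter,
                    n_perm=config.n_permutations, seed=config.seed))
            models["size~inter_individual"] = asdict(
                stats.permanova_regression(
                    attr_table.loc[healthy, ["size"]].to_numpy(), inter,
                    n_perm=config.n_permutations, seed=config.seed))
        report["linear_models"] = models
        report["stage_seconds"][stage] = time.perf_counter() - t0

        stage = "occupation analysis"
        occ = transport.occupation_contrast(emb, shift)
        disp = stats.dispersion_comparison(occ.before, occ.after,
                                           n_perm=config.n_permutations,
                                           seed=config.seed)
        report["occupation"] = {
            "total_variance_before": occ.total_variance_before,
            "total_variance_after": occ.total_variance_after,
            "test": asdict(disp),
        }

        stage = "outlier tests"
        if len(ids) >= 10:
            tout = stats.robust_mahalanobis_outliers(
                tgpa.pca.scores[:, :2], quantile=config.outlier_quantile,
                support_fraction=config.mcd_support_fraction, seed=config.seed)
            report["trajectory_outliers"] = {
                "flagged": [ids[i] for i in np.flatnonzero(tout.flags)],
                "squared_distances": dict(zip(ids, tout.squared_distances.tolist())),
                "threshold": tout.threshold,
            }

        if config.part_whole_rv:
            stage = "part-whole RV"
            t0 = time.perf_counter()
            rv = _part_whole_rv(sequences, config, emb.n)
            if rv is not None:
                report["part_whole_rv"] = rv
            report["stage_seconds"][stage] = time.perf_counter() - t0
    except Exception as exc:  # annotate failures with the stage that raised
        raise RuntimeError(f"trajectory pipeline failed at stage '{stage}': {exc}") from exc
    return report


def save_report(report: dict, outdir) -> Path:
    """Write a pipeline report: JSON for scalars/tests, CSV for tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scalars = {}
    for key, val in report.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(outdir / f"{key}.csv")
        elif isinstance(val, (dict, list, str, int, float, bool)) and key not in (
                "trajectories", "trajectory_gpa", "embedding", "pca", "static"):
            scalars[key] = val
    if "static" in report:
        report["static"]["scores"].to_csv(outdir / "inter_individual_scores.csv")
        scalars["static"] = {
            k: v for k, v in report["static"].items()
            if isinstance(v, (dict, list, str, int, float, bool))
            and k not in ("embedding", "pca")
        }
    path = outdir / "report.json"
    path.write_text(json.dumps(scalars, indent=1, default=float))
    return path
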