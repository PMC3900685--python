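"""Linear-shift approximate parallel transport.

Exact parallel transport (Levi-Civita) in Kendall shape space has no closed
form for 3D shapes, but when per-subject mean shapes are close together the
transport can be approximated by a Euclidean translation in the embedding
space: subtract each subject's own trajectory mean and add the common grand
mean.  This removes inter-individual mean differences while preserving
within-subject shape increments, after which a fresh GPA filters out any
residual rotation.  Validity of the approximation should be checked first
with :func:`lvmotion.shape_core.eligibility_diagnostic`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .shape_core import (
    EligibilityReport,
    ProcrustesEmbedding,
    eligibility_diagnostic,
    gpa,
    tangent_project,
)


@dataclass
class ShiftResult:
    """Outcome of the linear shift.

    ``embedding`` holds the re-aligned shifted frames; ``local_means`` the
    per-subject consensus shapes (unit centroid size) that were removed.
    """

    embedding: ProcrustesEmbedding
    local_means: dict[str, np.ndarray]
    grand_mean: np.ndarray
    subject_labels: np.ndarray
    diagnostic: EligibilityReport | None
    warnings: list[str]


def local_means(emb: ProcrustesEmbedding, labels=None, normalize: bool = True) -> dict:
    """Per-subject mean shapes of an embedding.

    Arithmetic means of the aligned rows, renormalized to unit centroid
    size by default.  A subject with a single frame triggers a warning and
    its mean is that frame.
    """
    lab = np.asarray(labels if labels is not None else emb.labels)
    if lab is None or len(lab) != emb.n:
        raise ValueError("need one label per embedded configuration")
    out: dict = {}
    for s in dict.fromkeys(lab.tolist()):  # preserve first-seen order
        rows = emb.aligned[lab == s]
        if rows.shape[0] == 1:
            warnings.warn(f"subject {s!r} has a single frame; local mean is that frame")
        mean = rows.mean(axis=0)
        if normalize:
            mean = mean / np.linalg.norm(mean)
        out[s] = mean
    return out


def linear_shift(
    emb: ProcrustesEmbedding,
    labels=None,
    eligibility_band: tuple[float, float] = (0.98, 1.02),
    check_eligibility: bool = True,
    re_gpa: bool = True,
) -> ShiftResult:
    """Transport every subject's trajectory to the grand mean.

    Each aligned frame is replaced by ``frame - Sm_i + grand_mean`` where
    ``Sm_i`` is the subject's own trajectory mean, so per-subject means of
    the shifted rows coincide with the grand mean by construction.  The
    shifted set is then re-aligned by a fresh GPA to remove any residual
    rotation.

    Eligibility (diagnostic slope inside ``eligibility_band``) is checked
    and produces a warning — not a failure — when violated, so exploratory
    use on dispersed data stays possible.
    """
    lab = np.asarray(labels if labels is not None else emb.labels)
    if lab is None or len(lab) != emb.n:
        raise ValueError("labels must match embedding rows")

    warns: list[str] = []
    diag = None
    if check_eligibility:
        diag = eligibility_diagnostic(emb, mode="from_consensus", distance="chordal")
        if not diag.within_band(eligibility_band):
            msg = (
                f"eligibility slope {diag.slope:.4f} outside band {eligibility_band}; "
                "linear shift may poorly approximate parallel transport"
            )
            warnings.warn(msg)
            warns.append(msg)

    # arithmetic (non-renormalized) subject means so the shifted per-subject
    # means equal the grand mean exactly
    shifted = emb.aligned.copy()
    subj_means: dict[str, np.ndarray] = {}
    for s in dict.fromkeys(lab.tolist()):
        mask = lab == s
        m = emb.aligned[mask].mean(axis=0)
        subj_means[s] = m
        shifted[mask] += emb.grand_mean - m

    if re_gpa:
        configs = shifted.reshape(emb.n, emb.k, emb.ndim)
        new_emb = gpa(configs, labels=lab)
    else:
        new_emb = ProcrustesEmbedding(
            aligned=shifted,
            grand_mean=emb.grand_mean,
            centroid_sizes=emb.centroid_sizes,
            k=emb.k,
            ndim=emb.ndim,
            labels=lab,
        )

    lm = {s: m / np.linalg.norm(m) for s, m in subj_means.items()}
    return ShiftResult(
        embedding=new_emb,
        local_means=lm,
        grand_mean=emb.grand_mean,
        subject_labels=lab,
        diagnostic=diag,
        warnings=warns,
    )


@dataclass
class OccupationContrast:
    """Per-frame dispersions before and after the shift, ready for testing."""

    before: np.ndarray
    after: np.ndarray

    @property
    def total_variance_before(self) -> float:
        return float(np.sum(self.before**2))

    @property
    def total_variance_after(self) -> float:
        return float(np.sum(self.after**2))


def occupation_contrast(before: ProcrustesEmbedding, after: ShiftResult | ProcrustesEmbedding) -> OccupationContrast:
    """Per-frame tangent distances to the respective consensus, before vs after shift.

    The contrast quantifies morpho-space occupation: the not-shifted cloud
    mixes inter- and intra-individual variation and should be more dispersed
    than the shifted one whenever subjects' mean shapes differ.  Feed the
    two distance vectors to :func:`lvmotion.stats.dispersion_comparison`.
    """
    emb_after = after.embedding if isinstance(after, ShiftResult) else after
    if emb_after.n != before.n:
        raise ValueError("embeddings must contain the same frames")
    d_before = np.linalg.norm(tangent_project(before), axis=1)
    d_after = np.linalg.norm(tangent_project(emb_after), axis=1)
    return OccupationContrast(before=d_before, after=d_after)
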