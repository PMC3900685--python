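"""Remove inter-individual variation with the linear shift and test occupation.

Subtracts each subject's trajectory mean and adds the grand mean (the
approximate parallel transport), re-aligns, and contrasts morpho-space
occupation before vs after: the not-shifted cloud mixes inter- and
intra-individual variation and should be significantly more dispersed.
"""

import lvmotion as lv
from lvmotion.transport import linear_shift, occupation_contrast

cohort = lv.generate_cohort(lv.CohortSpec(levels=12, meridians=12, seed=1))
frames = [f.coords for s in cohort.sequences for f in s.frames]
labels = cohort.frame_subject_labels()

emb = lv.gpa(frames, labels=labels)
shift = linear_shift(emb, labels)

occ = occupation_contrast(emb, shift)
test = lv.dispersion_comparison(occ.before, occ.after, n_perm=999, seed=1)

print(f"total tangent variance before shift: {occ.total_variance_before:.4f}")
print(f"total tangent variance after shift:  {occ.total_variance_after:.4f}")
print(f"dispersion pseudo-F = {test.statistic:.1f}, permutation p = {test.p_value:.3f}")
print("\nThe drop is the inter-individual share of the variation; a small p")
print("confirms the not-shifted occupation is significantly larger.")
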