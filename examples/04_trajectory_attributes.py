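"""Full trajectory pipeline: homologous times, attributes, outlier screening.

Runs the end-to-end motion analysis on a synthetic cohort and prints each
subject's trajectory size (path length in PC space), PC1-PC2 orientation of
the R-peak -> end-systole vector, and the robust Mahalanobis screening on
trajectory-shape PC1-PC2 that separates volumetric-overload subjects.
"""

import lvmotion as lv

cohort = lv.generate_cohort(lv.CohortSpec(levels=12, meridians=12, seed=1))
cfg = lv.AnalysisConfig(n_permutations=999, seed=1,
                        eligibility_mode="from_consensus")
report = lv.run_trajectory_pipeline(cohort.sequences, cohort.events, cfg)

print(report["attributes"].round(2).to_string())

print("\nlinear models (healthy subjects only):")
for name, model in report["linear_models"].items():
    print(f"  {name:<40} adjR2={model['adjusted_r_squared']:5.2f}  "
          f"p={model['p_value']:.3f}")

print("\npart-whole RV vs the global configuration:")
for part, block in report["part_whole_rv"].items():
    print(f"  {part:<12} RV={block['rv']:.3f}  p={block['p_value']:.4f}")

print("\ntrajectory-shape outliers (robust Mahalanobis on PC1-PC2):",
      ", ".join(report["trajectory_outliers"]["flagged"]) or "none")
print("Healthy trajectories cluster; overload subjects separate because their")
print("shape change between end-systole and mitral-valve opening is compressed.")
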