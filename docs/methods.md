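# Methods

This note documents the models, numerical choices, and limitations of
`lvmotion` at the level of detail a user needs to interpret its output.

## Shape model and superimposition

A configuration is a k×m landmark matrix (m = 2 or 3). Its *pre-shape*
removes location (centroid at the origin) and scale (Frobenius norm 1).
GPA (`shape_core.gpa`) iteratively rotates every pre-shape to the evolving
consensus — the renormalized mean of the aligned rows — until the consensus
displacement falls below 1e-10 (at most 100 iterations, after which a
convergence error carrying the last residual is raised). Rows keep unit
centroid size; reflections are excluded throughout, so the optimal-rotation
step corrects the sign of the smallest singular value when the cross-product
determinant is negative. On cohort-like data (a cloud around one base
shape) the iteration converges in a handful of steps; on maximally
dispersed clouds (geodesic spread near the π/2 bound) convergence is slow
and the iteration cap may bind — such data are outside the method's regime
anyway.

Two distances are exposed on pre-shapes after reflection-free optimal
rotation: the geodesic arc ρ = arccos⟨aR, b⟩ ∈ [0, π/2] and the chordal
distance ‖aR − b‖ = 2 sin(ρ/2). Note on naming: we follow the printed bound
(the arc attains π/2 for a planar shape and its mirror image) and call the
arc "Riemannian" and the chord "Euclidean"; in parts of the literature
"full Procrustes distance" instead denotes sin ρ. The code standardizes on
arc/chord to avoid the ambiguity.

Tangent projection at the grand mean removes the component of each aligned
row along the consensus direction (orthogonal projection; the consensus
maps to the origin; idempotent). PCA of tangent coordinates uses the SVD of
the column-centered matrix; each component's sign is fixed so its
largest-magnitude loading is positive (signs are otherwise arbitrary and
deterministic output is needed for regression tests). Ten components are
retained by default; a cumulative-variance threshold (e.g. 95%) is
available as an alternative stopping rule.

## Eligibility diagnostic and linear shift

The linear shift is only a faithful stand-in for parallel transport when
the shape cloud is nearly flat. `eligibility_diagnostic` regresses the
chordal (or projected-tangent) distance on the geodesic distance through
the origin — over all reciprocal pairs or from each shape to the consensus —
and reports slope, uncentered correlation and root-MS error. Since
chord/arc = 1 − ρ²/24 + O(ρ⁴), the slope approaches 1 from below as
dispersion shrinks; the default acceptance band is [0.98, 1.02]. Violation
warns rather than fails, so exploratory use on dispersed data stays
possible.

The shift itself replaces every aligned frame by frame − Sm_i + G. The
subtraction uses the *arithmetic* per-subject mean (not its unit-size
renormalization), so per-subject means of the shifted rows equal the grand
mean exactly by construction; the public `local_means` op returns unit-size
means, which is the conventional reporting form. The shifted set is then
re-aligned by a fresh GPA to scrub residual rotation. The re-GPA
renormalizes rows, which perturbs within-subject increments at second order
in the dispersion: the documented invariants (increment preservation and
idempotence at 1e-6/1e-8) hold in the low-dispersion regime the diagnostic
certifies, and degrade gracefully (to ~1e-4 at geodesic spread 0.23)
outside it.

## Homologous times and trajectory attributes

Nine homologous times per subject: the six electromechanical events plus
arithmetic midpoints between events 1–2, 4–5 and 5–6 ("median point
between" two instants is read as the midpoint — the only consistent reading
for two numbers). The first three PC-score curves are interpolated at these
times by cubic splines with not-a-knot end conditions (the default of the
common spline routine family; periodic conditions were rejected because an
acquisition is not guaranteed to close the cycle). With fewer than four
frames the interpolation degrades to the order the data support, with a
warning. Targets outside the acquisition window raise rather than
extrapolate. The end-systolic time is taken as the machine-marked frame
(±25 ms at 50 ms sampling); no sub-frame refinement is attempted.

Trajectory GPA treats the nine interpolated PC points as landmarks but
estimates translation, scale and rotation from the six event points only,
applying them to all nine; the midpoints are passively transported and
provably never influence the fitted transforms (tested by exact equality
against an active-only fit). Size (path length) and orientation (PC1–PC2
angle of the point-1 → point-4 vector, degrees, CCW positive, in
(−180, 180]) are computed on the *non-aligned* trajectories, in the fixed
PC frame of the shifted-data PCA — alignment is appropriate only for
trajectory *shape*. Attributes are invariant to time-unit changes because
they live in PC space.

## LV grid and descriptors

The grid model is a truncated prolate semi-ellipsoid sampled on 36 levels ×
36 meridians plus the apex pole per surface (1297 landmarks; 2594 for
endo + epi; 7782 flattened coordinates), ordered level-major from the base,
apex last, endocardium before epicardium. The long axis runs from the
base-ring centroid to the apex — an intrinsic, orientation-free choice.

AHA 16-segment labels: levels 1–12/13–24/25–36 form the basal/middle/apical
thirds; basal and middle rings are split into six 60° sectors, apical rings
into four 90° sectors, with boundaries anchored at meridian 0 (mid-septum
by grid convention); the apex joins the apical sector containing meridian 0.

Cavity volume closes the surface with a planar polygon fan over the basal
ring and applies the divergence theorem to the triangulated grid (signed
tetrahedra; positive for outward orientation; ml). At the default
resolution the inscribed-polyhedron bias is ≈0.6% (hemisphere benchmark).
Rotation per level is the circular mean of per-landmark angular
displacements about the long axis, right-hand positive (counterclockwise
viewed from the apex); twist = apical − basal level rotation; torsion =
twist / long-axis length. The machine conventions of commercial 3D-STE
systems are proprietary, so these definitions are self-consistent
stand-ins: correlations with workstation outputs are expected to be
qualitative, not numeric.

## Synthetic cohorts

The generator's defaults encode the study conditions it emulates: 17
healthy + 2 volumetric-overload subjects; heart rate 59–110 b/min; healthy
EF 53–68% with EDV 48–126 ml (overload: EDV 138–200 ml, EF 28–59%); 50 ms
frames over one cycle (cycle = 60000/HR ms); twist amplitude 8–18°;
isotropic landmark noise of 0.5 mm, below the ~2.5 mm spatial resolution of
the modality. Inter-individual base-shape variation spans elongation
(long-axis/radius ratio 1.8 ± 0.15), wall thickness (9 ± 1.2 mm) and
long-axis bending (bowing coefficient sd 3e-4 /mm) — chosen to mimic the
elongated-vs-massive and bent-vs-straight axes that dominate static LV
shape PCAs.

The cavity-volume curve is a monotone piecewise interpolant (PCHIP) through
values anchored at the six event times, so ground-truth events are exact by
construction and the minimum falls at the end-systolic event. Per frame,
the radial contraction λ solves λ²·λ_z = V(t)/EDV with coupled axial
shortening λ_z = 1 − 0.35(1 − λ); the epicardial surface contracts to
conserve wall volume (V_epi = V_cavity + V_wall), producing systolic wall
thickening. Twist is level-graded from −0.3 (base) to +0.7 (apex) of the
amplitude so the base-to-apex difference equals the amplitude exactly, with
a time course peaking at end-systole. The overload mode inflates volumes
and holds peak twist until after mitral-valve opening (delayed untwisting),
compressing the trajectory's shape change between homologous points 4 and 5
— the separating signature in trajectory-shape space.

What the generator does *not* emulate: speckle dropout and image-quality
artifacts, regional wall-motion abnormalities, fiber-architecture
electromechanics, respiratory/probe motion, and real acquisition jitter in
frame timing. Passing tests on synthetic cohorts therefore demonstrate the
*pipeline's* correctness and discriminative mechanics, not clinical
sensitivity/specificity.

## Inference

All permutation tests are seeded and report p = (exceedances + 1) /
(n_perm + 1); 999 permutations by default (configurable). Covariance blocks
use denominator n − 1 (the RV value is denominator-invariant). The
multivariate regression uses the Euclidean pseudo-F from the hat-matrix
projection of the centered response — identical to the redundancy-analysis
F, and to adonis on Euclidean distances, which coincide for responses in a
Euclidean PC space; collinear predictor columns are dropped with a warning.
The dispersion contrast permutes group membership over pooled
distances-to-consensus. Outlier screening fits a minimum-covariance-
determinant estimator (scikit-learn's seeded FAST-MCD, support fraction
0.75) and flags squared robust Mahalanobis distances above the chi-square
0.975 quantile at the score dimensionality. No multiple-testing correction
is applied; flag counts are reported so users can adjust if screening many
axes.

## Study sizes used by the test and acceptance suites

Replicated studies (the 50-cohort overload-detection battery, occupation
contrasts, null calibrations at 500 simulations) run on reduced 12×12+apex
grids per surface — the discrimination machinery is resolution-independent —
while single-pass layout checks and the acquisition-scale eligibility
diagnostic use the full 36×36+apex grids (≈300 frames × 7782 coordinates).
The eligibility diagnostic at that scale yields slope ≈ 0.999 with
uncentered correlation ≈ 1.000, matching what near-flat LV shape clouds
produce.

## Known limitations

- The linear shift is first-order: with geodesic dispersion beyond ~0.3 the
  transported trajectories absorb curvature distortion that the diagnostic
  will flag but the code will not correct (exact Levi-Civita transport for
  3D shapes is out of scope).
- GPA excludes reflections and assumes a consistent landmark ordering; no
  sliding semilandmarks or missing-landmark estimation.
- Twist/torsion conventions are package-defined; compare trends, not values,
  against workstation exports.
- The MCD flag rate is only asymptotically nominal; for n below ~20 the
  chi-square threshold is approximate and flags should be read as screening,
  not testing.
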