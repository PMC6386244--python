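# Methods

This note documents the models, numerical choices and limitations behind
`faceage`. It describes what the code computes; every number quoted as a
measurement is produced by the test suite or by `scripts/acceptance.py`,
not asserted here.

## Problem setting

Longitudinal 3D facial surface scans (triangle meshes in mm, one scan per
subject per year) are compared across ages to (1) describe where and how
fast the face grows between 7 and 17 years, separately per sex, and
(2) predict a subject's facial surface at another age — forward (age
progression) or backward (age regression). Raw scans carry arbitrary,
scan-specific meshings, so every analysis step first requires dense
correspondence: a common vertex indexing in which vertex *v* denotes the
same anatomical location on every scan (a "quasi-landmark").

## Dense correspondence (CPD-DCA)

Per scan, four steps:

1. **Rigid pre-alignment.** Nine anatomical landmarks (exocanthia,
   endocanthia, nasion, pronasale, cheilia, pogonion) give a 9-point
   least-squares rigid fit (Kabsch, proper rotation, no scaling) taking
   the base mesh into the scan's frame. This only accelerates and
   stabilises the next step.
2. **Non-rigid CPD registration.** The base vertices are treated as
   Gaussian-mixture centroids displaced by a smooth field
   `v(y_i) = Σ_j G(y_i, y_j) w_j` with Gaussian kernel width `beta`.
   EM alternates soft assignment of target vertices (with a uniform
   outlier component of prior weight `w`) and a ridge-regularised solve
   `(d(P1)G + λσ²I)W = PX − d(P1)Y`; σ² anneals toward the residual level
   and iteration stops when its relative change drops below `tol`.
   For bases above 5000 vertices the kernel is replaced by its top-K
   eigenpair approximation (K = 100) with a Woodbury solve.
3. **Surface projection.** Registered base vertices are snapped to the
   globally closest point of the target surface, computed exactly by a
   vectorised per-triangle Voronoi-region analysis (ties broken by lowest
   face index). Projection can only decrease the distance to the target
   surface.
4. **Dataset-wide pruning.** A vertex whose projection distance exceeds
   `prune_k` × (median edge length of the target mesh) in *any* scan is
   removed from *all* scans, preserving homology. Default `prune_k` = 3;
   an abort triggers if more than half the vertices would go. The depth to
   which pruning reaches into a surface hole equals the threshold: a
   vertex hovering over a hole sits roughly its in-plane rim distance away
   from the surviving surface, so tight thresholds (k ≈ 1) are needed to
   excise small holes in clean data, while k = 3 is a conservative default
   under noise.

### CPD parameter defaults

`beta = 0.1 ×` bounding-box diagonal (≈ 22 mm for a face), `w = 0.1`,
`tol = 1e-5`, `lam = 10`, `max_iter = 150`. The stiffness is set higher
than the value customary for generic point-cloud registration (λ ≈ 2)
because template-to-scan correspondence across *re-meshed* surfaces is
dominated by tangential drift: as σ² anneals, soft assignment approaches
per-vertex matching and inherits the target's sampling irregularity. On
synthetic re-meshed pairs with known homology, λ = 2 leaves ≈ 0.6 mm RMS
tangential error while λ = 10 roughly halves it, and (because the ridge
term λσ²I vanishes as σ² anneals) recovery of genuine smooth deformations
is unaffected — the acceptance suite measures a 2 mm bump recovered to
well under 0.01 mm RMS at these defaults. All parameters are
config-exposed and logged; none is claimed to be the value used by any
particular historical study.

## Superimposition and form space

Generalized Procrustes analysis translates every configuration to
centroid origin and iteratively rotates it onto the evolving consensus
(arithmetic mean, initialised from the first sample; convergence at
1e-7 mm RMS consensus change). **No scaling step is applied**: growth is
largely size change, so the analysis operates on *form* (size + shape).
A `shape_mode` flag restores the classical unit-centroid-size scaling for
exploration.

PCA is fitted per sex on all scans of that sex (both cohorts pooled), in
snapshot space: the thin SVD of the centred n × 3V matrix yields
eigenvalues identical to the dense 3V × 3V covariance spectrum at n ≪ 3V
cost. K retains the smallest number of components reaching
`variance_target` (default 0.95), capped at n − 1. PC signs are
normalised so training scores correlate positively with age (older faces
toward positive PC1), a pure convention that aids interpretation.

## Growth maps

For a transition a → b, each subject scanned at both ages contributes the
per-vertex displacement field points(b) − points(a) in the consensus
frame. Note that GPA absorbs the rigid part of growth, so these motion
vectors are displacements *relative to the superimposed pose*, not
absolute anatomical excursions. Per vertex, a one-sample Hotelling's T²
tests the mean displacement against zero: T² = n·x̄ᵀS⁻¹x̄,
F = (n−p)/(p(n−1))·T² on (p, n−p) df with p = 3. Raw p-values are
thresholded at α = 0.05 per vertex (no multiplicity correction, matching
the per-vertex display convention; Benjamini–Hochberg is available as an
option). Transitions with fewer than 5 complete pairs are skipped
(n − p ≥ 2 df needed). Singular per-vertex covariances (e.g. identical
displacement across subjects) get p = 1 and a diagnostic flag.

Maps export as ascii PLY with per-vertex colours: continuous magnitude
maps use the `viridis` colormap linearly between recorded vmin/vmax
(hence invertible to 1/255 quantisation); significance maps are binary
blue (significant) / grey (not). A CSV carries the raw per-vertex
statistics. A signed variant (displacement projected on consensus vertex
normals) is available; its sign convention (positive = outward along the
consensus normal) is this package's own.

## Ageing trajectories

Individual growth in score space is noisy, so each subject's score path
is reduced to an OLS line per component; a cohort model is the arithmetic
mean of per-subject intercepts and slopes. The two cohorts (ages ≈ 7–12
and 12–17, split at `split_age` = 12 with the age-12 scan shared) yield
two lines that are joined by the unique C¹ cubic Hermite segment between
the cohort *centres* (midpoints of the cohort age ranges, i.e. 9.5 and
14.5 for the default design): endpoint values are the cohort lines
evaluated at the centres, endpoint derivatives the cohort slopes, with
the standard h00/h10/h01/h11 basis on normalised time and derivative
scaling by the knot gap. Outside the knots the trajectory follows the
respective line. Evaluation outside a guard band of [6, 18] years raises
unless extrapolation is explicitly allowed.

## Age transformation and evaluation

A specimen aged from `a` to `b` keeps its individual deviation from the
mean face and translates along the population trajectory:
`s' = s + T(b) − T(a)` in score space, reconstructed as
`mean + basis·s'`. The same formula with `b < a` performs age regression,
and progression followed by regression returns the starting prediction
exactly (additivity).

Evaluation takes each subject's youngest scan, ages it to their oldest
scan's age, and measures per-vertex Euclidean distances to the true
oldest scan (homology makes per-vertex distances meaningful). Reported
scalars average subject-first: each subject's mean over vertices, then
the mean over subjects (the per-vertex group *map* is the vertex-wise
mean of subject error maps). The non-aged baseline reuses the
GPA-aligned youngest face unchanged, and a paired t-test on per-subject
mean errors decides whether ageing systematically beats it. Identity
transformation (b = a) leaves exactly the PCA truncation error, bounded
by the discarded variance.

## BMI covariate analysis

BMI = weight / height² (kg/m²). Percentiles come from an LMS reference:
age-interpolated Box-Cox power L, median M and coefficient of variation
S per sex, z = ((x/M)^L − 1)/(L·S) (log form for L = 0), percentile
= 100·Φ(z). The package ships a **synthetic** LMS reference — smooth,
plausibly-shaped BMI-for-age curves that are *not* any national
standard — and reads user CSV references (`sex,age,L,M,S`) for real
analyses. Per subject, ΔBMI percentile = percentile at last scan −
percentile at first scan; the mean prediction error is regressed on Δ
(simple OLS) and the slope tested by the regression-vs-residual F on
(1, n−2) df. Weight groups <25 / 25–75 / >75 (start percentile) are used
for display; cut points 25/75/90/97 are recorded constants.

## Synthetic data generator

The generator emulates the study design the pipeline targets, with every
deformation an analytic function of the template's (x, y)
parameterisation so ground-truth homology is available at any meshing:

- **Template**: a bilaterally symmetric face-like height field (elliptic
  dome plus Gaussian nose, brow, lips, chin) triangulated on a ≈ 1500
  vertex grid of a 130 × 170 mm patch; the nine landmarks sit at
  analytically known surface points.
- **Cohorts**: 20 subjects per sex per cohort by default, scanned at
  integer ages 7–12 and 12–17 (480 scans — the same order as the ~520 of
  a realistic two-cohort longitudinal study).
- **Identity**: 8 fixed Gaussian radial-basis displacement fields with
  per-subject N(0, 1.5 mm²) coefficients.
- **Growth**: displacement pattern concentrated at nose, chin, brow and
  forehead plus vertical elongation, scaled to 10 mm total (ages 7→17) at
  the fastest vertex, multiplied by a cumulative schedule S(age) whose
  piecewise-linear velocity is flat over 7–10, peaks at 11.5 y (girls) or
  12.5 y (boys) and decays to near zero by 16.5 — the classic pubertal
  spurt with earlier female timing.
- **Nuisance**: per-scan rigid jitter (±5°, ±10 mm), i.i.d. vertex noise
  (0.2 mm SD), and independent re-meshing (resolution ±2 grid lines,
  interior parameter jitter) that destroys native vertex correspondence;
  optionally a disc-shaped hole of configurable area fraction.
- **Anthropometry**: heights follow sex-specific piecewise-linear growth
  curves with subject offsets; each subject's BMI percentile performs a
  drifting walk (configurable drift SD) and weights are back-computed
  through the synthetic LMS reference, so ΔBMI-percentile analyses have
  known structure.
- **Determinism**: one seed feeds a fixed `SeedSequence` spawning scheme
  (identity fields → subjects → scans → anthropometry); identical seeds
  give byte-identical datasets (text OBJ/JSON/CSV and raw .npy).

What the generator does **not** emulate: photorealistic anatomy,
landmark placement error, expression variation, scanner artefacts other
than i.i.d. noise and holes, or anatomically validated growth
magnitudes. Passing tests therefore demonstrate correctness of the
machinery (registration, statistics, trajectory recovery, prediction
accounting), not clinical accuracy on real faces.

## Problem sizes in tests and the acceptance script

Unit tests use 120–800-vertex templates and 1–24 subjects; the
registration fidelity checks use the full 1500-vertex template; the
end-to-end smoke evaluation uses 4 subjects/sex/cohort at 800 vertices
(one sex), chosen so the whole suite runs on a laptop-class single core
in minutes. The pipeline itself is size-agnostic; 25k-vertex scans
engage the low-rank CPD path.

## Known limitations

- Correspondence across re-meshings retains a residual *tangential*
  error (≈ 0.4 mm RMS on noise-free synthetic pairs) that projection
  cannot remove; it is the dominant correspondence error source and sets
  a floor on achievable prediction error.
- The trajectory model assumes a common ageing pattern per sex (shared
  cohort slopes); individual growth-tempo differences enter as error.
- Per-subject lines + Hermite glue cannot represent curvature inside a
  cohort's age range.
- The paired t-test treats subjects as independent; the age-12 shared
  scan makes cohort models weakly dependent.
- The synthetic LMS reference supports testing only; conclusions about
  real BMI percentiles require a real national reference table.
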