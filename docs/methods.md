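# Methods

This note documents the models, conventions and numerical choices
behind `dentasym`, and what the synthetic-data tests do and do not
demonstrate about real scan data.

## Facial coordinate frame

The frame is the solution of three line-perpendicularity constraints on
an orthonormal, right-handed basis: X ⊥ (N − LS), Y ⊥ (CPR − CPL),
Z ⊥ (MP − MO), origin at LS. Three constraints on the three rotational
degrees of freedom generically determine the basis up to discrete sign
choices. We fix the signs anatomically — X·(CPR − CPL) > 0 (CPR is the
right eye, so +X points to the patient's right), Z·(N − LS) > 0 (nasion
is superior to the lips), Y = Z × X — giving +Y anterior and the
reading "negative x = patient's left".

The "eye centre" and "mid-porion/orbitale" constructions are
implemented as midpoints of their landmark pairs; that is the only
point-valued reading of a construction "from the line" between two
landmarks. Likewise dentMid is the midpoint of mes11/mes21.

**Solver.** Initialisation by Gram–Schmidt (X from the eye-line
direction orthogonalised against the LS–N direction, Z from LS–N
orthogonalised against X, Y completing the triad), then refinement by
Levenberg–Marquardt least squares over a rotation-vector chart around
the initialiser, minimising the three normalised constraint dot
products. Orthonormality is enforced exactly by the rotation
parameterisation. The solver refuses configurations in which any two
constraint vectors subtend less than 5° (anatomically the three lines
are near-orthogonal; near-collinearity indicates corrupt input) and
rejects solutions whose residual exceeds 1e-9; in practice residuals
reach machine precision (~1e-16) and a known generating rotation is
recovered to well below 1e-7 rad.

Because the constraints are formulated on landmark *differences* and
the origin on a landmark, the frame is equivariant under rigid motions
of the input: frame coordinates of every landmark, and hence every
deviation parameter, are invariant to how the scan happened to be
oriented (verified to 1e-9).

## Plane fit and deviation metrics

The maxillary median plane is fitted to RPM_1…RPM_6 by orthogonal
(total) least squares: normal = eigenvector of the centred scatter
matrix for its smallest eigenvalue, plane through the centroid,
rms residual = √(λ_min/n). A regression of one coordinate on the
others would not be rotation-invariant; the orthogonal fit is. The fit
refuses near-collinear point sets (second-smallest eigenvalue ≤ 1e-8 ×
largest). The normal's sign is fixed so its x-component is ≥ 0 (ties
broken on y, then z), making all signed plane distances reproducible.

Metric conventions, chosen so the three transverse quantities are
commensurate and additively consistent:

- deviations from facMP are plain x-coordinates (facMP is x = 0);
- dentMid→maxMP is the true perpendicular distance to the fitted plane;
- the maxMP–facMP gap "at the level of dentMid" is measured **along the
  transverse axis** at dentMid's (y, z):
  x\* = (d − n_y·y − n_z·z)/n_x. With that choice, whenever the planes
  are parallel, dentMid_facMP = dentMid_maxMP + maxMP_facMP_at_dentMid
  holds exactly; a perpendicular inter-plane distance would not be
  commensurate with the x-readouts. Requires |n_x| ≥ 0.5 (maxMP must
  stay near-sagittal; far beyond that the "transverse gap" loses
  meaning).
- the projected angle is the signed rotation about +Z carrying the
  facMP∩horizontal line (the y-axis) onto the maxMP∩horizontal line,
  i.e. atan2(n_y, n_x) for the n_x ≥ 0 representative, folded to
  (−90°, 90°] since planes define undirected lines. Positive = anterior
  end to the patient's left. Planes with |n_z| ≥ 0.95 are rejected as
  near-horizontal. The fitted plane is used as-is, not constrained to
  be vertical before projection: the projection itself discards the
  vertical tilt, and constraining first would discard fit information.

## True positions and variability

Per subject × landmark × axis, placements follow a random-intercept
model y_ij = μ + u_i + e_ij with rater effects u_i ~ N(0, σ_rater²) and
residual e_ij ~ N(0, σ²), fitted by REML. For the balanced complete
design (every rater, every repeat) the REML solution is closed-form:
the intercept is the grand mean, σ̂² = MSW, σ̂_rater² = (MSB − MSW)/k
truncated at zero (boundary case: σ̂² = total SS/(N−1)), and
Var(μ̂) = MSB/(rk). Unbalanced data are handled by profiling the REML
likelihood over γ = σ_rater²/σ² (log-scale bounded search, tolerance
1e-12, compared against the γ = 0 boundary). The implementation is
cross-checked against an independent mixed-model engine in the test
suite. Cross-axis covariance is not modelled: the quantities consumed
downstream (fixed intercepts, per-axis SDs) are identical for balanced
data, and a trivariate REML would add nothing they use.

Variability is a two-stage estimate: sample SDs (n−1 denominator) per
cell — per (subject, rater) over repeats for intra-rater, per
(subject, repeat) over raters for inter-rater — then an intercept-only
linear model over all cells of all subjects: mean SD with
CI = z₀.₉₇₅·sd(cells)/√n. The normal quantile (not t) is used because
cell counts are large in any realistic design (hundreds of cells); the
estimator weights cells equally (plain mean). Note the mean of sample
SDs is a c₄-biased estimate of σ (c₄(3) ≈ 0.886 for 3 repeats); the
pipeline reports the mean cell SD itself, as a descriptive variability
measure, not a debiased σ̂.

3D variability is computed per cell as √(sd_x² + sd_y² + sd_z²) and
then combined across cells — not as the 3D combination of the already
combined per-axis numbers. The two orders differ once cells are
heterogeneous; the per-cell order keeps the 3D number a mean of
per-cell quantities like the per-axis columns.

Landmark-level SDs are computed after transforming each rating into
the subject's *common frame*, built from the estimated true positions,
so "x" is transverse for every subject. Parameter-level SDs use each
rating's own frame (origin at its own LS): parameters are frame-scalars,
and rating-to-rating frame variation is part of the measurement error
being quantified.

**Sample size.** N = ⌈4·z²₁₋α/₂·σ²/w²⌉ (minimum 1) gives the number of
observations for which the expected 95% CI width of a normal mean with
variance σ² is ≤ w; it derives from width = 2z·σ/√N ≤ w. σ = 0.5 mm,
w = 0.25 mm, α = 0.05 gives N = 62, confirmed by Monte-Carlo in the
suite. The formula is quadratic in z; a linear-in-z variant is
dimensionally inconsistent with its own derivation.

## Cohort statistics

Per-subject parameter values entering cohort statistics come from the
estimated true landmark positions (one noise-free record per subject),
not from a single arbitrary rating. Summaries use linear-interpolation
(type-7) quantiles. The paired Wilcoxon signed-rank test drops zero
differences and mid-ranks ties; for ≤ 25 nonzero differences the exact
tie-aware null distribution is computed by convolving the per-pair
generating functions (1 + t^{2rᵢ})/2 over the doubled-rank lattice,
otherwise a normal approximation with continuity and tie corrections
is used. The location estimate is the Hodges–Lehmann median of Walsh
averages of the differences, with a distribution-based CI (k-th
smallest/largest Walsh average, k from the signed-rank null). Spearman
correlation is the Pearson correlation of mid-ranks. With n = 66
subjects the asymptotic Wilcoxon p is the default; the exact variant is
available via the `exact=` flag.

## Synthetic cohorts

The generator emulates a 4-rater × 3-repeat digitisation study on a
bilaterally symmetric adult-scale template face (LS at origin, paired
landmarks mirrored about x = 0, raphe landmarks on x = 0, porion and
orbitale at one height so the canonical axes satisfy the frame
constraints exactly). Subject-level asymmetry draws (all centred
normal):

| parameter | default SD | rationale |
|---|---|---|
| maxillary transverse shift | 1.3 mm | matches the spread of skeletal-midline gaps seen in untreated adults (IQR ≈ 1.8 mm) |
| maxillary horizontal rotation | 1.4° | plane-angle IQR ≈ 1.9° |
| dental offset vs maxMP | 0.7 mm (group A) | dental–skeletal IQR ≈ 1.0 mm; group B uses a larger value to model tooth migration |
| nose-tip deviation | 0.7 mm | PRN IQR ≈ 0.9 mm |
| chin deviation (POG+GN jointly) | 1.2 mm | chin IQR ≈ 1.4–1.8 mm |
| rater bias (per rater × landmark × axis) | 0.3 mm | inter-rater SDs exceed intra-rater SDs by roughly this margin |
| repeat noise | per-landmark table | anisotropic: raphe 0.2–0.3 mm transverse vs 0.6–1.6 mm sagittal; incisor points sharp; chin/orbitale diffuse |

The rotation is applied about the vertical axis through the raphe
centroid, so shift and rotation are approximately separable at the
dentMid level and ground truth is interpretable against the pipeline's
translation/rotation decomposition. Randomness uses a seeded
`numpy` generator with one spawned sub-stream per subject (plus one for
rater biases), so datasets are exactly reproducible and subjects
independent.

**What the generator does not emulate:** surface-based landmark
ambiguity (noise is Gaussian, real placement error is surface-
constrained and skewed), scan-merging/registration error between face
and jaw models, correlated errors across neighbouring landmarks, tooth
morphology changes under migration (group B differs only in midline
offset), and vertical/sagittal asymmetry. Passing tests therefore
demonstrate correctness of the geometry and statistics under the
declared error model, not clinical accuracy on real scans.

## Problem sizes and determinism

Default verification runs use cohorts of 3–100 subjects (66 for the
cohort-scale checks, matching a realistic reference-group size; 200
single-landmark subjects for variance-component recovery; 500
replications for CI calibration; 1,000 random configurations for the
frame solver). All stochastic tests and the acceptance script draw
from fixed or CLI-provided seeds.

## Known limitations

- The Wilcoxon CI uses Walsh averages of all differences but critical
  values from the nonzero-difference null; with many exact zero
  differences the CI is conservative.
- The REML profile search bounds γ in [e⁻²⁵, e²⁵]; variance ratios
  outside that range are clamped (indistinguishable from the boundary
  in double precision).
- `offset_at_point` and `projected_angle` are undefined for planes far
  from sagittal (|n_x| < 0.5) or near-horizontal (|n_z| ≥ 0.95); such
  inputs raise `GeometryError` rather than returning extrapolated
  numbers.
- Group assignment is an input annotation; nothing in the pipeline
  infers it from morphology.
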