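# Methods

`femofall` is a desk-scale re-implementation of a femoral sideways-fall
analysis pipeline: subject-specific hexahedral femur models with
density-derived elastic-perfectly-plastic bone properties are loaded to
failure under a lateral-fall configuration, ten mechanical descriptors are
extracted from the force-displacement response, and the descriptors'
ability to separate hip-fracture cases from controls is quantified with
cross-validated logistic regression, AUROC and the DeLong test.  Because
the underlying clinical images and cohort are not available, every input is
synthetic: phantom meshes stand in for reconstructed anatomies, and cohorts
are drawn from the published group distributions (64 fracture + 64 control
post-menopausal women; means and SDs transcribed in
`src/femofall/data/reference_cohort.yaml`).

## Constitutive model and material mapping

Radiological density rho_QCT (g/cm^3) converts to ash density by
rho_ash = 0.87 rho_QCT + 0.079 and to apparent density via a fixed
ash/apparent ratio (default 0.6; configurable in [0.55, 0.63] — values
outside that physiological range raise a warning).  Elasticity follows
compartment-specific power laws: trabecular E = 0.003715 rho_app^1.96
(rho_app in kg/m^3) and cortical E = 10200 rho_ash^2.01 (g/cm^3), E in
MPa, nu = 0.3.  Yield stresses: trabecular sigma_yc = 38.5 rho_app^1.48
and sigma_yt = 22.6 rho_app^1.26 with rho_app in g/cm^3 — the Morgan-type
coefficients produce physiological MPa only in those units, so the two
density conventions are kept explicit; cortical sigma_yc = -0.41 + 0.0062 E
(a "+0.41" reading of the ambiguous printed intercept is selectable by
config) and sigma_yt = 0.33 + 0.0039 E, with a 0.01 MPa positivity floor.
Density images are accepted per-node or as rectilinear grids in mg/cm^3
(the vBMD convention) and sampled at element centroids by default, or
averaged over the 2x2x2 Gauss points by config.

## FE solver

Small-strain hex8 elements with B-bar (mean-dilatation) integration to
avoid volumetric locking at nu = 0.3; full integration is available by
config.  Plasticity is J2 perfect plasticity with radial return; each
integration point selects compressive vs tensile yield by the sign of its
trial mean stress.  A hard sign switch makes the stress response
discontinuous in strain (points whose trial pressure crosses zero jump
between yield surfaces), which stalls Newton iterations on bending-dominated
phantoms; the selection is therefore blended linearly over a narrow pressure
band (half-width 5% of the mean yield stress, `switch_band`; 0 restores the
sharp rule).  The global solve is a damped Newton with backtracking line
search and, at actively yielding points only, a 0.1% elastic admixture in
the iteration matrix; both devices affect only the iteration path — the
converged residual (tolerance 1e-6 relative to the running internal-force
scale) and all committed quantities use the true constitutive response.
These choices were validated against closed forms: the uniaxial bar
reproduces slope EA/L, plateau sigma_y A, residual displacement D0 - F0/k
and the dissipation rectangle to 1e-9 relative, and a distorted-mesh patch
test is exact to 1e-10 (this test caught an inverse-Jacobian transpose bug
during development — it is the reason it exists).

Side-fall boundary conditions follow the cadaveric-experiment layout: the
distal shaft section is fully clamped, the greater-trochanter surface is
fixed only along the fall direction, and the femoral-head surface is
rigidly coupled (translations only) to a reference point displaced along
the fall direction in 0.05 mm increments (default) up to 6 mm.  The fall
direction is parameterized by adduction and internal rotation, both within
0-30 degrees.  Constraints are implemented by a sparse affine reduction
u = Z q + c + lam p, which also supplies the reaction force as p . f_int.

**Failure detection.**  The reference procedure stops "when the reaction
force starts to drop".  Under small-strain perfect plasticity the reaction
at a monotonically driven constraint is non-decreasing toward the limit
load (Drucker stability), so a literal drop never materializes without the
geometric nonlinearity the original (Abaqus-based) models had.  The package
therefore offers three criteria on `LoadProgram`: `"drop"` (first force
decrease below 0.999 of the running maximum — the faithful reading, which
correctly never fires on a uniaxial bar), `"plateau"` (tangent stiffness
below 2% of the initial stiffness, i.e. limit-load attainment — the event
the drop criterion detects when geometry softens), and
`"drop_or_plateau"` (used by the phantom studies).  F0 is the maximum
recorded force and D0 its displacement (first index on ties).

Energy bookkeeping uses the midpoint-rule identities of the discrete
problem: external work accumulates (F_n + F_{n+1})/2 * delta_d, elastic
energy is 0.5 sigma : C^-1 sigma integrated over the mesh, and dissipation
accumulates (sigma_n + sigma_{n+1})/2 : delta_eps_p per point.  These three
satisfy W = E_el + E_dis identically at equilibrium, so the energy-balance
check (tolerance 1e-4 relative) is a genuine test of solver consistency,
not of the bookkeeping.

## Descriptor extraction

The loading curve truncated at the strength point is approximated by a
continuous two-segment ("bilinear") least-squares fit whose first segment
is anchored at the origin — F1 and D1 are reported as single elastic
force/displacement values, which forces that anchoring.  The breakpoint is
found on a grid (200 uniform candidates united with the sample abscissae,
guaranteeing the fit is at least as good as an exhaustive per-sample
search) and refined by bounded scalar minimization.  Degenerate inputs
(fewer than 4 points, collinear data, or no concave second regime) return
k2 = k1 with D1 = D0.  The ten descriptors and their identities
(D2 = D0 - D1, E_res = E_nl - E_dis, F0 >= F1, 0 <= D3 <= D0) are enforced
by `DescriptorSet.validate` and fuzzed over 10^4 generated curves in the
acceptance suite.  D3 and the dissipated energy come from the simulated
unloading branch when present (zero-force intercept by linear
interpolation; area between loading and recovered curves) and otherwise
from elastic unloading at the fitted initial slope; the two paths agree
exactly when unloading is linear at slope k1.  E_res is defined by the
identity E_nl - E_dis; the unloading-curve integral serves as a
cross-check only.

## Synthetic cohorts

*Descriptor level.*  Per group, subjects are multivariate-normal draws with
the reference means/SDs.  The between-descriptor correlation is not
reported anywhere; the default is block-structured (0.9 within force-like
descriptors, 0.8 within displacements and densities, 0.7 within energies,
0.6 force-displacement and force-energy, 0.5 displacement-energy, 0.2-0.3
to densitometry), verified positive definite at build time.  Every result
involving descriptor combinations is conditional on this choice and is
reported as such.  Positivity is enforced by rejection re-sampling of the
offending rows (mean bias negligible at the reference coefficients of
variation).

*Curve level.*  Per subject the quadruple (F0, D0, D3, D1) is drawn from
the group distribution and an exact elastic-plastic curve is built around
it: initial slope k1 = F0 / (D0 - D3), breakpoint (D1, k1 D1), second slope
joining (D0, F0), linear unloading at k1, optional quadratic knee rounding
(default relative width 0.1) that leaves F0, D0 and D3 untouched.  This
construction makes the extracted strength and residual displacement
reproduce the configured moments by construction — those are the quantities
the calibration checks target — while F1 and the energies follow to within
a few percent (the printed group table is internally consistent with an
exact bilinear response, so the discrepancy is small).  When a draw
violates D1 < D0 - D3 (which would break F0 >= F1), only D1 is re-drawn
from its conditional normal, preserving the F0/D0/D3 marginals.

*Phantoms.*  `graded_beam` is a prismatic hexahedral beam (default 4x4x20
elements, 20x20x100 mm) with a one-layer cortical shell and trabecular
core; `femur_like` sweeps square-to-ellipse cross-sections along a shaft
that bends 45 degrees into a narrowed neck and widened head, with densities
tapering through the neck so the limit load is reached within a few mm of
head displacement.  Default densities (cortical 850, trabecular
180 mg/cm^3, 5% nodal noise) give compartment summaries in the range of the
reference densitometry (e.g. cortical sBMD ~ 149 mg/cm^2).  These phantoms
exercise the solver and the density summaries; they do not attempt to match
real inter-subject anatomy statistics, so cohort-level results are always
generated at descriptor or curve level.

Compartment summaries are volume-weighted means (mg/cm^3); the mean
cortical thickness is estimated as cortical volume over lateral boundary
surface area, and cortical sBMD is vBMD times thickness in cm.

## Discrimination statistics

Group differences use a Shapiro-Wilk gate at alpha = 0.05 per group (the
gating test itself is a package choice): both groups normal leads to the
unpaired t-test (Welch by default, pooled by config), otherwise the
Mann-Whitney U test with scipy's exact/asymptotic policy and tie
correction.  Logistic models are unpenalized with an intercept, fitted by
Newton-IRLS with features standardized inside each training fold;
separation is handled by capping |beta| at 50 rather than penalizing.

Two cross-validated AUROC estimators are provided, and the distinction
matters.  Pooling the n leave-one-out held-out probabilities into a single
AUROC (`pooled_loo`) is severely pessimistically biased for weakly
informative predictors: removing a case both shifts the fold's intercept
(63 vs 64 class balance) and drags the fitted slope away from the left-out
subject, anti-correlating score and label — on null features at n = 128 the
pooled estimate averages ~0.36 rather than 0.5.  The published univariate
AUROC values track the binormal values Phi(dmu / sqrt(s0^2 + s1^2)) of
their own group table and therefore cannot have been produced by a
pooled-LOO estimator.  The default estimator is leave-pair-out CV
(`leave_pair_out`): every (case, control) pair is scored by a model fitted
on the remaining n - 2 subjects and the AUROC is the fraction of correctly
ordered pairs — an established, nearly unbiased CV estimator of AUC, here
vectorized so all ~4096 pair models are fitted simultaneously by batched
IRLS.  Reported AUROCs use leave-pair-out; the pooled-LOO scores are kept
because the DeLong comparison needs paired per-subject scores, and are used
only there.  Replicate-averaged leave-pair-out AUROCs on binormal 64+64
cohorts reproduce every published univariate value within 0.02-0.03.

The DeLong machinery is the standard placement-value estimator: per-model
case and control placements, covariance across models, normal test on the
AUROC difference; identical rankings short-circuit to p = 1.  Its single-
model variance is validated against a stratified bootstrap (within 15% at
n = 200).

Combination descriptors (strength + residual displacement, etc.) depend on
the unreported joint distribution; under the default correlation block the
acceptance suite checks only the qualitative property that a combination
does not fall below its best single component.

## Problem sizes and numerical defaults

Acceptance-grade runs use: 100-500 binormal replicates per descriptor
(AUROC means stabilize to ~0.003 SE at 500), 5000 subjects per curve-level
cohort, phantoms of at most 2000 elements with 0.05-0.1 mm increments, and
10^4 fuzzed curves for the identity sweep.  Newton tolerance is 1e-6
relative, IRLS tolerance 1e-6-1e-8 with at most 60 iterations, and the
bilinear-fit grid is 200 (60 in the bulk fuzz, where the exact breakpoint
is included among the samples).

## Known limitations

- Small strain and no contact: the post-peak softening branch of a real
  fall cannot be reproduced; failure is identified with limit-load
  attainment (see failure detection above).
- The synthetic cohorts inherit only the published marginal moments; all
  joint-distribution statements (combination AUROCs, DeLong p-values
  between descriptors) are conditional on the default correlation block.
- Phantom anatomy is schematic; absolute phantom strengths (hundreds of N
  for the default femur-like phantom) are below in-vivo femur strengths,
  deliberately so — they are solver exercisers, not anatomy models.
- Mann-Whitney p-values use scipy's tie-corrected implementation; for very
  small groups with heavy ties the exact distribution is approximated.
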