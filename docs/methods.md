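# Methods

This note documents the models implemented in `ssimfem`, the assumptions
behind them, the parameters that matter, and what the synthetic cohorts
do and do not establish about real data.

## Shape model

Anatomy is represented non-parametrically: a subject's shape is the
template carried through a Gaussian-kernel deformation

    x ↦ x + Σₖ exp(−‖x − cₖ‖² / w²) βₖ ,

with control points `cₖ` on a regular lattice over the template bounding
box and moment vectors `βₖ` (mm) as the subject descriptor. This is a
*small-deformation* (single-step) kernel model: it linearises the
geodesic flows used by large-deformation diffeomorphic registration while
keeping the same data structure — moments on a shared control grid — and
therefore the same downstream statistics. The departure matters only for
large deformations, where a single kernel step is no longer
diffeomorphic; for the population-scale shape differences modelled here
the linearisation is the standard desk-scale simplification. It is
exactly linear in `β`, which the tests exploit as an invariant.

Pose is removed in two steps before moment fitting: (1) a closed-form
initialisation that superposes femoral-head centres and aligns neck axes,
resolving the roll about the neck axis by aligning shaft axes (the
anti-parallel case degenerates gracefully to a half-turn about the axis
the frame construction selects); (2) point-to-point ICP (KD-tree closest
points, determinant-corrected SVD updates). ICP non-convergence returns
the best transform with a warning rather than failing, since a warm-started
registration is still usable.

Moment fitting alternates closest-point correspondence with a
ridge-regularised linear solve for `β`. Two numerical regimes matter:

- **Kernel width.** The default is twice the control-grid spacing, which
  gives smooth, fully covering deformations but makes the moment →
  displacement map strongly ill-conditioned (overlapping kernels are
  nearly collinear). *Deformations* are still well determined; *moments*
  are not. Recovery of moments is therefore only meaningful at a width of
  about one grid spacing, with displacements below the surface-mesh
  resolution (so correspondences are unambiguous) and with the ridge
  pushed toward zero. The self-consistency tests run in exactly this
  regime and recover synthetic moments to well under 5% relative error.
- **Ridge default.** `reg_lambda = 1e-6 · trace(KᵀK)`, a scale-free
  conditioning floor. With it, solutions are stable but biased toward
  zero in near-null kernel directions; moments attached to control points
  far from the surface are unidentifiable in principle (they move no
  surface point) and are reported as ≈0.

## Intensity model

Scanner intensities are mapped to hydroxyapatite-equivalent density by an
ordinary-least-squares line through a calibration phantom (standard
five-sample design spanning 0–200 mg/cm³). Densities are sampled once per
tetrahedral element of the subject-morphed template mesh — `centroid`
(default) or `mean5` (four nodes + centroid) aggregation, configurable
and recorded — replacing full volume integration; with elements small
relative to field variation the difference is second-order. Calibrated
values below zero are clamped to 0 and counted. Because all subject
meshes are the one template morphed by each subject's moments, element
order is identical across subjects and the per-subject vectors stack into
the N × n matrix G without correspondence errors.

## PLS models (SSM, SIM, SSIM)

All three statistical models use NIPALS PLS1 against the centered binary
fracture status: weights `w_j ∝ X_jᵀy_j`, scores `t_j = X_j w_j`,
loadings `p_j = X_jᵀt_j/(t_jᵀt_j)`, response loadings
`q_j = y_jᵀt_j/(t_jᵀt_j)`, then rank-one deflation of both blocks.
Numerical conventions:

- Columns are centered but **not** variance-scaled by default: each block
  has homogeneous units, and scaling would inflate noise-dominated
  coordinates. A `scale` flag exists and is recorded.
- Mode signs are fixed by making each weight's largest-magnitude entry
  positive, so repeated fits and exports are reproducible.
- "Mode variance" σ²_j is the sample variance (ddof = 1) of the j-th
  score column; ±σ mode exports decode `x̄ ± σ_j p_j` back to a deformed
  surface (shape), an element field (intensity), or both (fused).
- Variance-explained profiles are cumulative Frobenius fractions
  `‖t_j p_jᵀ‖²/‖X_c‖²` for the data block and `‖q_j t_j‖²/‖y_c‖²` for the
  status; extraction stops early (flagged) if the residual
  cross-covariance vanishes.
- Projection of new subjects repeats the training recursion (deflate by
  `t_j p_j` after each mode), so training rows reproduce their stored
  components to round-off — the property the cross-validation relies on.

The fused model (SSIM) is two-level: the shape and intensity component
matrices are concatenated — by default every mode each first-level model
needed to reach 90% of its data variance — and a second PLS is fitted on
that score matrix. Block provenance is kept so fused modes can be decoded
through their parent models. The concatenated columns are left unscaled;
experiments with per-column standardisation amplified the noise-dominated
late modes and consistently hurt, so the natural (decaying) score
variances act as the regulariser. How many columns to concatenate and
whether to rescale them are genuinely open choices; both are exposed as
configuration.

## Outlier screening

Influence is measured on the PLS-component regression (the raw p ≫ N
matrices admit no classical OLS diagnostics): for each subject the
m-component PLS regression is literally refitted without that subject and

    D_i = Σ_k (ŷ_k − ŷ_k^{(−i)})² / ((m+1) s²)

with `s²` the full-model residual mean square. No shortcut approximations
are used; an independent refit oracle reproduces the distances to 1e-8.
Because the PLS directions themselves depend on the response, removing
*any* subject rotates them slightly, which puts these distances on a much
larger scale than the classical OLS ≈ 1/N. The default flagging threshold
is therefore the scale-free form of the usual rule, 4·mean(D); an
absolute cutoff can be supplied instead. On strong-signal cohorts, a
subject displaced six score standard deviations along the first mode is
flagged with no false positives; on weak-signal cohorts such a
displacement is not identifiable in principle (its distance sits inside
the bulk), which is the expected behaviour of the diagnostic, not a
failure of the implementation.

## Classification and validation

Logistic regression is fitted by IRLS (convergence at max coefficient
update < 1e-8, cap 100 iterations). Quasi-separation is detected via
runaway linear predictors (|η| > 15) and resolved by refitting with a
small ridge (1e-4) on the slopes, flagged in the result. Folds are
class-balanced: each class is shuffled with the run seed and dealt
round-robin, with the dealing pointer carried across classes so fold
sizes differ by at most one (93 subjects in 10 folds gives sizes 9–10
with 4–5 of each class — the arithmetic the cohort design forces).
Within each fold the *entire* statistical model — PLS extraction,
including the two-level fusion and its variance cut — is refitted on
training subjects only; test subjects are projected and scored, and
scores are pooled into a single ROC per model. AUC is the Mann–Whitney
pair statistic with ties counted ½ (computed by midranks, exact under
ties). Confidence intervals are class-stratified bootstrap percentiles
(default 2000 resamples, seeded); the interval method is a package
choice, as is the fixed 0.5 confusion-matrix threshold. The default two
predictor components follow the study protocol this pipeline mirrors.

## Synthetic cohorts

The generator emulates the statistical structure of a QCT fracture
cohort, not its anatomy. The template is a stylised proximal femur
(capped shaft tube + angled head sphere, mm scale) extracted as a
watertight surface from an implicit union by marching cubes, filled with
tetrahedra by Delaunay triangulation of a jittered interior lattice
(default ≈ 400–600 elements — far coarser than a clinical 1.5 mm mesh,
deliberately, since all acceptance checks are statistical), with a
cortical-shell density baseline (950 mg/cm³ within 2.5 mm of the surface,
280 inside).

Per cohort (single seeded RNG stream, documented draw order): status with
near-balanced classes; unit effect directions — shape `u_s` (random),
density `u_i` (positively biased: global mass loss plus spatial
redistribution at spatial/mean ratio 6, so an areal average sees part but
not all of the signal), interaction `u_x` (orthogonal to `u_i` and to the
element-volume vector, hence invisible to the areal average); eight
shared nuisance latents with geometrically decaying amplitudes (8.0,
decay 0.7) loading on both blocks; then subject scores

    a_i = z_a − d_s(status−½),  b_i = z_b − d_i(status−½),
    moments_i = a_i u_s + Σ amp_l z_l v_l + ε,
    density_i = base + b_i u_i + d_si·1[a_i<0 ∧ b_i<0]·u_x
                + Σ amp_l z_l w_l + ε,

with i.i.d. Gaussian noise (default σ = 0.3) and clamping at zero. The
aBMD analog divides total calibrated mass by the template's frontal
(coronal) shadow area — polygon union of projected boundary faces — with
mm→cm conversion; using the shared template geometry makes it a purely
densitometric average, as DXA's single number is. With all effects zero
the classes are exchangeable by construction.

The default effect sizes (d_s = 0.3, d_i = 1.0, d_si = 1.0, N = 100)
define the reference condition: weak shape signal, strong density signal,
and a joint effect. The strong structured nuisance is what reproduces the
key qualitative finding — the intensity model's two raw-space components
lose part of the signal to estimation noise, while the two-level fused
model re-collects it from the wider component sets, so the median
cross-validated AUC ordering is shape < intensity ≤ fused with a positive
fused-minus-intensity margin. The aBMD analog lands between the shape
model and the intensity model and is *comparable* to the intensity model
at these effect sizes: with a unit-variance density latent, the
noise-free areal average is a strong summary, and the clear
intensity-over-aBMD separation seen in real cohorts would require larger
effect sizes than the reference condition fixes.

What passing tests on these cohorts do **not** show: anything about real
anatomical covariance structure (the nuisance spectrum is a modelling
choice, not an inference), partial-volume or cortical-shell imaging
effects, pair-matching confounders, or absolute AUC levels — only the
relative ordering and the mechanics of the pipeline are exercised.
Effect-direction recovery (cosine > 0.9 between a generative direction
and the first PLS mode) is likewise verified on clean single-effect
cohorts without structured nuisance: with strong correlated nuisance the
X-loading provably mixes nuisance into every mode at any plausible effect
size, so that check is only informative in the clean configuration.

## Degenerate inputs and edge cases

Single-class responses, empty fused blocks, mismatched subject sets,
ragged intensity vectors, non-binary status files, truncated matrix rows,
out-of-domain field samples, zero projected shadow area and folds that
would lose a class are all hard errors with named context. Perfect
regression fits make Cook's distances undefined (reported as zero with a
warning); unreachable variance targets return the full mode count with a
flag; all-tied scores give AUC ½.
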