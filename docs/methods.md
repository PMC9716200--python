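# Methods

This note documents the models and procedures implemented in
`kneewear`, their assumptions, the parameters that matter, and the
design decisions taken where several constructions were defensible.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohort generator

**What it emulates.** The generator stands in for a CT-derived clinical
cohort: corresponded femur/tibia surface meshes with joint-centre
landmarks, arthritic degradation, per-case wear fields, and the study
roster (933 cases, 460 female / 473 male, with 61 + 74 exclusions for
hip/knee prostheses, osteosynthesis and segmentation errors, leaving
798). Exclusion reasons are generated mutually disjoint so per-reason
tallies sum exactly; overlap in real patients is unknown.

**Limb geometry.** Bones are schematic tube-with-articular-cap
surfaces, not anatomically detailed reconstructions: the downstream
pipeline needs dense correspondence, landmarks, a measurable joint gap
and controllable morphology, nothing more. Key constructions:

* *Canonical frame*: +x medial, +y posterior, +z superior, knee centre
  at the origin. All lengths mm, angles degrees.
* *HKA alignment* (`hka_deg`, default 180, healthy SD 2.5°) is built
  into the bone geometry as a smooth coronal bend of each shaft
  relative to its articular cap, split evenly over femur and tibia —
  constitutional varus/valgus lives in the distal femur and proximal
  tibia, exactly the property that lets an articulated shape model
  recover pre-disease alignment from bone shape. A rigid per-bone
  rotation would carry no shape information and make twin realignment
  impossible in principle.
* *Torsions* twist the bone ends about the long axis (healthy femoral
  anteversion 10 ± 5°, tibial external torsion 20 ± 5°), the *tibial
  slope* tilts the plateau about the medial axis (7 ± 2.5°), *bowing*
  bows the femoral shaft, `scale_mm` is the femoral length
  (420 ± 20 mm); the tibia is 0.88× the femur, the neutral joint gap
  6 mm per 420 mm femur.
* *Individuality* beyond the six parameters is a smooth seeded radial
  perturbation (default amplitude 0.6 mm) of the shafts, tapered to
  zero at the articular caps so articulating surfaces stay congruent
  across the cohort — otherwise per-case surface congruence dominates
  the joint-space maps and confounds any wear↔geometry analysis. The
  shaft cross-section is deliberately asymmetric (real bone is), which
  prevents rigid registration from locking onto a rotated pose.
* Same `(params, seed, resolution)` → bit-identical meshes; all limbs
  at one resolution share the template topology.

**Arthritic degradation** (`impose_arthritis`) applies, in order:
osteophyte-like offsets along outward vertex normals (restricted to the
joint margins — osteophytes do not form on the articulating surface);
optional patterned "wear carving" of the femoral cap along the joint
axis; uniform joint-space narrowing as a rigid femoral translation; and
extra coronal misalignment as a rigid femoral rotation about the knee.
The exact per-vertex displacement field is returned, so subtracting it
restores the input to machine precision and every reconstruction can be
scored against truth. Narrowing beyond the generated joint clearance is
rejected as non-physical.

**Wear fields** are mixtures of five smooth bump templates on the unit
square (u medial→lateral, v anterior→posterior): medial, lateral,
anteromedial, posteromedial, tibial spine. Medial/lateral and
antero/posteromedial are exact mirror pairs, which is what makes the
mirror augmentation in the encoder stage act transitively on the
taxonomy. The default class mixture follows the clinically observed
dominance of medial wear (medial 35%, bicompartmental 27%,
anteromedial 12%, posteromedial 11%, lateral 10%, spine 5% after
normalization); per-case weights get Gaussian jitter (SD 0.15) and the
field additive Gaussian noise (SD 0.05), clipped to [0, 1].

## Shape models and the virtual healthy twin

`build_ssm` performs generalized Procrustes alignment (rigid, no
scaling — mm units are meaningful) followed by SVD of the stacked
vertex coordinates; modes are orthonormal, variances sorted descending,
and `variance_kept` controls truncation (the experiment harnesses keep
all non-null modes: with ~15–25 training shapes every mode carries
signal, and overall size dominates the spectrum so an energy threshold
would discard alignment-bearing modes).

`robust_fit` interleaves (i) closest-point correspondence from model
vertices to the target surface, (ii) one-sided outlier flagging at
residual > mean + 2 SD — only protruding/distant pairs are disease
artifacts; the threshold is recomputed each iteration — (iii) rigid
re-alignment on inlier pairs, and (iv) least-squares coefficient
update on inliers, with loadings clamped to ±3 SD. Two numerical
choices matter and were found necessary: coefficients start from the
best isotropic rescaling of the mean (closest-point correspondence
alone carries almost no stretch signal, so the dominant size mode
otherwise stalls), and outlier trimming is suspended for a short
burn-in (3 iterations, with convergence not declared before one
post-burn-in robust update) so genuine shape discrepancy is not
discarded before the fit can absorb it. Convergence: relative
coefficient change < 1e-4, at most 50 iterations.

**Per-bone joint centres.** Each bone model carries its adjacent joint
centres (hip+knee for the femur, knee+ankle for the tibia) as
pseudo-vertices: they are synthesized from the loadings but take no
part in surface correspondence. A fitted bone therefore comes with
model-regressed joint-centre estimates.

**Twin reassembly.** `build_twin_models` learns, on the training limbs,
a least-squares regression from the concatenated per-bone loading
vectors (plus intercept) to the articulated whole-limb loadings;
`reconstruct_twin` applies it to the two robust fits and synthesizes
the articulated shape (bones + landmarks in one frame). This is the
well-posed realization of "reassembly according to the articulated
model": the relative bone pose follows the healthy population's
pose/shape covariance. An alternating scheme — rigidly align fitted
bones to the articulated prediction, update coefficients, repeat — was
implemented first and abandoned: the per-bone rigid gauge freedom gives
it a continuum of spurious fixed points, with coronal errors of several
degrees even on undeformed inputs, while the regression form is exact
in the identity limit (RMS < 0.1 mm, coronal error < 0.02° in the
validation harness).

**Alignment measurement** is intrinsic (invariant to rigid motion of
the limb): the coronal plane is spanned by the hip–ankle mechanical
axis and the stored medio-lateral axis; HKA is the angle at the knee
between the projected rays to hip and ankle, reported > 180° for varus.
Classification is inclusive at the conventional thresholds: valgus
≤ 177°, varus ≥ 183°. Torsions and slope are recovered from the stored
anatomical axes; femoral bowing from the mid-shaft chord deviation.

**Mahalanobis normalization** divides each mode loading by √(mode
variance), damping dominant unrelated variance (size) before
classification.

## Joint-space mapping

JSW is the unsigned closest-point distance from each femoral ROI vertex
to the tibial surface (exact point–triangle distances over KD-tree
candidates); interpenetration is clamped to 0 mm with a warning. Wear
w = clamp(1 − JSW/reference, 0, 1) with a cohort-level reference
(default 8 mm) so values are comparable across cases; a per-case
reference would absorb exactly the size/geometry signal the analysis is
about.

Flattening is a discrete harmonic map with cotangent weights: the
single boundary loop is pinned to the unit-square perimeter by
cumulative arc length, with four corners chosen deterministically (the
boundary vertex with maximal summed distance to the rest, then its
quarter-arc-length companions); interior vertices solve the Laplace
system. For a planar square patch with corners at the corners this is
the identity to solver precision. Orientation is normalized so no
tested geometry has flipped triangles; the maximal quasi-conformal
distortion (singular-value ratio of the per-triangle Jacobian) is
reported on the result. True conformal square maps need free
boundaries; the harmonic map with fixed square boundary is the standard
practical construction and is what the pipeline's mirror-symmetry
properties require.

Rasterization uses a thin-plate-spline RBF on the scattered (u,v)
samples, evaluated at pixel centres of an S×S grid (default 128;
the experiment harnesses use 32 px, which resolves the five bump
templates while keeping autoencoder training to seconds), clipped to
[0, 1]. The polynomial tail of the TPS reproduces constants and linear
ramps exactly, which the tests assert.

## Principal polynomial autoencoder

The network is a two-layer fully-connected encoder (pixels → hidden →
latent 15) with a mirrored decoder, written directly in numpy with
analytic gradients and Adam — desk-scale wear images do not need a GPU
framework, and a closed implementation keeps training bit-reproducible
from the seed. Defaults: tanh hidden units (width 256 at library level;
harnesses use 128 for 32 px images), linear latent and output layers,
lr 1e-3, batch 64, 300 epochs, masked-pixel MSE + L2 (1e-5) + sparse-AE
KL penalty (1e-4, target mean activation 0.1, hidden activations mapped
to (0,1)). Linear activations are available as a configuration, in
which case the model's degree-1 limit provably reproduces PCA — the
test suite asserts subspace agreement within 5°.

The bottleneck replacement: latent activations of the (original,
non-mirrored) images are centred and SVD-decomposed; component j's raw
scores are then residualized by a polynomial regression (default degree
2, with intercept) on the final scores of components 1..j−1. Residuals
are exactly orthogonal to all lower components, so pairwise Pearson
correlations vanish by construction. Components are reported in order
of decreasing residual variance; fractions are over total latent
variance, so their sum is ≤ 1 (the polynomial-explained share is
attributed to earlier components). Degree 1 leaves the SVD scores
untouched (orthogonal scores have nothing linear to remove). The
SVD+polynomial stage is fitted post hoc on the trained encoder's
activations, matching the "replace the last layer" construction;
training is on the 4× mirror-augmented set, component scores are
reported for original cases only.

Identifiability caveat: components are defined by variance ordering,
so two planted factors of *equal* strength give degenerate singular
values and rotationally mixed components — recovery tests use distinct
factor strengths, and factor–component alignment is asserted with a
one-to-one matching.

## Statistics

CCA is the SVD of the whitened cross-covariance with a ridge of
`reg`·trace/dim (default 1e-6) on each block; p-values come from
permuting one block's rows (default 1000 permutations, here 200 in the
harnesses), p = (1 + #{r_perm ≥ r_obs})/(1 + N). The permutation null
is the honest significance gauge: with 15 component scores against 8
shape features the sample canonical correlation is biased upward
(≈ 0.35–0.4 under the null at n = 300), and the permutation
distribution carries exactly that bias.

LDA risk classification uses scikit-learn's LDA inside a strict
leave-one-out loop (k-fold available as an override; "leave-one-out"
is the evaluation of record). All rates (PPV, NPV, sensitivity,
specificity) are computed from held-out predictions only, and the
reported r is the point-biserial correlation of the held-out
discriminant score with the binary label. On null data this r has a
known negative bias of order p/n (leaving a case out shifts its own
class mean away), which is why the negative-control harness uses 100
cases per group — large enough that the bias (|r| ≈ 0.05–0.07) is well
inside the null criterion. UMAP embeddings are visualization only;
no quantitative claim depends on their geometry.

## Experiment harnesses

All four harnesses share the `ExperimentConfig` seed ladder
(`numpy.random.SeedSequence` children, all < 2³¹), emit a config hash,
and are bit-reproducible from an equal config. Problem sizes are the
package's defaults for desk-scale work: ~300 vertices per bone, 15–25
training limbs, cohorts of 40–300, 32 px wear images — each harness
runs in seconds to about a minute on one CPU.

1. **Synthetic validation**: fresh draws from the healthy articulated
   model (new loading vectors, *not* training shapes — so the identity
   limit is meaningful) are degraded (3 mm osteophytes on 5% of
   knee-margin vertices, 1.5 mm narrowing, misalignment uniform ±5°)
   and reconstructed; reports per-bone RMS after rigid alignment
   (shape error) and the coronal HKA error (pose error) against
   ground truth.
2. **Wear–geometry study**: medial-wear loading is generated with a
   chosen correlation (default 0.5) to the standardized HKA angle and
   carved into the femoral cap (up to 3.5 mm); the full chain
   (arthritis → twin → JSW map → PPAE → CCA of all decorrelated
   components against the twin's first 8 Mahalanobis loadings) must
   recover it. The wear-study cohort standardizes limb size and tibial
   slope: both shape the baseline joint-space map, and leaving them
   free plants additional genuine geometry↔wear associations that
   confound measurement of the planted one.
3. **Risk benchmark**: an at-risk population shifts HKA towards varus
   and increases tibial slope (total 2 SD split over the two features);
   its arthritic limbs go through the twin pipeline, controls are
   projected directly, and LOOCV-LDA on Mahalanobis loadings yields the
   classifier report (per-sex stratification available).
4. **Negative control**: healthy limbs deformed *randomly*
   (independently of morphotype) and reconstructed, classified against
   untouched controls — the pipeline itself must carry no phenotype
   signal. This null is asserted before the risk benchmark in the test
   suite.

## What passing tests do and do not show

The synthetic cohort gives the pipeline exactly the properties the
analysis assumes: dense correspondence, alignment encoded in bone
geometry, wear that is a smooth mixture of a small number of spatial
patterns, and deformities that are outliers with respect to a healthy
model. Real CT data violates each of these to some degree —
segmentation noise, correspondence error from non-rigid registration,
cartilage (not bone) as the eroding tissue, osteophytes that blend into
the articular margin, and morphotype–disease correlations that are not
planted but confounded. Passing tests therefore demonstrate that the
*method* is implemented correctly and recovers known structure under
its stated assumptions; they do not certify clinical accuracy, and the
reconstruction errors reported here (≈ 0.1 mm at desk scale with
model-representable inputs) are necessarily optimistic relative to any
real cohort.

## Known limitations

* Limb geometry is schematic; torsion/slope measurements rely on
  stored anatomical axes rather than being re-derived from the surface.
* The wear carving deforms the femoral bone surface (the generator has
  no cartilage layer), so deep wear slightly imprints on the twin fit;
  the robust outlier rule suppresses most but not all of it.
* The assembly regression is linear in the loadings; with very few
  training limbs it interpolates and its extrapolation beyond ±3 SD
  samples is untested.
* The autoencoder is fully connected, as specified — no convolutional
  inductive bias — so image sizes beyond ~64 px waste parameters.
* Component identifiability requires separated variances (see above);
  equal-strength wear factors are reported as mixed components.
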