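# kneewear

Analysis pipeline for studying **cartilage wear patterns in knee
osteoarthritis (OA) and their relation to native lower-limb
morphology**, built around virtual-healthy-twin reconstruction and a
principal polynomial autoencoder, and driven end-to-end by a synthetic
cohort generator with known ground truth.

## The scientific problem

End-stage knee OA erodes the femorotibial joint space, but where the
cartilage is lost — medial, lateral, anteromedial, posteromedial, or at
the tibial spines — varies between patients and is thought to reflect
each limb's *pre-disease* geometry: varus (bow-legged) alignment loads
the medial compartment, valgus the lateral one, a steep tibial slope
shifts contact posteriorly. Testing this requires two things that are
hard to get from an arthritic knee: an anatomically standardized map of
the wear itself, and the limb's geometry *before* disease deformed it.

The pipeline answers both:

1. **Virtual healthy twin.** A statistical shape model (SSM) built from
   healthy limbs — mean shape `x̄` plus orthonormal modes `Φ` with mode
   variances `λᵢ`, so a shape is `x ≈ x̄ + Φb` — is fitted to each
   arthritic femur and tibia by interleaved closest-point
   correspondence / least-squares updates, excluding correspondence
   pairs whose residual exceeds mean + 2 SD (osteophytes and eroded
   regions). The fitted bones are then reassembled through a healthy
   *articulated* whole-limb model so the twin's relative bone pose —
   and hence its hip–knee–ankle (HKA) alignment — comes from the
   healthy population's pose/shape covariance, not from the diseased
   joint.
2. **Anatomically standardized wear maps.** Joint space width (JSW) is
   measured per corresponded femoral vertex as the closest-point
   distance to the tibia, normalized and inverted so 1 = complete
   erosion (JSW 0 mm), the articular region is flattened onto the unit
   square by a discrete harmonic map, and the values are
   thin-plate-spline rasterized to an isotropic pixel image.
3. **Principal polynomial autoencoder (PPAE).** A two-layer
   fully-connected autoencoder compresses the wear images into a
   15-dimensional latent space; its bottleneck is replaced by a
   low-rank SVD of the latent activations followed by *sequential
   polynomial regression* — each component's scores are residualized on
   polynomial functions of the previous components — yielding ordered,
   exactly decorrelated non-linear wear components with variance
   attribution. Left-right and antero-posterior mirroring quadruples
   the training data first.
4. **Morphometric statistics.** Canonical correlation analysis (CCA,
   permutation-tested) links wear components to twin shape loadings;
   a linear discriminant (LDA) on Mahalanobis-normalized loadings
   (`bᵢ/√λᵢ`), evaluated with leave-one-out cross-validation,
   quantifies the morphology-based OA risk as PPV/NPV,
   sensitivity/specificity and the point-biserial correlation of the
   held-out discriminant score with the group label; UMAP gives 2D
   views of the shape spaces.

Because clinical CT cohorts of this kind are not publicly available,
the package ships a first-class **synthetic cohort generator**:
parametric femur+tibia meshes in dense template correspondence with
controllable HKA angle, torsions, tibial slope, bowing and size;
arthritic degradation (marginal osteophytes, joint-space narrowing,
patterned wear carving, coronal misalignment) with the exact applied
deformation recorded; wear fields that are known mixtures of five
spatial patterns; and a cohort roster reproducing the study
population's inclusion/exclusion accounting. Every experiment therefore
has planted ground truth to score against.

## Worked example

```python
import numpy as np
from kneewear import (ExperimentConfig, run_synthetic_validation,
                      generate_roster, apply_exclusions)

# cohort accounting
roster = generate_roster()
included, counts = apply_exclusions(roster)
print("cohort:", len(roster), "included:", len(included),
      "| female excluded:", counts["female"]["excluded"],
      "male excluded:", counts["male"]["excluded"])

# twin-reconstruction validation on deformed synthetic limbs
cfg = ExperimentConfig(seed=1, n_cases=20, n_train=20, resolution=300)
rep = run_synthetic_validation(cfg)
print(f"twin reconstruction: RMS {rep.rms_mm:.3f} mm "
      f"(femur {rep.rms_femur_mm:.3f}, tibia {rep.rms_tibia_mm:.3f}), "
      f"coronal error {rep.coronal_abs_err_deg:.3f} deg")

# wear-pattern decomposition on a synthetic wear cohort
from kneewear import synthetic_cohort as sc, ppae
from kneewear.jsw_mapping import WearImage
uv = sc.default_uv_grid(16)
fields = sc.generate_wear_cohort(300, seed=0, uv=uv)
imgs = [WearImage(pixels=f.field.reshape(16, 16),
                  mask=np.ones((16, 16), bool)) for f in fields]
model = ppae.train(ppae.augment(imgs), latent_dim=8, hidden=64,
                   epochs=150, seed=0)
comps, model = ppae.fit_polynomial_bottleneck(model, imgs, degree=2)
print("component variance fractions:", np.round(comps.variance_fraction[:4], 3),
      "cumulative(4):", round(float(comps.cumulative_fraction[3]), 3))
```

prints

```
cohort: 933 included: 798 | female excluded: 61 male excluded: 74
twin reconstruction: RMS 0.096 mm (femur 0.093, tibia 0.098), coronal error 0.012 deg
component variance fractions: [0.345 0.274 0.096 0.043] cumulative(4): 0.757
```

Reading: of the 933-case roster, 798 pass the inclusion criteria (no
hip/knee prosthesis, no osteosynthesis, no segmentation error). Over 20
synthetic cases degraded with osteophytes, 1.5 mm narrowing and up to
±5° misalignment, the reconstructed twins deviate from the true
pre-disease geometry by under 0.1 mm RMS and ~0.01° in the coronal
plane — the imposed misalignment is removed, not reproduced. The PPAE
decomposes the wear cohort into decorrelated components; the first four
carry ~76% of the latent variance here, and walking each component
(`ppae.component_wear_interpretation`) shows which wear pattern —
medial, lateral, antero/posteromedial, spine — it encodes.

A thin CLI wraps the generators and harnesses:

```bash
kneewear synth roster --out roster.csv
kneewear synth limbs --n 5 --seed 0 --out meshes/
kneewear experiment validate --seed 1 --n-cases 50 --out report.json
kneewear experiment risk --seed 1 --out risk.json
```

## Layout

```
src/kneewear/
  synthetic_cohort.py   parametric limbs, arthritis, wear fields, roster
  ssm_twin.py           shape models, robust fitting, twin reassembly
  jsw_mapping.py        JSW maps, harmonic flattening, rasterization
  ppae.py               principal polynomial autoencoder
  morpho_stats.py       CCA, LOOCV-LDA risk report, UMAP embedding
  experiments.py        the four end-to-end study harnesses
  cli.py                `kneewear` command-line front end
docs/methods.md         model assumptions, parameters, design notes
tests/                  pytest suite incl. acceptance checks
```
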