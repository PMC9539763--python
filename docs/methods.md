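# Methods

## Scope and data model

The package translates low-field MR volumes of the male pelvis into
synthetic CT (sCT) and evaluates the result with the image-quality and
dosimetric machinery standard in MRI-guided adaptive radiotherapy. Its
universal currency is the `Volume`: a 3D scalar grid plus per-axis voxel
spacing (mm), an origin, and a modality tag (MR, CT, SCT, DOSE, MASK). The
fixed axis convention is axis 0 = left–right (sagittal slicing), axis 1 =
anterior–posterior (coronal), axis 2 = superior–inferior (axial). Physical
space is corner-anchored with half-open voxel extents: voxel `i`'s center
sits at `origin + (i + 0.5)·spacing`. I/O goes through nibabel (NIfTI-1)
and SimpleITK (NRRD); resampling is linear for images and dose, nearest for
masks, so masks stay binary. The clinical-scale working grid is 256³ at
1.5×1.5×1 mm³; the desk-scale default used throughout tests and examples is
48–64³ at 6×6×4 mm³, chosen so the whole pipeline — training included —
runs in minutes on one CPU core.

## Preprocessing

* **Exterior masking.** Outside the body contour, CT/sCT are forced to
  −1000 HU and MR to 0. The operation is idempotent and is re-applied to
  every synthesis output.
* **CT normalization.** HU in [−1000, 3095] map affinely onto [−1, 1] with
  both endpoints pinned: `x = (HU + 1000)/2047.5 − 1`. The map is strictly
  increasing and exactly invertible; `denormalize_ct` is its inverse and is
  used to emit sCT in HU.
* **MR normalization.** MR units are scanner-arbitrary, so intensities are
  z-scored. The mean and SD are computed only over voxels with intensity ≥
  40 (on TrueFISP images this threshold separates air/gas, which carry no
  signal, from tissue); the z-score is divided by 3 and clipped, so ±3σ maps
  to ±1 and air saturates at −1. After normalization the exterior is forced
  to exactly −1 in both modalities — this makes the background value exact
  on any input, which the trainer's empty-plane detection relies on.
* **Bias-field correction.** MR intensity non-uniformity is modeled as a
  smooth multiplicative field. The built-in correction is homomorphic:
  Gaussian smoothing of the log-intensities restricted to the body
  (normalized convolution), subtraction of the in-body mean so the field is
  pure shape, division, and rescaling to preserve the in-body mean
  intensity. The smoothing scale (default σ = 40 mm) must sit well above
  anatomical detail. This is a deliberately simple correction; the
  parameters of the N4 algorithm a clinical workflow would use (B-spline
  order 3, grid (1,1,1), shrink factor 4, 50/40/30 iterations, convergence
  1e-4) are recorded in `preprocess.N4_REFERENCE_SETTINGS` so an external N4
  implementation can be slotted in with the documented configuration.
  The tissue threshold (40) is applied to bias-corrected intensities, since
  correction precedes normalization in the pipeline.

## Networks and objective

The generator is a U-Net: `depth` stride-2 3×3 convolutions with leaky-ReLU
(0.2) halve the plane per level while channel widths double from
`base_channels`; the decoder mirrors them with nearest-neighbour ×2
upsampling, concatenating the matching encoder features; a final tanh
bounds the output to [−1, 1]. The discriminator is conditional and
patch-wise: the MR and CT planes are stacked as two channels and reduced by
four stride-2 convolutions to a 2D score map — 16×16 for 256² inputs, 4×4
at the 64² desk scale — so each score judges a local patch rather than the
whole image. Both networks are implemented in NumPy (im2col convolutions
with explicit backward passes, weights initialized N(0, 0.02)); there is no
batch/instance normalization, which these small desk-scale widths (depth 3,
16 base channels) do not need for stable training. Full-scale
configurations (depth 6+, 64 base channels) are expressible through the
same specs.

The generator objective is `L_T = L_cGAN + λ₁ L_L1 + λ₂ L_MI` with λ₁ = 100
and λ₂ = 5.

* `L_L1` is the plain mean absolute voxel error between the real and
  generated CT planes.
* `L_MI = 1 − nMI`, with `nMI = I(a,b)/√(H(a)H(b))` computed from a 64-bin
  joint histogram on [−1, 1]²; this normalization is 1 for identical images
  and ~0 for independent ones, and the square-root form is the unique
  common choice hitting exactly 1 at identity. Degenerate inputs (zero
  marginal entropy, i.e. constant images) return 1 when equal, else 0. For
  gradient flow the training path uses linear (hat-kernel) soft binning of
  the generated plane with an analytic gradient; the hard-histogram value
  is the reference the tests check, and the soft value converges to it as
  bins grow. The MI term exists because clinical MR/CT pairs are only
  approximately registered: it rewards intensity-distribution dependence
  without penalizing small spatial misalignment the way L1 does.
* Adversarial losses are least-squares with the standard label convention:
  the discriminator drives real-pair scores to 1 and generated-pair scores
  to 0, and the generator drives its scores to 1. Patch score maps are
  averaged, not summed, so loss magnitudes are independent of patch count.

## Training loop

Optimization is Adam with momentum parameters (0.5, 0.999), initial
learning rates 2×10⁻⁴ (generator) and 5×10⁻⁵ (discriminator), both decayed
multiplicatively by 1% per epoch (`lr·0.99^epoch` — the multiplicative
reading never reaches zero, unlike a linear −1%-of-initial schedule, which
would cross zero at epoch 100); the reference schedule is 100 epochs at
full scale, and the desk-scale smoke runs use 2–12.

Each iteration draws one axial, one sagittal and one coronal plane pair
from one case, uniformly from that orientation's not-yet-used slice
indices; indices are consumed on draw, so no slice repeats within an epoch
for a given case and orientation, and an epoch caps at
`slices_per_volume × n_cases` iterations (`slices_per_volume` is the
smallest grid side, so every orientation can always supply a fresh slice).
If *any* drawn plane is pure background (every voxel −1), the whole batch
is disregarded — it consumes its slice indices but no optimizer step. The
three planes of a batch contribute mean gradients to a single generator
step and a single discriminator step. Discriminator updates draw the
generated plane through a history buffer (capacity 50, swap probability
0.5): below capacity the fresh plane is stored and used; at capacity a
random stored plane replaces it with probability ½ — damping oscillation by
letting the discriminator also see older generator outputs. The entire
loop, including weight initialization, is a pure function of
`(cases, TrainConfig)`; two runs with the same seed produce bit-identical
loss histories and weights.

## Inference and fusion

A trained generator translates 2D planes, so a 3D MR volume is sliced along
each orientation's axis, translated slice by slice, restacked, and
denormalized to HU — three volumes sCT_ax, sCT_sag, sCT_cor. The final
sCT_ave is their voxelwise arithmetic mean (an equal-weight mean, since the
CT map is affine, averaging in HU and averaging normalized values are
equivalent — asserted by test). Averaging three independently sliced
predictions suppresses the across-slice discontinuities any single 2D
orientation produces, and its MAE against any reference is bounded above by
the mean of the three single-orientation MAEs (triangle inequality). The
full chain re-applies the exterior convention, so every output is −1000 HU
outside the body and all HU lie in [−1000, 3095].

## Image-quality metrics

MAE (`mean |sCT − CT|`), ME (`mean (sCT − CT)`; positive = sCT too dense),
and PSNR (`10·log10(MAX_CT²/MSE)`, MAX_CT the maximum reference-CT value,
with an unbounded sentinel when MSE = 0) are evaluated over the voxels
inside the body contour; MAE/ME are additionally reported per tissue
segment. Segments come from HU thresholds on the *reference* CT only: air
< −200 HU, bone > 200 HU, soft tissue the inclusive residual [−200, 200];
no morphological post-processing, so the three segments exactly partition
the body and whole-body MAE is their count-weighted mean. SSIM is a single
global statistic over the whole grid — `(2μ₁μ₂+c₁)(2σ₁₂+c₂) /
((μ₁²+μ₂²+c₁)(σ₁²+σ₂²+c₂))` with c₁ = (0.01·4095)², c₂ = (0.03·4095)² —
not a windowed mean; the conventional sliding-window variant is available
behind `ssim_global(..., windowed=True)` for comparison with other
software.

## Dosimetry

DVHs are exact cumulative curves built from the sorted in-structure voxel
doses (no histogram binning); Dx% — the minimum dose to the hottest x% of
the structure — is the (1 − x/100) quantile with linear interpolation
between order statistics, making every Dx% exactly linear under dose
scaling. Dose-difference tables report evaluated − reference per metric in
Gy and as % of the prescription (default 36.25 Gy, the 5-fraction SBRT
prostate schedule).

The gamma index uses global normalization: ΔD is `dose_percent` of the
*maximum reference dose*, and the ROI keeps reference voxels above 10% of
that maximum. For each ROI voxel the implementation minimizes
`(Δd/ΔD)² + (|r|/dta)²` over nearby points of the compared distribution
with trilinear sub-voxel interpolation, in two stages: a coarse lattice
(dta/2 steps, radius 2·dta) bounds gamma from above everywhere; voxels
still failing are re-searched on a fine lattice (dta/10 steps) out to one
DTA inclusive — beyond that the spatial term alone exceeds 1, so no farther
point can flip a failure; at exactly one DTA it can (when the local dose
difference is zero), so the boundary is kept. Against an exhaustive 0.1 mm
search the two-stage result is exact whenever the fine step divides the
oracle step, which the tests exploit. Pass rate is the percentage of ROI
voxels with γ ≤ 1; loosening both criteria can only raise it.

## The phantom

The paired-case generator emulates the features the pipeline depends on: a
CT in [−1000, 3095] HU whose tissue classes respect the segmentation
thresholds (air −1000, gas −800, fat −90, muscle 45, bladder 15, prostate
40, bone 700 HU); an MR with arbitrary positive units and TrueFISP-like
contrast ordering (bladder brightest ≈ 800, fat 450 > muscle 300, bone and
gas near zero — below the air threshold, reproducing the air/bone ambiguity
that makes MR→CT translation hard); a smooth multiplicative bias field
(exponential of a seeded low-order polynomial, amplitude-limited to ±20% by
default); Gaussian CT noise (20 HU), Rician MR noise (magnitude of a
complex Gaussian, SD 15); partial-volume smoothing at class boundaries; a
gas pocket in the rectum (the main source of air-segment error in clinical
pelvis data); and exact exterior conventions. Geometry is a parametric
pelvis: elliptical body with fat rim, bone ring plus femoral-head spheres,
bladder, rectal tube, prostate/PTV with a thin urethra. Because CT is a
monotone lookup of the tissue class up to noise, a learnable MR→CT mapping
exists by construction.

The analytic dose is a Gaussian falloff (SD 40 mm) normalized to the
prescription at the PTV centroid voxel — monotone along every ray, which
the DVH and gamma tests exploit; `perturb_dose` produces scaled/shifted
copies for controlled gamma comparisons.

**What the phantom does not capture:** realistic anatomy and inter-patient
variability, MR artifacts beyond bias and Rician noise, imperfect MR/CT
registration (the pairs are perfectly aligned, so the MI term's
misalignment robustness is exercised only structurally), and real dose
physics (no beams, no electron-return effect). Passing tests therefore
demonstrate the correctness and contracts of the pipeline — not clinical
attainability of any particular HU accuracy, which requires a patient
cohort and full-scale training.

## Problem sizes and reproducibility

Desk-scale defaults were chosen once for CPU practicality: 48³–64³ grids,
depth-3/16-channel networks, cohorts of 2–8 cases, 1–12 epochs. The
acceptance script (`scripts/acceptance.py`) trains 12 epochs on eight 48³
cases and evaluates two held-out cases; its dose comparison perturbs the
analytic plan (0.5% scale + 0.05 Gy noise) as a stand-in for a dose engine,
which is out of scope. Every random draw in the package flows through
`numpy.random.default_rng` seeded from explicit configuration, and all
reports serialize deterministically, so identical seeds give byte-identical
outputs at any scale.

## Known limitations

* The bias-field correction is homomorphic smoothing, not N4; it removes
  large-scale multiplicative fields well but can slightly flatten genuine
  low-frequency anatomy contrast.
* The global-statistic SSIM is systematically higher than windowed SSIM on
  structured errors; use the windowed flag when comparing against tools
  that window.
* Gamma search resolution is dta/10; gamma values (not pass/fail at the
  tested resolutions) carry that quantization.
* NumPy networks are CPU-bound and desk-scale; the architecture specs scale
  up, but full 256³ training is impractical without an accelerator-backed
  reimplementation of the layer primitives.
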