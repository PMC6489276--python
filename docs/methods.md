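# Methods

## The measurement

Radiotherapy of thoracic tumors injures the surrounding lung: early
radiation pneumonitis and late fibrosis both show up on CT as a local
increase in tissue density. `lungdelta` quantifies this objectively by
comparing follow-up CT scans against the treatment-planning CT, voxel by
voxel, inside the lung parenchyma:

1. each follow-up scan is **deformably registered** into the planning frame
   (the planning CT is the frame that carries the dose grid and the structure
   sets, so it is always the follow-up that gets deformed);
2. the **analyzed volume** is built on the planning CT: lung minus tumor and
   minus every structure denser than aerated parenchyma (vessels,
   atelectasis), each removed with a dilated safety margin;
3. inside that volume, **ΔHU = follow-up − planning** is computed per voxel
   and paired with the planned dose D at the same voxel;
4. the pairs are aggregated in half-open **5-Gy dose strata** (mean with a
   normal-approximation 95% CI), rank-correlated (**Spearman**, average
   ranks with tie correction), and fit with a **zero-intercept linear
   regression**

       ΔHU = b·D,     b̂ = Σ dᵢyᵢ / Σ dᵢ²   [HU/Gy],

   per patient and pooled over the cohort; unpaired **Welch t-tests**
   compare timepoints and tumor entities.

The zero intercept encodes the physical prior that unirradiated parenchyma
has no dose-driven density change; the per-patient slope b is the natural
effect size and is known to vary strongly between individuals.

## Synthetic phantom cohort

No public dataset accompanies the kind of study this pipeline targets, so
the package ships a first-class generator whose phantoms exercise every
stage with known ground truth:

* **Planning CT** — exterior air (−1000 HU), a soft-tissue body ellipsoid
  (≈20 HU), two aerated lung ellipsoids (base −820 HU) carrying smooth
  Gaussian-correlated parenchymal texture (sd 45 HU, correlation ≈9 mm,
  clipped to ±150 HU so every parenchyma voxel stays below −500 HU), a
  dense spherical tumor (30 HU, radius 11 mm) in the right lung, and 16
  dense vascular tubes per lung (−50 HU, radii 1.5–3.5 mm) radiating from
  each hilum — roughly the vascular volume fraction of real parenchyma and,
  like real vessels, the features that anchor intensity-based registration.
  Default grid: 56×72×72 voxels at 2 mm isotropic spacing (2-mm slices being
  the acquisition the pipeline emulates).
* **Dose field** — an analytic anisotropic exponential-of-quadratic falloff
  from the tumor centre, normalized to the prescription there (74/60/66 Gy
  for NSCLC/SCLC/esophageal carcinoma; entity mix 35:11:35 by default).
  The default falloff scale of 24 mm (axial anisotropy ×1.3) puts the
  synthetic lung V20 at ≈30%, the planning-constraint level typical for such
  treatments. The field is smooth, strictly monotone along rays, and
  analytic — no treatment-planning engine is involved or intended.
* **Inter-scan deformation** — a stationary Gaussian random vector field
  (periodic smoothing, correlation ≈24 mm), rescaled so the maximum
  displacement equals the requested amplitude (default 3 mm; a Jacobian
  check rejects folding). This is a surrogate for posture/breathing
  differences, not a biomechanical model.
* **Follow-up scan** — inside lung-minus-tumor each voxel gains the expected
  response r(D) (linear by default; threshold-linear and sigmoid shapes and
  a low-dose "overinflation dip" are available to probe threshold
  hypotheses), then i.i.d. Gaussian noise (default sd 60 HU) is added, then
  the deformation is applied. Applying the response *before* the deformation
  keeps the response and the registration error separable: with an identity
  deformation the downstream statistics admit exact closed-form checks.
* **Per-patient slopes** are drawn from N(1.5, 2.0²) HU/Gy — the magnitude
  and large inter-individual spread reported for this effect — and the
  6-month response is scaled ×1.15 relative to 12 weeks, reproducing the
  larger late density change. With these defaults ≳90% of analyzed ΔHU
  values fall in [−100, 300] HU, matching the envelope such studies report.

What the phantoms do **not** emulate: real anatomy (lobes, airways,
diaphragm), spatially correlated CT noise, scanner artifacts, tumor
regression between scans, and breathing-phase differences beyond a smooth
random warp. Passing recovery tests therefore certifies the *pipeline
machinery* — registration, masking, bookkeeping, statistics — not clinical
performance on patient data.

## Registration

Backend: multi-resolution (shrink 4/2/1) **symmetric-forces demons** from
SimpleITK, 100/100/80 iterations, displacement-field Gaussian smoothing of
2.0/1.5/1.0 voxels per level, final resampling with B-spline interpolation
(sharper than linear at lung/vessel edges, which dominate the residual).

The demons forces are computed on **high-pass filtered** images (original
minus a 20-mm Gaussian blur). This matters: genuine radiation-induced
density change varies on the scale of the dose distribution, and an
intensity-based registration run on raw images will "explain away" part of
the real signal as spurious deformation (on noise-free phantoms with a known
linear response, raw-intensity demons biased the recovered slope by ≈−70%;
with the high-pass prefilter the bias is a few percent). The anatomy that
should drive alignment — texture, vessels, boundaries — lives at finer
scales and survives the filter.

Contract rather than algorithm: the backend is pluggable, and correctness is
defined by the result invariants (aligned volume on the planning grid;
metric never worsened — otherwise the rigidly resampled follow-up is
returned with a convergence flag; voxels pulled from outside the follow-up
extent marked invalid and excluded downstream). On noise-free phantoms with
4-mm deformations the default backend typically cuts the lung-masked mean
absolute HU difference by 80–90%; occasional deformation instances land a
few points below 80%, which we regard as the honest capability of a generic
intensity-based method at this voxel size. Negative-Jacobian voxels can
occur near strong edges and are reported as a warning, not silently fixed.

## Masking

The analysis mask is `lung ∖ dilate(exclusion, margin)` where `exclusion`
is tumor ∪ {lung voxels > −300 HU} ∪ any extra structures. The dilation is a
Euclidean distance threshold in physical mm (exact on anisotropic grids,
ties at the radius included). Defaults: −300 HU parenchyma threshold
(separates vessels/atelectasis from aerated lung; the threshold is
configurable because no canonical value exists) and a 6-mm margin (≈3 voxels
at 2-mm slices — a "small safety margin" against partial-volume and residual
registration error). The mask is built once on the planning CT and reused
for all timepoints: dense consolidations appearing on follow-up are the
signal, and re-masking them would erase it. A threshold-based lung
segmentation (largest interior low-HU components, exterior air removed) is
provided for when no lung contour is supplied.

## Statistics: conventions and numerical choices

* Dose bins are half-open [5k, 5k+5) Gy; the top bin is truncated at the
  cohort maximum and flagged. Bin-mean CIs use mean ± 1.96·sd/√n (bins hold
  thousands of voxels; exact t quantiles would change nothing).
* The unit of analysis is the voxel. Pooled statistics concatenate all
  voxels (so patients with more analyzed lung weigh more); a
  patient-weighted mode (equal weight per patient, averaging per-patient
  statistics) is provided and labelled, since either convention is
  defensible.
* Zero-intercept regression inference uses n−1 residual degrees of freedom;
  p-values below numerical resolution are reported as computed but should be
  read as "<0.001" — at voxel-level n, tiny p-values carry no extra meaning.
* Spearman correlation with all doses (or all deltas) identical is reported
  as *undefined* (`rho=None`), never as NaN propagating into reports.
* Group comparisons use Welch's unequal-variance t-test on per-patient mean
  ΔHU summaries; the degenerate all-constant case returns p=1 with a flag.
* No multiple-testing correction is applied; the reports state raw p-values.
* Exclusion accounting is conserved: for every scan, analyzed voxels +
  voxels invalid after registration + voxels outside the analysis mask equal
  the volume size, and the pipeline writes the ledger (`exclusions.csv`).

## Problem sizes used in the tests and the acceptance script

Unit tests run on 32×40×40 phantoms; recovery and calibration tests use the
default 56×72×72 grid (≈29 000 analyzed voxels per patient) with cohorts of
3–12 patients. The acceptance script simulates 12 patients with 3-mm
deformations and 16% six-month dropout and runs the full registration
pipeline. These sizes were chosen so the whole validation runs comfortably
on a laptop-class single core; all statistics scale trivially to larger
grids.

## Known limitations

* White voxel noise understates the spatial correlation of real CT noise;
  bin CIs on real data would be wider than the phantom suggests.
* The registration bar (≥80% MAD reduction at ≤5 mm deformations) reflects
  phantom texture contrast; performance on low-dose or ultra-low-dose CT
  will differ.
* The dose field is analytic and unimodal; real plans (multiple beams,
  heterogeneity corrections) have richer low-dose structure, which mainly
  affects how many voxels populate the low bins.
* Tumor voxels receive no modelled response and are excluded from analysis;
  tumor regression/progression between scans is not simulated at all.
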