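# Methods

## Coordinate conventions

All volumes are indexed `[x, y, z]`, assumed RAS-like: x sagittal
(left → right, left hemisphere at `x < nx/2`), y coronal (posterior →
anterior; "posterior" means *decreasing* y), z axial (inferior → superior;
slice `z = 0` is the most inferior). Indices are 0-based voxel indices;
physical spacing lives in `voxel_size` (mm). NIfTI files that are not in
this orientation are reoriented to closest-canonical on load and the
reorientation is logged.

## Phantoms

`generate_segmentation` places convex box parcels at fixed fractional
positions of the grid: cerebellum inferior-posterior (a gray shell labeled
`cerebellum_gray` around a core labeled `whole_cerebellum`; the "whole
cerebellum" *region* is their union), brainstem medial, temporal blocks
lateral-inferior with an anterior temporal pole, a medial stack holding the
six temporal meta-ROI parcels, occipital posterior, parietal/precuneus
superior-posterior, frontal anterior, plus choroid plexus, striatum and a
meninges/bone cap. The layout is deterministic and seed-independent; every
required parcel must reach 50 voxels or a sizing error names the first
parcel that does not fit (grids below 32³ always fail; comfortable sizing
starts around 48³, and all tests use the 64³ default). Geometry is
schematic: only the topology and adjacency the read rule cares about is
modeled, not anatomy — in particular the "inferior/middle temporal" boxes
sit medially, so they fall in the mesial crosshair quadrants.

The temporal quadrant labels in the segmentation are generated with the
*same* landmark rule the read module recomputes (see below), so the static
labels and the dynamic quadrant assignment agree by construction.

`generate_pet` sets every labeled voxel to 1.0 (so the cerebellar mean is
exactly 1 before noise) and paints scenario lesions at
`lesion_ratio × cerebellar mean` (default 2.0):

| scenario | lesion placement |
|---|---|
| `negative` | none |
| `typical_ad` | blobs in both posterolateral temporal and both parietal parcels; all twelve meta-ROI parcels filled |
| `occipital_predominant` | one occipital lobe (side flag, default left) |
| `lateralized` | posterolateral temporal + occipital + parietal, one side |
| `infarct_mimic` | one parietal/precuneus focus |
| `meningioma` | one frontal focus |
| `offtarget_only` | choroid plexus, striatum, brainstem filled |

Blobs are grown as 26-connected regions from the parcel centroid
(deterministic breadth-first order), default 150 voxels. Noise is additive
Gaussian (`noise_sd`, clipped at zero) on brain voxels, seeded; PET count
statistics, scatter, attenuation and point-spread are deliberately not
modeled — the read rule operates on ratios of means, for which additive
noise is an adequate stress test. Because the lesions of
`occipital_predominant`, `lateralized` and `infarct_mimic` lie wholly
outside the temporal meta-ROI, these phantoms are visual-positive but
SUVR-negative at any cutoff above baseline: the discordance mechanism the
package exists to study.

## Visual-read emulation

* **Reference**: mean PET value over the whole-cerebellum region in the
  axial slice with maximal cerebellar cross-section (ties → most inferior
  slice). This 2D convention is deliberately distinct from the SUVR
  module's 3D cerebellar-gray reference.
* **Threshold**: `threshold_factor` (default 1.65) × reference mean,
  restricted to cortical gray labels. Cerebellum, brainstem, choroid
  plexus, striatum, meninges/bone and background are excluded *before*
  clustering, so off-target uptake can be reported but never scored.
* **Clusters**: connected components (6/18/26-connectivity, default 26) of
  at least `min_cluster_voxels` voxels (default 20 — an operationalization
  of "small noncontiguous foci"; the guideline gives no number).
* **Quadrants**: the coronal crosshair is the first plane posterior to the
  posterior-most brainstem voxel (a voxel is "anterior" iff
  `y ≥ min brainstem y`); the per-hemisphere sagittal crosshair is the
  medio-lateral midpoint `(x_min + x_max + 1)//2` of the temporal pole on
  its widest axial slice (ties → most inferior). Every temporal-cortex
  voxel gets exactly one of {anterolateral, anterior-mesial,
  posterolateral, posterior-mesial}.
* **Classification**: positive iff a surviving cluster touches
  posterolateral temporal (by quadrant), occipital, or parietal/precuneus
  cortex. Asymmetry is flagged when any target region's left/right mean
  uptake log-ratio exceeds ln 1.25 (an invented, configurable threshold —
  readers report asymmetry only qualitatively). A suprathreshold cluster
  confined to frontal cortex raises a `frontal_focal_uptake` notable
  finding; mass-lesion diagnosis (meningioma, infarct) is out of scope —
  in practice it requires MR review, so phantoms carry scenario ground
  truth and the result exposes the hook.

Positivity, cluster sets and peak ratios are invariant to global intensity
rescaling, and raising the threshold factor can only remove positivity.

## SUVR quantification

Regional means are plain voxel averages per label; SUVR = mean/reference
with `cerebellum_gray` as reference (its own SUVR is set to exactly 1).
The temporal meta-ROI pools the six parcels across hemispheres weighted by
voxel count — equal to the mean over the union of meta-ROI voxels divided
by the reference mean. Bilateral volume-weighted pooling (rather than
hemisphere averaging) is a documented choice; it makes strongly lateralized
signal dilute, which is the mechanism behind borderline-negative SUVRs in
lateralized cases. Centiloid is an affine map `slope·SUVR + intercept`;
the defaults (slope 200, intercept −100) are placeholders — real use
supplies tracer-specific calibration constants. Ties at a cutoff count as
positive for above-positive markers (deterministic, documented; sources
rarely state tie handling).

## Manly mixtures and cutoffs

A component is Gaussian(μ, σ) after the exponential Manly transform
`T_λ(x) = (e^{λx} − 1)/λ` (identity at λ = 0); its measurement-scale
density is the Gaussian density at `T_λ(x)` times the Jacobian `e^{λx}`.
Each component carries its own λ, which is what log or Box-Cox transforms
of the pooled sample cannot express. Two conventions worth noting:

* **Skew sign**: because the *transformed* variable is Gaussian, λ > 0
  yields a concave inverse map and hence *negative* measurement-scale
  skewness; right-skewed biomarkers correspond to λ < 0. The synthetic
  cohort defaults use negative λ accordingly.
* **Normalization**: the density integrates to 1 minus the Gaussian mass
  outside the transform's range (`1 + λy > 0`); for all defaults this mass
  is ≲ 1e-5 and the cohort sampler rejects it. `|λx| > 700` saturates
  rather than overflows.

**EM.** Data are standardized internally (the family is closed under affine
maps, so the fit is exactly equivariant and components are back-transformed
to the measurement scale, λ_x = λ_z/s). E-step: responsibilities from the
weighted log densities. M-step: closed-form weights; per component, λ by
bounded scalar maximization of the profiled expected log-likelihood
(μ, σ closed-form given λ), bounds ±5/range on the standardized scale to
keep `e^{λx}` tame. Initialization: quantile splits of the sorted sample
(0.5, 0.35, 0.65, 0.25, 0.75 for the default 5 starts; further starts drawn
uniformly), λ = 0. Convergence at |Δ log L| < 1e-8 or 500 iterations; the
trace is monotone up to that slack. A start collapses (and is discarded)
when a component's responsibility mass drops below 2 effective points or
its variance vanishes; if all starts collapse the fit fails with
diagnostics. Components are ordered by measurement-scale median.

**Decision boundary.** The cutoff is the root of
`log(π₁f₁) − log(π₂f₂)` between the component medians: a 2001-point grid
locates the first rightward crossing where the posterior of the lower
component drops through ½, then Brent's method polishes it to ~1e-12. The
posterior at the returned cutoff is ½ to well under 1e-6.

**Known limitation — weak identification of λ.** For a minority component
that is nearly Gaussian over its span (e.g. weight 0.2, σ = 0.25 at
n = 5000), the skew is weakly identified: maximum-likelihood λ̂ varies
widely across replicate simulations (single-replicate fits can land far
from the generative value *with higher likelihood than the truth*), while
weights, locations, scales and — especially — the decision boundary are
recovered tightly. Cutoffs are therefore much more trustworthy than the
fitted skews; interpret λ̂ only with large, well-separated components.

## Synthetic cohorts

Each participant has a latent disease state (prevalence default 0.25).
Biomarkers are drawn conditionally independently given the state from
per-state Manly components specified by measurement-scale targets (mean,
SD, λ), converted to transformed-scale parameters by the delta method
(μ = T_λ(mean), σ = SD·e^{λ·mean}). Defaults approximate published
normal/impaired summaries: SUVR 1.13/1.60, Centiloid 5/85, p-tau181
38/95 pg/ml, Aβ42/Aβ40 0.085/0.051 (the ratio decreases with disease).
The visual-read status is generated with P(+|disease) = 0.85,
P(+|healthy) = 0.03, so realistic discordances occur; a lumbar-puncture
subset (default fraction 144/189) carries CSF values, others are missing
and handled by per-comparison complete-case analysis. Follow-up diagnoses
are a yearly Markov chain over {CN, UD, AD, FTD} (defaults keep CN sticky,
route UD mostly to AD, and make FTD nearly absorbing); "0.5 in memory
only"-type labels are folded into UD. What the generator does *not*
emulate: between-biomarker correlation beyond the latent state, age/sex
structure, measurement batch effects, and visual reads driven by the
actual images — so passing tests demonstrate the pipeline's logic, not
clinical performance.

## Concordance statistics

`solve_cells` reconstructs a 2×2 table from printed marginals via
`a = (row⁺ + col⁺ + n_agree − n)/2`, failing loudly when no non-negative
integer solution exists. κ is the unweighted two-category Cohen's kappa
with chance agreement from marginal products; no confidence intervals.
Trajectory rules are applied in a fixed order (FTD at the last visit →
reassigned_nonAD; baseline-CN AD later walked back → reverter; baseline-CN
ending in AD → converter; all-CN / all-AD stable; else indeterminate);
"uncertain dementia" alone never completes a conversion.

## Problem sizes

Defaults were chosen so every analysis is interactive on a laptop: 64³
phantoms, cohorts of a few hundred for the demonstration pipeline and
n = 5000 for recovery simulations (20 replicate seeds for parameter
recovery, 5 for closed-loop cutoff recovery). The acceptance script runs
the whole set in well under a minute.
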