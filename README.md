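# tauread

Tools for comparing three ways of calling a tau PET scan "positive", and for
quantifying how well they agree:

1. **Algorithmic visual read** — an emulation of the manufacturer's
   ¹⁸F-flortaucipir visual-interpretation rule on 3D volumes: a cerebellar
   reference drawn in the axial plane of maximal cerebellar cross-section, a
   threshold at **1.65 × the mean cerebellar counts**, 26-connected cluster
   detection restricted to cortical gray matter, and region logic — positive
   iff contiguous suprathreshold uptake touches **posterolateral temporal,
   occipital, or parietal/precuneus** cortex. Uptake confined to medial
   temporal, anterolateral temporal, or frontal cortex, off-target binding
   (choroid plexus, striatum, brainstem, meninges/bone), and small
   noncontiguous foci never make a scan positive. The temporal lobe is split
   into quadrants by crosshair planes placed posterior to the brainstem and at
   the medio-lateral midpoint of the temporal pole.
2. **Temporal meta-ROI SUVR** — the volume-weighted mean SUVR of the amygdala,
   entorhinal, fusiform, parahippocampal, inferior temporal, and middle
   temporal parcels against a cerebellar-gray reference, binarized at a
   configurable cutoff (default 1.32). Amyloid PET is standardized to the
   Centiloid scale by a configurable affine map (default cutoff 21.6 CL).
3. **Mixture-model biomarker cutoffs** — two-component univariate
   **Manly-Gaussian mixtures** fitted by EM, with a per-component skew
   λ (the component is Gaussian after the exponential transform
   y = (e^{λx} − 1)/λ). The positivity cutoff is the decision boundary where
   the component posterior crosses ½. Published cutoffs (SUVR 1.32,
   21.6 CL, p-tau181 58.1 pg/ml, Aβ42/Aβ40 0.0737) ship as defaults.

Agreement between modalities is summarized by 2×2 tables, percent agreement
and Cohen's κ = (p_o − p_e)/(1 − p_e); tables can be reconstructed from
printed marginals via a = (row⁺ + col⁺ + n_agree − n)/2. Longitudinal
diagnosis sequences over {CN, UD, AD, FTD} are classified into trajectory
categories (stable / converter / reverter / reassigned non-AD).

Everything runs on **synthetic data**: schematic labeled brain phantoms with
scenario-driven lesions (typical AD, occipital-predominant, lateralized,
infarct mimic, meningioma, off-target-only) and cohort tables drawn from
Manly mixtures tied to a latent disease state. No downloads are needed.

The package is aimed at methods researchers who want to study *why* visual
reads and meta-ROI SUVR disagree: the meta-ROI contains no occipital or
parietal/precuneus cortex, so occipital-predominant or infarct-driven uptake
is visually positive yet SUVR-negative — the phantoms reproduce exactly this
mechanism.

## Worked example

```sh
tauread simulate phantom --scenario occipital_predominant --out-dir phantom/
tauread suvr --pet phantom/pet.nii.gz --seg phantom/seg.nii.gz
tauread read --pet phantom/pet.nii.gz --seg phantom/seg.nii.gz
```

The SUVR report gives `"meta_roi_suvr": 1.0` and `"suvr_status": "negative"`
(the occipital lesion lies entirely outside the six meta-ROI parcels, so the
meta-ROI sits at the cerebellar baseline), while the read report returns
`"positivity": "positive"` with one 150-voxel cluster whose
`regions_touched` include `left_occipital` — a visual-positive /
SUVR-negative discordance produced mechanistically.

The full synthetic pipeline (phantoms → SUVR → visual read → mixture cutoffs
→ concordance):

```sh
tauread pipeline --seed 7 --n-cohort 400 --out report.json
```

On a 400-participant synthetic cohort this refits the four biomarker
mixtures and prints, among other things,

```json
"fitted_cutoffs": {"suvr_cutoff": 1.2946, "centiloid_cutoff": 39.67,
                   "ptau_cutoff": 71.21, "abeta_ratio_cutoff": 0.0529},
"visual_vs_suvr": {"table": {"a": 88, "b": 13, "c": 26, "d": 273, "n": 400},
                   "percent_agreement": 90.25, "kappa": 0.7523}
```

i.e. the refitted SUVR cutoff (1.29) lands near the generative boundary
between the healthy (~1.13) and disease (~1.60) components, and visual read
vs SUVR status agree on 361/400 of the synthetic participants (κ = 0.75 —
lower than in a real elderly cohort because the simulated visual read is
deliberately noisy). The report is byte-identical across runs for a fixed
seed.

## Layout

- `tauread.synthetic` — phantom segmentations, scenario PET, cohort simulation
- `tauread.suvr` — regional means, meta-ROI SUVR, Centiloid, binarization
- `tauread.visual_read` — reference plane, threshold mask, clusters, quadrants, read logic
- `tauread.mixture` — Manly transform/density, EM, decision boundaries, cutoffs
- `tauread.concordance` — 2×2 tables, κ, discordance patterns, trajectories
- `tauread.io` / `tauread.cli` — NIfTI + sidecar JSON, CSV, YAML, CLI

See `docs/methods.md` for the models, conventions, and known limitations.
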