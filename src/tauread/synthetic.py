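"""Synthetic phantoms and cohorts for the tau-status comparison pipeline.

Two generators live here:

* **Phantoms** — a schematic, fully deterministic brain parcellation
  (:func:`generate_segmentation`) on which scenario-driven PET uptake is
  painted (:func:`generate_pet`).  Parcels are convex boxes placed in
  anatomically plausible relative positions (cerebellum inferior-posterior,
  brainstem medial, temporal lobes lateral-inferior, occipital posterior,
  frontal anterior); only the topology and adjacency relevant to the read rule
  are modeled, not anatomy.  Scenarios encode the qualitative case types the
  pipeline must discriminate: typical AD, occipital-predominant uptake,
  lateralized uptake, a parietal/precuneus infarct mimic, a frontal
  meningioma-like focus, and pure off-target binding.

* **Cohorts** — per-participant biomarker tables drawn from two-component
  skewed (Manly-Gaussian) mixtures tied to a latent disease state, plus
  visual-read statuses, a lumbar-puncture subset with CSF values, and yearly
  follow-up diagnosis sequences generated by a Markov transition matrix over
  {CN, UD, AD, FTD}.

All randomness flows from the integer ``seed`` in the parameter objects; the
segmentation itself is seed-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .mixture import manly_inverse, manly_transform
from .visual_read import quadrant_split_planes
from .volumes import LabelVolume, PetVolume

SCENARIOS = (
    "negative",
    "typical_ad",
    "occipital_predominant",
    "lateralized",
    "infarct_mimic",
    "meningioma",
    "offtarget_only",
)

#: Diagnosis states for the follow-up chains, in transition-matrix row order.
DIAGNOSIS_STATES = ("CN", "UD", "AD", "FTD")

#: Biomarker columns of a cohort table (measurement scale / units as printed
#: in cohort characteristic tables: SUVR and the CSF ratio dimensionless,
#: Centiloid on the amyloid-PET standard scale, p-tau181 in pg/ml).
BIOMARKERS = ("suvr", "centiloid", "ptau181", "abeta42_40_ratio")

COHORT_COLUMNS = (
    "participant_id",
    "disease_state",
    "visual_read",
    "suvr",
    "centiloid",
    "ptau181",
    "abeta42_40_ratio",
    "baseline_dx",
)


class PhantomSizingError(ValueError):
    """The grid is too small to place a parcel of the required minimum size."""


class LesionPlacementError(ValueError):
    """The requested lesion does not fit inside its target parcel."""


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    scenario: str = "negative"
    lesion_ratio: float = 2.0
    lesion_voxels: int = 150
    noise_sd: float = 0.0
    seed: int = 0
    lesion_side: str = "left"  # side used by lateralized-type scenarios

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.lesion_ratio <= 0:
            raise ValueError("lesion_ratio must be positive")
        if self.lesion_voxels < 1:
            raise ValueError("lesion_voxels must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.lesion_side not in ("left", "right"):
            raise ValueError("lesion_side must be 'left' or 'right'")


# ---------------------------------------------------------------------------
# Segmentation phantom
# ---------------------------------------------------------------------------

_MIN_PARCEL_VOXELS = 50

#: Base parcel names replicated per hemisphere (prefixed left_/right_).
HEMISPHERE_PARCELS = (
    "temporal_pole",
    "anterolateral_temporal",
    "anterior_mesial_temporal",
    "posterolateral_temporal",
    "posterior_mesial_temporal",
    "amygdala",
    "entorhinal",
    "parahippocampal",
    "fusiform",
    "inferior_temporal",
    "middle_temporal",
    "occipital",
    "parietal_precuneus",
    "frontal",
)

MIDLINE_PARCELS = (
    "cerebellum_gray",
    "whole_cerebellum",
    "brainstem",
    "choroid_plexus",
    "striatum",
    "meninges_bone",
)


def required_labels() -> list[str]:
    names = list(MIDLINE_PARCELS)
    for side in ("left", "right"):
        names.extend(f"{side}_{p}" for p in HEMISPHERE_PARCELS)
    return names


def _frac_slices(shape, fx, fy, fz):
    nx, ny, nz = shape
    return tuple(
        slice(int(round(lo * n)), int(round(hi * n)))
        for (lo, hi), n in zip((fx, fy, fz), (nx, ny, nz))
    )


# Fractional bounding boxes (half-open) per midline parcel and per-hemisphere
# template; hemisphere x-bounds are mirrored via x -> 1 - x for the right side.
_MIDLINE_BOXES = {
    "cerebellum_gray": ((0.30, 0.70), (0.10, 0.35), (0.05, 0.25)),  # shell; core carved out below
    "whole_cerebellum": ((0.38, 0.62), (0.16, 0.29), (0.09, 0.21)),  # central core
    "brainstem": ((0.44, 0.56), (0.35, 0.55), (0.10, 0.45)),
    "striatum": ((0.30, 0.45), (0.55, 0.68), (0.45, 0.60)),
    "choroid_plexus": ((0.52, 0.68), (0.45, 0.60), (0.50, 0.62)),
    "meninges_bone": ((0.20, 0.80), (0.20, 0.80), (0.94, 1.00)),
}

# Left-hemisphere fractions (x mirrored for the right hemisphere).
_TEMPORAL_BLOCK = ((0.05, 0.30), (0.18, 0.60), (0.28, 0.50))  # quadrant-labeled cortex
_TEMPORAL_POLE = ((0.05, 0.30), (0.60, 0.68), (0.28, 0.50))
_MEDIAL_STACK_X = (0.30, 0.42)
_MEDIAL_STACK_Y = (0.18, 0.68)
_MEDIAL_STACK_Z = (0.28, 0.42)
_MEDIAL_STACK_ORDER = ("amygdala", "entorhinal", "parahippocampal", "fusiform", "inferior_temporal", "middle_temporal")
_LEFT_BOXES = {
    "occipital": ((0.08, 0.46), (0.02, 0.16), (0.30, 0.62)),
    "parietal_precuneus": ((0.10, 0.46), (0.10, 0.40), (0.65, 0.90)),
    "frontal": ((0.10, 0.46), (0.70, 0.95), (0.35, 0.85)),
}


def _mirror_x(fx: tuple[float, float]) -> tuple[float, float]:
    return (1.0 - fx[1], 1.0 - fx[0])


def generate_segmentation(spec: PhantomSpec) -> LabelVolume:
    """Deterministic schematic parcellation for the given grid.

    Raises :class:`PhantomSizingError` (naming the first unplaceable parcel)
    when the grid cannot host every required parcel with at least
    ``50`` voxels; grids below 32 voxels per axis always fail.
    """
    shape = tuple(spec.grid_shape)
    if min(shape) < 32:
        raise PhantomSizingError(
            f"grid {shape} too small to place parcel 'cerebellum_gray' (all axes must be >= 32)"
        )
    data = np.zeros(shape, dtype=np.int16)
    label_map: dict[str, int] = {"background": 0}
    next_id = 1

    def paint(name: str, mask: np.ndarray) -> None:
        nonlocal next_id
        target = mask & (data == 0)
        data[target] = next_id
        label_map[name] = next_id
        next_id += 1

    def box_mask(fx, fy, fz) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[_frac_slices(shape, fx, fy, fz)] = True
        return m

    # Cerebellum: core first so the outer box becomes a gray shell around it.
    paint("whole_cerebellum", box_mask(*_MIDLINE_BOXES["whole_cerebellum"]))
    paint("cerebellum_gray", box_mask(*_MIDLINE_BOXES["cerebellum_gray"]))
    for name in ("brainstem", "striatum", "choroid_plexus", "meninges_bone"):
        paint(name, box_mask(*_MIDLINE_BOXES[name]))

    pole_masks = {}
    block_masks = {}
    for side in ("left", "right"):
        mirror = side == "right"

        def hemi(fx, fy, fz):
            return box_mask(_mirror_x(fx) if mirror else fx, fy, fz)

        pole_masks[side] = hemi(*_TEMPORAL_POLE)
        paint(f"{side}_temporal_pole", pole_masks[side])
        block_masks[side] = hemi(*_TEMPORAL_BLOCK)
        # Medial temporal / meta-ROI parcels: six slabs stacked front-to-back.
        edges = np.linspace(_MEDIAL_STACK_Y[0], _MEDIAL_STACK_Y[1], len(_MEDIAL_STACK_ORDER) + 1)
        sx = _mirror_x(_MEDIAL_STACK_X) if mirror else _MEDIAL_STACK_X
        for name, lo, hi in zip(_MEDIAL_STACK_ORDER, edges[:-1], edges[1:]):
            paint(f"{side}_{name}", box_mask(sx, (lo, hi), _MEDIAL_STACK_Z))
        for name, fracs in _LEFT_BOXES.items():
            paint(f"{side}_{name}", hemi(*fracs))

    # Temporal quadrants: label the remaining temporal block with the same
    # crosshair rule the read module recomputes from landmarks.
    y_split, x_mid = quadrant_split_planes(data == label_map["brainstem"], pole_masks)
    xg = np.arange(shape[0])[:, None, None]
    yg = np.arange(shape[1])[None, :, None]
    anterior = np.broadcast_to(yg >= y_split, shape)
    for side in ("left", "right"):
        if side == "left":
            mesial = np.broadcast_to(xg >= x_mid[side], shape)
        else:
            mesial = np.broadcast_to(xg < x_mid[side], shape)
        block = block_masks[side]
        paint(f"{side}_anterolateral_temporal", block & anterior & ~mesial)
        paint(f"{side}_anterior_mesial_temporal", block & anterior & mesial)
        paint(f"{side}_posterolateral_temporal", block & ~anterior & ~mesial)
        paint(f"{side}_posterior_mesial_temporal", block & ~anterior & mesial)

    vol = LabelVolume(data=data, voxel_size=tuple(spec.voxel_size), label_map=label_map)
    for name in required_labels():
        if vol.count(name) < _MIN_PARCEL_VOXELS:
            raise PhantomSizingError(
                f"grid {shape} too small to place parcel {name!r} with >= {_MIN_PARCEL_VOXELS} voxels"
            )
    return vol


# ---------------------------------------------------------------------------
# PET phantom
# ---------------------------------------------------------------------------

_NEIGHBORS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _grow_blob(region: np.ndarray, n_voxels: int, label: str) -> np.ndarray:
    """Deterministic 26-connected blob of ``n_voxels`` grown from the parcel center."""
    coords = np.argwhere(region)
    if coords.shape[0] < n_voxels:
        raise LesionPlacementError(
            f"lesion of {n_voxels} voxels exceeds parcel {label!r} size {coords.shape[0]}"
        )
    center = coords.mean(axis=0)
    start = tuple(coords[np.argmin(((coords - center) ** 2).sum(axis=1))])
    shape = region.shape
    chosen = np.zeros(shape, dtype=bool)
    chosen[start] = True
    frontier = [start]
    count = 1
    while count < n_voxels:
        nxt = set()
        for vox in frontier:
            for d in _NEIGHBORS_26:
                nb = (vox[0] + d[0], vox[1] + d[1], vox[2] + d[2])
                if all(0 <= nb[i] < shape[i] for i in range(3)) and region[nb] and not chosen[nb]:
                    nxt.add(nb)
        if not nxt:  # region exhausted along this front (cannot happen if sized above)
            raise LesionPlacementError(f"could not grow contiguous lesion inside {label!r}")
        frontier = sorted(nxt)
        for nb in frontier:
            chosen[nb] = True
            count += 1
            if count >= n_voxels:
                break
    return chosen


def _scenario_sites(spec: PhantomSpec) -> tuple[list[str], list[str]]:
    """(labels that get a grown blob of lesion_voxels, labels filled entirely)."""
    side = spec.lesion_side
    other = "right" if side == "left" else "left"
    if spec.scenario == "negative":
        return [], []
    if spec.scenario == "typical_ad":
        blobs = [f"{s}_posterolateral_temporal" for s in (side, other)]
        blobs += [f"{s}_parietal_precuneus" for s in (side, other)]
        fills = [f"{s}_{p}" for s in ("left", "right") for p in _MEDIAL_STACK_ORDER]
        return blobs, fills
    if spec.scenario == "occipital_predominant":
        return [f"{side}_occipital"], []
    if spec.scenario == "lateralized":
        return [f"{side}_posterolateral_temporal", f"{side}_occipital", f"{side}_parietal_precuneus"], []
    if spec.scenario == "infarct_mimic":
        return [f"{side}_parietal_precuneus"], []
    if spec.scenario == "meningioma":
        return [f"{side}_frontal"], []
    if spec.scenario == "offtarget_only":
        return [], ["choroid_plexus", "striatum", "brainstem"]
    raise ValueError(f"unknown scenario {spec.scenario!r}")


def generate_pet(spec: PhantomSpec, seg: LabelVolume) -> PetVolume:
    """Scenario-driven PET uptake on the phantom segmentation.

    Baseline uptake is 1.0 in every labeled voxel (so the cerebellar mean is
    exactly 1.0 before noise); each scenario lesion is a contiguous
    26-connected cluster of ``lesion_voxels`` voxels at
    ``lesion_ratio`` x cerebellar mean inside its target parcel (typical-AD
    additionally fills the temporal meta-ROI parcels; off-target-only fills
    choroid plexus, striatum and brainstem).  Gaussian noise with sd
    ``noise_sd`` is then added to brain voxels (clipped at zero), reproducibly
    from ``spec.seed``.
    """
    if tuple(seg.shape) != tuple(spec.grid_shape):
        raise ValueError("segmentation grid does not match spec.grid_shape")
    brain = seg.data != 0
    pet = np.zeros(seg.shape, dtype=np.float64)
    pet[brain] = 1.0
    blobs, fills = _scenario_sites(spec)
    for label in blobs:
        blob = _grow_blob(seg.mask(label), spec.lesion_voxels, label)
        pet[blob] = spec.lesion_ratio
    for label in fills:
        pet[seg.mask(label)] = spec.lesion_ratio
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pet[brain] = np.clip(pet[brain] + rng.normal(0.0, spec.noise_sd, int(brain.sum())), 0.0, None)
    return PetVolume(data=pet, voxel_size=tuple(spec.voxel_size))


def generate_phantom(spec: PhantomSpec) -> tuple[PetVolume, LabelVolume]:
    """Convenience wrapper: segmentation + PET for one spec."""
    seg = generate_segmentation(spec)
    return generate_pet(spec, seg), seg


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class BiomarkerComponent:
    """One mixture component, parameterized on the measurement scale.

    ``mean``/``sd`` are the target measurement-scale moments; ``lam`` is the
    Manly skew (per unit of measurement).  Internally, draws use the
    transformed-scale parameters mu = T_lam(mean), sigma = sd * exp(lam*mean)
    (first-order delta method), so lam = 0 reduces exactly to
    Normal(mean, sd).
    """

    mean: float
    sd: float
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("component sd must be positive")

    @property
    def transformed_mu(self) -> float:
        return float(manly_transform(self.mean, self.lam))

    @property
    def transformed_sigma(self) -> float:
        return float(self.sd * np.exp(self.lam * self.mean))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n values: Gaussian on the transformed scale, inverse-mapped back.

        Draws outside the inverse transform's domain (1 + lam*y <= 0, tail
        mass ~1e-5 for the defaults) are rejected and redrawn.
        """
        y = rng.normal(self.transformed_mu, self.transformed_sigma, n)
        if self.lam != 0.0:
            bad = 1.0 + self.lam * y <= 0.0
            while bad.any():
                y[bad] = rng.normal(self.transformed_mu, self.transformed_sigma, int(bad.sum()))
                bad = 1.0 + self.lam * y <= 0.0
        return manly_inverse(y, self.lam)


def default_biomarker_components() -> dict[str, tuple[BiomarkerComponent, BiomarkerComponent]]:
    """(healthy, disease) components per biomarker.

    Chosen so the marginal moments resemble published cognitively-normal vs
    impaired summaries: SUVR ~1.15 vs ~1.6, Centiloid ~5 vs ~85 (negative
    values possible), p-tau181 ~38 vs ~95 pg/ml, Abeta42/40 ratio ~0.085 vs
    ~0.051 (the ratio *decreases* with disease).  Negative lam values give the
    right-skewed measurement-scale shapes typical of SUVR, Centiloid and
    p-tau distributions (lam > 0 would skew left).
    """
    return {
        "suvr": (BiomarkerComponent(1.13, 0.09, -1.5), BiomarkerComponent(1.60, 0.28, -0.8)),
        "centiloid": (BiomarkerComponent(5.0, 12.0, -0.02), BiomarkerComponent(85.0, 40.0, -0.004)),
        "ptau181": (BiomarkerComponent(38.0, 14.0, -0.02), BiomarkerComponent(95.0, 40.0, -0.008)),
        "abeta42_40_ratio": (BiomarkerComponent(0.085, 0.011, 0.0), BiomarkerComponent(0.051, 0.012, 0.0)),
    }


def default_transition_matrix() -> np.ndarray:
    """Yearly diagnosis transition probabilities over (CN, UD, AD, FTD)."""
    return np.array(
        [
            [0.90, 0.06, 0.035, 0.005],
            [0.15, 0.60, 0.22, 0.03],
            [0.03, 0.07, 0.88, 0.02],
            [0.00, 0.02, 0.03, 0.95],
        ]
    )


@dataclass
class CohortSimParams:
    n: int = 189
    components: dict[str, tuple[BiomarkerComponent, BiomarkerComponent]] = field(
        default_factory=default_biomarker_components
    )
    disease_prevalence: float = 0.25
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    n_followups: int = 5
    #: fraction of participants with CSF available (lumbar-puncture subset).
    csf_fraction: float = 144.0 / 189.0
    #: visual-read positivity probabilities given (healthy, disease) state.
    p_visual_positive: tuple[float, float] = (0.03, 0.85)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0.0 <= self.disease_prevalence <= 1.0:
            raise ValueError("disease_prevalence must lie in [0, 1]")
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (len(DIAGNOSIS_STATES), len(DIAGNOSIS_STATES)):
            raise ValueError(f"transition_matrix must be {len(DIAGNOSIS_STATES)}x{len(DIAGNOSIS_STATES)}")
        if np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition_matrix rows must be non-negative and sum to 1")
        self.transition_matrix = tm
        missing = [b for b in BIOMARKERS if b not in self.components]
        if missing:
            raise ValueError(f"missing biomarker components for {missing}")
        if not 0.0 <= self.csf_fraction <= 1.0:
            raise ValueError("csf_fraction must lie in [0, 1]")


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate a biomarker cohort table.

    Columns: ``participant_id``, ``disease_state`` (0/1 latent), ``visual_read``
    ("positive"/"negative"), one column per biomarker (CSF columns NaN outside
    the lumbar-puncture subset), ``baseline_dx``, and ``dx_year_1`` ..
    ``dx_year_{n_followups}``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    disease = rng.random(n) < params.disease_prevalence

    table: dict[str, object] = {
        "participant_id": [f"sub-{i:04d}" for i in range(n)],
        "disease_state": disease.astype(int),
    }
    p_vis = np.where(disease, params.p_visual_positive[1], params.p_visual_positive[0])
    table["visual_read"] = np.where(rng.random(n) < p_vis, "positive", "negative")

    for name in BIOMARKERS:
        healthy, sick = params.components[name]
        values = np.empty(n)
        values[~disease] = healthy.sample(rng, int((~disease).sum()))
        values[disease] = sick.sample(rng, int(disease.sum()))
        table[name] = values

    has_csf = rng.random(n) < params.csf_fraction
    for name in ("ptau181", "abeta42_40_ratio"):
        col = np.asarray(table[name], dtype=float)
        col[~has_csf] = np.nan
        table[name] = col

    # Baseline diagnosis: healthy -> CN; diseased -> CN/UD/AD mixture.
    baseline_idx = np.zeros(n, dtype=int)
    n_sick = int(disease.sum())
    baseline_idx[disease] = rng.choice([0, 1, 2], size=n_sick, p=[0.3, 0.3, 0.4])
    states = [baseline_idx]
    cum = np.cumsum(params.transition_matrix, axis=1)
    for _ in range(params.n_followups):
        u = rng.random(n)
        prev = states[-1]
        nxt = (u[:, None] > cum[prev]).sum(axis=1) if n else np.zeros(0, dtype=int)
        states.append(nxt.astype(int))
    dx_names = np.array(DIAGNOSIS_STATES)
    table["baseline_dx"] = dx_names[baseline_idx] if n else np.array([], dtype=object)
    for year in range(1, params.n_followups + 1):
        table[f"dx_year_{year}"] = dx_names[states[year]] if n else np.array([], dtype=object)

    columns = list(COHORT_COLUMNS) + [f"dx_year_{y}" for y in range(1, params.n_followups + 1)]
    return pd.DataFrame(table, columns=columns)
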