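"""Algorithmic emulation of the flortaucipir visual-interpretation rule.

The manufacturer's read rule, as operationalized here on labeled volumes:

1. draw the cerebellar reference in the axial plane where the whole cerebellum
   has its largest cross-sectional area and take the mean counts there;
2. threshold the volume at ``threshold_factor`` (default 1.65) times that
   reference mean, restricted to cortical gray matter — off-target structures
   (choroid plexus, striatum, brainstem, meninges/bone) never contribute;
3. keep only contiguous suprathreshold clusters of at least
   ``min_cluster_voxels`` voxels (small noncontiguous foci are ignored);
4. the scan is positive iff some cluster touches posterolateral temporal,
   occipital, or parietal/precuneus cortex; uptake confined to medial temporal,
   anterolateral temporal, or frontal cortex leaves the scan negative.

The temporal lobe is split into anterolateral / anterior-mesial /
posterolateral / posterior-mesial quadrants by two crosshair planes: a coronal
plane immediately posterior to the brainstem, and a per-hemisphere sagittal
plane through the medio-lateral midpoint of the temporal pole on its widest
axial slice.  Asymmetry and off-target uptake are reported separately from
positivity, mirroring how readers annotate but do not score them.

Coordinate convention: see :mod:`tauread.volumes` ("posterior" = decreasing
coronal index ``y``; the most inferior axial slice is ``z = 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import BACKGROUND_ID, LabelVolume, PetVolume, check_same_grid

#: Labels excluded from the threshold mask: reference tissue plus the
#: structures where off-target binding is expected.
NON_CORTICAL_LABELS = (
    "cerebellum_gray",
    "whole_cerebellum",
    "brainstem",
    "choroid_plexus",
    "striatum",
    "meninges_bone",
)

#: Off-target structures reported (but never scored) by the read.
OFFTARGET_LABELS = ("choroid_plexus", "striatum", "brainstem", "meninges_bone")

#: Base names of parcels treated as temporal cortex for quadrant assignment.
TEMPORAL_CORTEX_PARCELS = (
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
)

QUADRANT_NAMES = (
    "anterolateral_temporal",
    "anterior_mesial_temporal",
    "posterolateral_temporal",
    "posterior_mesial_temporal",
)

#: Parcels (base names) whose involvement makes a read positive.
TARGET_PARCELS = ("posterolateral_temporal", "occipital", "parietal_precuneus")


class LandmarkError(ValueError):
    """A landmark parcel required by the crosshair construction is missing/empty."""


@dataclass
class ReadConfig:
    """Tunables of the read rule."""

    threshold_factor: float = 1.65
    connectivity: int = 26
    min_cluster_voxels: int = 20
    #: |ln(left mean / right mean)| above which a target region is flagged asymmetric.
    asymmetry_log_ratio_flag: float = math.log(1.25)

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")


@dataclass
class CerebellarReference:
    plane_index: int
    mean: float


@dataclass
class ClusterInfo:
    """One contiguous suprathreshold cluster surviving the size filter."""

    size: int
    regions_touched: set[str]
    peak_ratio: float
    hemisphere: str  # "left" | "right" | "bilateral"
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "size": self.size,
            "regions_touched": sorted(self.regions_touched),
            "peak_ratio": self.peak_ratio,
            "hemisphere": self.hemisphere,
        }


@dataclass
class QuadrantAssignment:
    """Crosshair-derived relabeling of temporal cortex into quadrants."""

    y_split: int  # anterior iff y >= y_split
    x_mid: dict[str, int]  # per hemisphere; mesial side faces the midline
    codes: np.ndarray  # int8 volume, 0 = not temporal cortex
    code_map: dict[int, str]  # code -> e.g. "left_posterolateral_temporal"

    def counts(self) -> dict[str, int]:
        return {name: int(np.count_nonzero(self.codes == code)) for code, name in self.code_map.items()}


@dataclass
class VisualReadResult:
    positivity: str  # "positive" | "negative"
    clusters: list[ClusterInfo]
    asymmetric: bool
    dominant_side: str | None
    offtarget_flags: set[str]
    notable_findings: set[str]
    reference_mean: float
    reference_plane: int

    def to_dict(self) -> dict:
        return {
            "positivity": self.positivity,
            "clusters": [c.to_dict() for c in self.clusters],
            "asymmetric": self.asymmetric,
            "dominant_side": self.dominant_side,
            "offtarget_flags": sorted(self.offtarget_flags),
            "notable_findings": sorted(self.notable_findings),
            "reference_mean": self.reference_mean,
            "reference_plane": self.reference_plane,
        }


def cerebellar_reference(pet: PetVolume, seg: LabelVolume) -> CerebellarReference:
    """Mean counts over the whole cerebellum in its widest axial slice.

    The slice with the maximal cerebellar cross-sectional voxel count is
    selected; ties resolve to the most inferior slice.
    """
    check_same_grid(pet, seg)
    names = [n for n in ("whole_cerebellum", "cerebellum_gray") if n in seg.label_map]
    if not names:
        raise LandmarkError("whole_cerebellum label absent from segmentation")
    mask = seg.mask(*names)
    if not mask.any():
        raise LandmarkError("whole_cerebellum label is empty")
    per_slice = mask.sum(axis=(0, 1))
    plane = int(np.argmax(per_slice))  # argmax returns the first (most inferior) maximum
    slice_mask = mask[:, :, plane]
    mean = float(pet.data[:, :, plane][slice_mask].mean())
    return CerebellarReference(plane_index=plane, mean=mean)


def threshold_mask(
    pet: PetVolume, seg: LabelVolume, reference_mean: float, config: ReadConfig | None = None
) -> np.ndarray:
    """Boolean mask of cortical-gray voxels at or above threshold x reference."""
    config = config or ReadConfig()
    check_same_grid(pet, seg)
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    excluded = {seg.label_map[n] for n in NON_CORTICAL_LABELS if n in seg.label_map}
    excluded.add(BACKGROUND_ID)
    cortical = ~np.isin(seg.data, sorted(excluded))
    return (pet.data >= config.threshold_factor * reference_mean) & cortical


def _connectivity_structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def find_clusters(
    mask: np.ndarray,
    seg: LabelVolume,
    config: ReadConfig | None = None,
    pet: PetVolume | None = None,
    reference_mean: float | None = None,
) -> list[ClusterInfo]:
    """Connected components of ``mask``, size-filtered and annotated.

    ``peak_ratio`` is NaN when no PET volume/reference is supplied (pure
    cluster-geometry use).  Clusters are returned largest first.
    """
    config = config or ReadConfig()
    if mask.shape != seg.shape:
        raise ValueError("mask grid does not match segmentation grid")
    labeled, n_comp = ndimage.label(mask, structure=_connectivity_structure(config.connectivity))
    id_to_name = seg.id_to_name
    mid_x = seg.shape[0] // 2
    clusters: list[ClusterInfo] = []
    for comp in range(1, n_comp + 1):
        voxels = np.nonzero(labeled == comp)
        size = voxels[0].size
        if size < config.min_cluster_voxels:
            continue
        regions = {id_to_name[i] for i in np.unique(seg.data[voxels]) if i != BACKGROUND_ID}
        on_left = bool((voxels[0] < mid_x).any())
        on_right = bool((voxels[0] >= mid_x).any())
        hemisphere = "bilateral" if (on_left and on_right) else ("left" if on_left else "right")
        if pet is not None and reference_mean:
            peak_ratio = float(pet.data[voxels].max() / reference_mean)
        else:
            peak_ratio = float("nan")
        clusters.append(ClusterInfo(size=int(size), regions_touched=regions, peak_ratio=peak_ratio, hemisphere=hemisphere, voxels=voxels))
    clusters.sort(key=lambda c: -c.size)
    return clusters


def quadrant_split_planes(
    brainstem_mask: np.ndarray, pole_masks: dict[str, np.ndarray]
) -> tuple[int, dict[str, int]]:
    """Crosshair planes from the brainstem and temporal-pole landmarks.

    Returns ``(y_split, x_mid)``: a voxel is anterior iff its coronal index
    ``y >= y_split`` (the dividing plane ``y_split - 1`` is the first plane
    posterior to the posterior-most brainstem voxel); ``x_mid[side]`` is the
    medio-lateral midpoint of that side's temporal pole on its widest axial
    slice (ties to the most inferior slice).
    """
    if not brainstem_mask.any():
        raise LandmarkError("brainstem landmark is empty")
    y_split = int(np.nonzero(brainstem_mask)[1].min())
    x_mid: dict[str, int] = {}
    for side, pole in pole_masks.items():
        if not pole.any():
            raise LandmarkError(f"{side} temporal pole landmark is empty")
        per_slice = pole.sum(axis=(0, 1))
        z = int(np.argmax(per_slice))
        xs = np.nonzero(pole[:, :, z].any(axis=1))[0]
        x_mid[side] = int((xs.min() + xs.max() + 1) // 2)
    return y_split, x_mid


def temporal_quadrants(seg: LabelVolume) -> QuadrantAssignment:
    """Assign every temporal-cortex voxel to exactly one crosshair quadrant."""
    if "brainstem" not in seg.label_map:
        raise LandmarkError("brainstem label absent from segmentation")
    pole_masks = {}
    for side in ("left", "right"):
        name = f"{side}_temporal_pole"
        if name not in seg.label_map:
            raise LandmarkError(f"{name} label absent from segmentation")
        pole_masks[side] = seg.mask(name)
    y_split, x_mid = quadrant_split_planes(seg.mask("brainstem"), pole_masks)

    codes = np.zeros(seg.shape, dtype=np.int8)
    code_map: dict[int, str] = {}
    code = 0
    xg = np.arange(seg.shape[0])[:, None, None]
    yg = np.arange(seg.shape[1])[None, :, None]
    for side in ("left", "right"):
        present = [f"{side}_{p}" for p in TEMPORAL_CORTEX_PARCELS if f"{side}_{p}" in seg.label_map]
        temporal = seg.mask(*present)
        anterior = np.broadcast_to(yg >= y_split, seg.shape)
        if side == "left":
            mesial = np.broadcast_to(xg >= x_mid[side], seg.shape)
        else:
            mesial = np.broadcast_to(xg < x_mid[side], seg.shape)
        for quad, region in (
            ((anterior & ~mesial), "anterolateral_temporal"),
            ((anterior & mesial), "anterior_mesial_temporal"),
            ((~anterior & ~mesial), "posterolateral_temporal"),
            ((~anterior & mesial), "posterior_mesial_temporal"),
        ):
            code += 1
            codes[temporal & quad] = code
            code_map[code] = f"{side}_{region}"
    return QuadrantAssignment(y_split=y_split, x_mid=x_mid, codes=codes, code_map=code_map)


def _target_region_masks(seg: LabelVolume, quadrants: QuadrantAssignment) -> dict[str, dict[str, np.ndarray]]:
    """Per target region, per hemisphere boolean masks (quadrant-based for temporal)."""
    name_to_code = {v: k for k, v in quadrants.code_map.items()}
    out: dict[str, dict[str, np.ndarray]] = {}
    for region in TARGET_PARCELS:
        per_side = {}
        for side in ("left", "right"):
            if region == "posterolateral_temporal":
                per_side[side] = quadrants.codes == name_to_code[f"{side}_{region}"]
            else:
                per_side[side] = seg.mask(f"{side}_{region}")
        out[region] = per_side
    return out


def classify_read(
    clusters: list[ClusterInfo],
    seg: LabelVolume,
    config: ReadConfig | None = None,
    pet: PetVolume | None = None,
    reference_mean: float | None = None,
) -> VisualReadResult:
    """Apply the positive/negative region logic to size-filtered clusters.

    Positive iff any cluster touches posterolateral temporal (by the crosshair
    quadrants), occipital, or parietal/precuneus cortex.  Asymmetry, off-target
    flags and notable findings are annotations, never part of positivity.
    """
    config = config or ReadConfig()
    quadrants = temporal_quadrants(seg)
    targets = _target_region_masks(seg, quadrants)

    positive = False
    for cluster in clusters:
        quad_codes = np.unique(quadrants.codes[cluster.voxels])
        quad_names = {quadrants.code_map[c] for c in quad_codes if c != 0}
        cluster.regions_touched |= quad_names
        touched = {r.split("_", 1)[1] for r in cluster.regions_touched if r.startswith(("left_", "right_"))}
        if touched & set(TARGET_PARCELS):
            positive = True

    asymmetric = False
    dominant_side: str | None = None
    best = 0.0
    if pet is not None:
        for region, sides in targets.items():
            lm, rm = sides["left"], sides["right"]
            if not (lm.any() and rm.any()):
                continue
            left_mean = float(pet.data[lm].mean())
            right_mean = float(pet.data[rm].mean())
            if left_mean <= 0 or right_mean <= 0:
                continue
            lr = math.log(left_mean / right_mean)
            if abs(lr) > config.asymmetry_log_ratio_flag and abs(lr) > best:
                asymmetric = True
                best = abs(lr)
                dominant_side = "left" if lr > 0 else "right"

    offtarget: set[str] = set()
    if pet is not None and reference_mean:
        thr = config.threshold_factor * reference_mean
        for name in OFFTARGET_LABELS:
            if name in seg.label_map and bool((pet.data[seg.mask(name)] >= thr).any()):
                offtarget.add(name)

    notable: set[str] = set()
    frontal_labels = {f"{s}_frontal" for s in ("left", "right")}
    for cluster in clusters:
        static = {r for r in cluster.regions_touched if r in seg.label_map}
        if static and static <= frontal_labels:
            notable.add("frontal_focal_uptake")

    ref_mean = float(reference_mean) if reference_mean else float("nan")
    return VisualReadResult(
        positivity="positive" if positive else "negative",
        clusters=clusters,
        asymmetric=asymmetric,
        dominant_side=dominant_side,
        offtarget_flags=offtarget,
        notable_findings=notable,
        reference_mean=ref_mean,
        reference_plane=-1,
    )


def read_pipeline(pet: PetVolume, seg: LabelVolume, config: ReadConfig | None = None) -> VisualReadResult:
    """Full read: reference plane -> threshold mask -> clusters -> classification.

    Deterministic, and invariant to global rescaling of the PET volume by any
    positive constant (every step operates on ratios to the reference mean).
    """
    config = config or ReadConfig()
    ref = cerebellar_reference(pet, seg)
    mask = threshold_mask(pet, seg, ref.mean, config)
    clusters = find_clusters(mask, seg, config, pet=pet, reference_mean=ref.mean)
    result = classify_read(clusters, seg, config, pet=pet, reference_mean=ref.mean)
    result.reference_plane = ref.plane_index
    return result
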