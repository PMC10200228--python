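"""Regional SUVRs, the temporal meta-ROI, Centiloid standardization, and statuses.

The standardized uptake value ratio (SUVR) of a parcel is its mean PET
activity divided by the mean activity of a reference region — here cerebellar
gray.  The temporal meta-ROI SUVR is the volume-weighted mean SUVR of the
amygdala, entorhinal, fusiform, parahippocampal, inferior temporal, and middle
temporal parcels, pooled across hemispheres by voxel count (equivalently: the
mean activity over the union of their voxels divided by the reference mean).
Note the meta-ROI contains none of the occipital or parietal/precuneus cortex
that drives the visual-read rule, which is exactly why lateralized or
occipital-predominant uptake can be visually positive yet SUVR-negative.

Amyloid PET burden is standardized to the Centiloid scale by a configurable
affine map; the calibration constants come from tracer-specific calibration
studies and are configuration here, not computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .volumes import BACKGROUND_ID, LabelVolume, PetVolume, check_same_grid

#: Base names (per hemisphere) of the temporal meta-ROI parcels.
META_ROI_PARCELS = (
    "amygdala",
    "entorhinal",
    "fusiform",
    "parahippocampal",
    "inferior_temporal",
    "middle_temporal",
)

#: Reference region for SUVR quantification (the visual read uses its own,
#: plane-based cerebellar reference — a deliberately distinct convention).
REFERENCE_LABEL = "cerebellum_gray"

POSITIVE = "positive"
NEGATIVE = "negative"

ABOVE_POSITIVE = "above_positive"
BELOW_POSITIVE = "below_positive"


class EmptyLabelError(ValueError):
    """A parcel named in the label map has no voxels in the volume."""


class RegionStat(NamedTuple):
    mean: float
    count: int


@dataclass
class SuvrResult:
    per_label_mean: dict[str, float]
    reference_mean: float
    per_label_suvr: dict[str, float]
    meta_roi_suvr: float
    meta_roi_labels: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "reference_mean": self.reference_mean,
            "meta_roi_suvr": self.meta_roi_suvr,
            "meta_roi_labels": list(self.meta_roi_labels),
            "per_label_suvr": dict(sorted(self.per_label_suvr.items())),
        }


@dataclass
class CutoffConfig:
    """Biomarker positivity cutoffs with their directions.

    The defaults are published cohort-level cutpoints (tau PET temporal
    meta-ROI SUVR 1.32, amyloid PET 21.6 Centiloid, CSF p-tau181 58.1 pg/ml,
    CSF Abeta42/Abeta40 0.0737) shipped as configuration for use without
    refitting; :func:`tauread.mixture.derive_cutoffs` re-estimates them on a
    cohort table.
    """

    suvr_cutoff: float = 1.32
    centiloid_cutoff: float = 21.6
    ptau_cutoff: float = 58.1
    abeta_ratio_cutoff: float = 0.0737

    def __post_init__(self) -> None:
        for name in ("suvr_cutoff", "centiloid_cutoff", "ptau_cutoff", "abeta_ratio_cutoff"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def directions(self) -> dict[str, str]:
        return {
            "suvr": ABOVE_POSITIVE,
            "centiloid": ABOVE_POSITIVE,
            "ptau181": ABOVE_POSITIVE,
            "abeta42_40_ratio": BELOW_POSITIVE,
        }

    def cutoff_for(self, biomarker: str) -> float:
        return {
            "suvr": self.suvr_cutoff,
            "centiloid": self.centiloid_cutoff,
            "ptau181": self.ptau_cutoff,
            "abeta42_40_ratio": self.abeta_ratio_cutoff,
        }[biomarker]

    def status_for(self, biomarker: str, value: float) -> str:
        return binarize(value, self.cutoff_for(biomarker), self.directions[biomarker])

    def to_dict(self) -> dict:
        return {
            "suvr_cutoff": self.suvr_cutoff,
            "centiloid_cutoff": self.centiloid_cutoff,
            "ptau_cutoff": self.ptau_cutoff,
            "abeta_ratio_cutoff": self.abeta_ratio_cutoff,
        }


def regional_means(pet: PetVolume, seg: LabelVolume) -> dict[str, RegionStat]:
    """Arithmetic mean activity and voxel count per named parcel.

    Raises :class:`EmptyLabelError` naming the first label-map entry with no
    voxels, and a grid-mismatch error when the volumes disagree in shape.
    """
    check_same_grid(pet, seg)
    flat = seg.data.ravel()
    sums = np.bincount(flat, weights=pet.data.ravel())
    counts = np.bincount(flat)
    out: dict[str, RegionStat] = {}
    for name, lid in seg.label_map.items():
        if name == "background":
            continue
        if lid >= counts.size or counts[lid] == 0:
            raise EmptyLabelError(f"label {name!r} (id {lid}) has no voxels")
        out[name] = RegionStat(mean=float(sums[lid] / counts[lid]), count=int(counts[lid]))
    return out


def meta_roi_suvr(means: dict[str, RegionStat], reference: str = REFERENCE_LABEL) -> SuvrResult:
    """SUVRs per parcel and the volume-weighted temporal meta-ROI SUVR.

    The meta-ROI pools the six temporal parcels across both hemispheres,
    weighting each parcel's SUVR by its voxel count, so the result equals the
    plain mean over the union of meta-ROI voxels divided by the reference mean.
    """
    if reference not in means:
        raise KeyError(f"reference parcel {reference!r} missing from regional means")
    ref = means[reference].mean
    if ref <= 0:
        raise ValueError(f"reference mean must be positive, got {ref}")

    meta_labels = tuple(f"{side}_{p}" for p in META_ROI_PARCELS for side in ("left", "right"))
    missing = [m for m in meta_labels if m not in means]
    if missing:
        raise KeyError(f"meta-ROI parcels missing from regional means: {missing}")

    per_label_suvr = {name: stat.mean / ref for name, stat in means.items()}
    per_label_suvr[reference] = 1.0  # exact by definition
    weight_sum = sum(means[m].count for m in meta_labels)
    meta = sum(per_label_suvr[m] * means[m].count for m in meta_labels) / weight_sum
    return SuvrResult(
        per_label_mean={k: v.mean for k, v in means.items()},
        reference_mean=ref,
        per_label_suvr=per_label_suvr,
        meta_roi_suvr=float(meta),
        meta_roi_labels=meta_labels,
    )


def compute_suvr(pet: PetVolume, seg: LabelVolume, reference: str = REFERENCE_LABEL) -> SuvrResult:
    """Regional means + meta-ROI SUVR in one call."""
    return meta_roi_suvr(regional_means(pet, seg), reference)


def centiloid(suvr: float, slope: float = 100.0 / 0.5, intercept: float = -100.0) -> float:
    """Affine standardization of an amyloid PET SUVR to the Centiloid scale.

    The default slope/intercept are placeholder calibration constants (an SUVR
    of 0.5 maps to 0 CL, 1.0 to 100 CL); real use supplies tracer-specific
    values from a Centiloid calibration.
    """
    if slope == 0:
        raise ValueError("Centiloid slope must be non-zero")
    return slope * suvr + intercept


def centiloid_inverse(cl: float, slope: float = 100.0 / 0.5, intercept: float = -100.0) -> float:
    if slope == 0:
        raise ValueError("Centiloid slope must be non-zero")
    return (cl - intercept) / slope


def binarize(value: float, cutoff: float, direction: str) -> str:
    """Binary biomarker status; ties at the cutoff count as positive for
    above-positive markers (value >= cutoff), and as negative for
    below-positive markers (positive iff value < cutoff)."""
    if not np.isfinite(value):
        raise ValueError(f"cannot binarize non-finite value {value}")
    if direction == ABOVE_POSITIVE:
        return POSITIVE if value >= cutoff else NEGATIVE
    if direction == BELOW_POSITIVE:
        return POSITIVE if value < cutoff else NEGATIVE
    raise ValueError(f"unknown direction {direction!r}")
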