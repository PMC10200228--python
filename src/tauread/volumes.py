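"""In-memory containers for PET and segmentation volumes.

Coordinate convention (used everywhere in the package): arrays are indexed
``[x, y, z]`` with

* axis 0 (sagittal, x): left -> right, the left hemisphere occupies ``x < nx // 2``;
* axis 1 (coronal, y): posterior -> anterior ("posterior" means decreasing y);
* axis 2 (axial, z): inferior -> superior (the most inferior axial slice is ``z = 0``).

Indices are 0-based voxel indices; ``voxel_size`` carries the physical spacing
in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Label id reserved for background (outside the head).
BACKGROUND_ID = 0


class GridMismatchError(ValueError):
    """PET and segmentation volumes do not share the same voxel grid."""


@dataclass
class PetVolume:
    """A 3D non-negative activity volume on a regular grid."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"PET volume must be 3D, got {self.data.ndim}D")
        if np.any(self.data < 0):
            raise ValueError("PET volume contains negative activity values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def scaled(self, factor: float) -> "PetVolume":
        """Return a copy with every voxel multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return PetVolume(self.data * factor, self.voxel_size)


@dataclass
class LabelVolume:
    """A 3D integer parcellation plus a name -> id label dictionary."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    label_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("segmentation volume must hold integer labels")
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got {self.data.ndim}D")
        if "background" not in self.label_map:
            self.label_map = {"background": BACKGROUND_ID, **self.label_map}
        if self.label_map["background"] != BACKGROUND_ID:
            raise ValueError("background label id must be 0")
        present = set(np.unique(self.data).tolist())
        known = set(self.label_map.values())
        stray = present - known
        if stray:
            raise ValueError(f"label ids {sorted(stray)} in volume are missing from label_map")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def id_to_name(self) -> dict[int, str]:
        return {v: k for k, v in self.label_map.items()}

    def id_for(self, name: str) -> int:
        try:
            return self.label_map[name]
        except KeyError:
            raise KeyError(f"label {name!r} not present in label_map") from None

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of voxels belonging to any of the named parcels."""
        ids = [self.id_for(n) for n in names]
        return np.isin(self.data, ids)

    def count(self, name: str) -> int:
        return int(np.count_nonzero(self.data == self.id_for(name)))


def check_same_grid(pet: PetVolume, seg: LabelVolume) -> None:
    if pet.shape != seg.shape:
        raise GridMismatchError(f"PET grid {pet.shape} does not match segmentation grid {seg.shape}")
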