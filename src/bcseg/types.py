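"""Core domain containers: CT slices and binary masks.

Conventions: grids are row-major 2-D numpy arrays indexed (row, col), origin
top-left. Slice pixels carry Hounsfield units (water 0, air about -1000,
cortical bone well above 400). Masks are boolean and aligned pixel-for-pixel
with their slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

import numpy as np

#: Segmentation targets of the three-slice protocol, keyed by the slice they
#: live on.
TARGETS_BY_SLICE = {
    "liver": ("liver_accurate", "liver_crude", "spleen"),
    "abdomen": ("sat", "vat", "ipat", "rpat", "dsat", "ssat",
                "spine_bone_marrow", "skeleton_muscle"),
    "thigh": ("thigh_sat", "thigh_muscle", "imat", "bone_marrow", "cortical_bone"),
}

KNOWN_TARGETS = tuple(t for ts in TARGETS_BY_SLICE.values() for t in ts)


class SliceType(str, Enum):
    LIVER = "liver"
    ABDOMEN = "abdomen"
    THIGH = "thigh"

    @classmethod
    def coerce(cls, value) -> "SliceType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ValueError(f"unknown slice type {value!r}; expected one of "
                             f"{[m.value for m in cls]}") from exc


def slice_type_of_target(target: str) -> SliceType:
    """Map a segmentation-target name to the slice it is defined on."""
    for stype, targets in TARGETS_BY_SLICE.items():
        if target in targets:
            return SliceType(stype)
    raise KeyError(f"unknown segmentation target {target!r}")


@dataclass
class CTSlice:
    """A single axial CT slice in Hounsfield units."""

    pixels: np.ndarray
    slice_type: SliceType
    spacing: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(f"CTSlice pixels must be a non-empty 2-D grid, got shape {self.pixels.shape}")
        self.slice_type = SliceType.coerce(self.slice_type)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A boolean segmentation mask aligned to a CT slice."""

    pixels: np.ndarray
    label: str = "mask"

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(f"BinaryMask pixels must be a non-empty 2-D grid, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"BinaryMask values must be 0/1, found {uniq[:10]}")
            arr = arr.astype(bool)
        self.pixels = arr

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def __eq__(self, other) -> bool:
        return (isinstance(other, BinaryMask) and self.label == other.label
                and self.pixels.shape == other.pixels.shape
                and bool(np.array_equal(self.pixels, other.pixels)))
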