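"""Thigh cortical-bone / bone-marrow segmentation without learning.

Cortical bone is bright enough on CT (well above 400 HU) that a fixed
threshold followed by light morphology segments it reliably: threshold,
remove small bright objects (calcifications), fill small holes inside the
cortex. Bone marrow is then whatever the cortical shell encloses: fill the
shell's cavities and subtract the shell. A quality-control step counts
shells and cavities; a healthy thigh slice has exactly two marrow cavities
(one femur per leg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy import ndimage
from skimage import morphology

from .losses import dice_score  # noqa: F401  (re-exported convenience for QC scripts)
from .types import BinaryMask, CTSlice, SliceType


@dataclass(frozen=True)
class BonePipeConfig:
    hu_threshold: float = 400.0
    min_object_px: int = 20
    max_hole_px: int = 50
    connectivity: int = 8
    closing_radius: int = 1   # applied only when fewer than 2 cavities emerge

    def __post_init__(self):
        if self.hu_threshold <= 0:
            raise ValueError("hu_threshold must be positive")
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def _skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2


@dataclass
class BoneQCReport:
    cortical_components: int
    marrow_cavities: int
    flags: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def segment_cortical(slc: CTSlice, cfg: BonePipeConfig = BonePipeConfig()) -> BinaryMask:
    """Threshold > ``hu_threshold``, drop small objects, fill small holes.

    Returns an empty mask (no exception) when nothing exceeds the threshold;
    :func:`qc_bone` reports that state.
    """
    if slc.slice_type is not SliceType.THIGH:
        raise ValueError(f"bone pipeline is defined on thigh slices, got {slc.slice_type.value}")
    conn = cfg._skimage_connectivity
    raw = np.asarray(slc.pixels) > cfg.hu_threshold
    # max_size is inclusive: objects/holes of area < the configured bound go
    cleaned = morphology.remove_small_objects(raw, max_size=cfg.min_object_px - 1,
                                              connectivity=conn)
    filled = morphology.remove_small_holes(cleaned, max_size=cfg.max_hole_px - 1,
                                           connectivity=1)
    return BinaryMask(filled, label="cortical_bone")


def _fill_cavities(mask: np.ndarray) -> np.ndarray:
    """Fill every cavity: complement components not connected to the border."""
    return ndimage.binary_fill_holes(mask)


def segment_marrow(slc: CTSlice, cortical: BinaryMask,
                   cfg: BonePipeConfig = BonePipeConfig()) -> BinaryMask:
    """Marrow = hole-filled cortical shell minus the shell itself.

    If the shell is broken (fewer than two cavities found), a light closing
    with radius ``cfg.closing_radius`` is applied before filling so hairline
    cortex breaks do not leak the cavity into the background; the closing is
    used only for the fill, the subtracted shell stays untouched.
    """
    shell = cortical.pixels
    filled = _fill_cavities(shell)
    marrow = filled & ~shell
    if _count_cavities(shell, marrow, cfg) < 2 and cfg.closing_radius > 0:
        closed = morphology.closing(shell, morphology.disk(cfg.closing_radius))
        marrow = _fill_cavities(closed) & ~shell
    return BinaryMask(marrow, label="bone_marrow")


def _count_cavities(shell: np.ndarray, marrow: np.ndarray, cfg: BonePipeConfig) -> int:
    _, n = ndimage.label(marrow, structure=_structure(cfg))
    return int(n)


def _structure(cfg: BonePipeConfig) -> np.ndarray:
    return ndimage.generate_binary_structure(2, cfg._skimage_connectivity)


def qc_bone(cortical: BinaryMask, marrow: BinaryMask,
            cfg: BonePipeConfig = BonePipeConfig()) -> BoneQCReport:
    """Automated sanity checks mirroring a visual review of the pipeline.

    Flags anatomical deviations (cavity count != 2, e.g. a missing femur or a
    solid metal implant), an empty threshold result, marrow touching the
    image border (leaked cavity), and marrow overlapping the shell.
    """
    if cortical.shape != marrow.shape:
        raise ValueError("cortical and marrow masks must be aligned")
    struct = _structure(cfg)
    _, n_cort = ndimage.label(cortical.pixels, structure=struct)
    _, n_marrow = ndimage.label(marrow.pixels, structure=struct)
    flags: List[str] = []
    if cortical.area == 0:
        flags.append("empty_cortical_mask")
    if n_marrow != 2:
        flags.append("anatomical_deviation:cavity_count")
    border = np.zeros(marrow.shape, bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (marrow.pixels & border).any():
        flags.append("marrow_touches_border")
    if (marrow.pixels & cortical.pixels).any():
        flags.append("marrow_overlaps_cortical")
    return BoneQCReport(int(n_cort), int(n_marrow), flags)


def run_pipeline(slc: CTSlice, cfg: BonePipeConfig = BonePipeConfig()):
    """Convenience wrapper: (cortical, marrow, qc) in one call."""
    cortical = segment_cortical(slc, cfg)
    marrow = segment_marrow(slc, cortical, cfg)
    return cortical, marrow, qc_bone(cortical, marrow, cfg)
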