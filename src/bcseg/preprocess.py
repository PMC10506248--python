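"""Slice preprocessing: HU windowing, adaptive median filtering, z-score.

The three steps run in that fixed order. Windowing clamps intensities to a
target-specific Hounsfield range (it does not rescale, preserving HU
semantics until normalization removes scale anyway). The adaptive median
filter is the classical variant that grows its aperture per pixel until the
window median is no longer an impulse, which suppresses salt-and-pepper
noise while leaving smooth structure untouched. Normalization is image-wise
z-score with the population (ddof=0) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import CTSlice, slice_type_of_target

#: Final HU windows per slice, with the override used for the skeletal-muscle
#: and spine-bone-marrow targets.
SLICE_WINDOWS = {
    "liver": (-25, 125),
    "abdomen": (-219, 190),
    "thigh": (-198, 189),
}
OVERRIDE_WINDOW = (-181, 216)
OVERRIDE_TARGETS = ("skeleton_muscle", "spine_bone_marrow")


@dataclass(frozen=True)
class HUWindow:
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"window lo must be < hi, got [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class PreprocessConfig:
    window: HUWindow
    amf_max_window: int = 7
    eps: float = 1e-8

    def __post_init__(self):
        _check_aperture(self.amf_max_window)
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    @classmethod
    def for_target(cls, target: str, **kw) -> "PreprocessConfig":
        return cls(window=default_window(target), **kw)


def _check_aperture(w: int) -> None:
    if w < 3 or w % 2 == 0:
        raise ValueError(f"adaptive-median aperture must be an odd integer >= 3, got {w}")


def default_window(target: str) -> HUWindow:
    """The HU window of the slice a segmentation target lives on.

    Skeletal-muscle and spine-bone-marrow use their own wider window.
    """
    if target in OVERRIDE_TARGETS:
        return HUWindow(*OVERRIDE_WINDOW)
    stype = slice_type_of_target(target)   # raises KeyError for unknown targets
    return HUWindow(*SLICE_WINDOWS[stype.value])


def hu_window(slc: CTSlice, window: HUWindow) -> CTSlice:
    """Clamp every pixel to [window.lo, window.hi]."""
    return CTSlice(np.clip(slc.pixels, window.lo, window.hi),
                   slc.slice_type, slc.spacing)


def adaptive_median(slc: CTSlice, max_window: int = 7) -> CTSlice:
    """Adaptive median filter with growing aperture (3 up to ``max_window``).

    Per pixel: starting at aperture 3, if the aperture median lies strictly
    between the aperture min and max ("stage B"), output the pixel itself
    when the pixel also lies strictly between min and max, else the median;
    otherwise grow the aperture and repeat; if the largest aperture is still
    degenerate, output its median. Borders are reflect-padded.
    """
    _check_aperture(max_window)
    x = np.asarray(slc.pixels, dtype=np.float64)
    out = np.empty_like(x)
    undecided = np.ones(x.shape, dtype=bool)
    pmax = max_window // 2
    xp = np.pad(x, pmax, mode="reflect")
    for w in range(3, max_window + 1, 2):
        off = pmax - w // 2
        win = sliding_window_view(xp[off:xp.shape[0] - off, off:xp.shape[1] - off], (w, w))
        win = win.reshape(x.shape + (w * w,))
        med = np.median(win, axis=-1)
        wmin = win.min(axis=-1)
        wmax = win.max(axis=-1)
        stage_b = (med > wmin) & (med < wmax)
        decide = undecided & stage_b
        keep = decide & (x > wmin) & (x < wmax)
        out[keep] = x[keep]
        out[decide & ~keep] = med[decide & ~keep]
        undecided &= ~decide
        if w == max_window:
            out[undecided] = med[undecided]
        if not undecided.any():
            break
    if np.issubdtype(slc.pixels.dtype, np.integer):
        out = np.round(out).astype(slc.pixels.dtype)
    return CTSlice(out, slc.slice_type, slc.spacing)


def zscore(slc: CTSlice, eps: float = 1e-8) -> np.ndarray:
    """Image-wise z-score; an (almost) constant image maps to all zeros."""
    x = np.asarray(slc.pixels, dtype=np.float64)
    sd = x.std()
    if sd <= eps:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def preprocess(slc: CTSlice, cfg: PreprocessConfig) -> np.ndarray:
    """window -> adaptive median -> z-score; returns the model-input grid."""
    return zscore(adaptive_median(hu_window(slc, cfg.window), cfg.amf_max_window), cfg.eps)
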