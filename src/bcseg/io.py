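"""Reading and writing CT slices and binary masks.

Formats and conventions
-----------------------
* NIfTI (``.nii`` / ``.nii.gz``): slices stored as int16 HU, masks as uint8
  {0, 1}. A singleton third dimension is squeezed on read.
* 16-bit PNG: PNG cannot store negatives, so slice pixels are stored as
  ``HU + 1024`` (fixed convention, no sidecar) and decoded back on read.
* 8-bit PNG masks: {0, 255} on disk, {0, 1} in memory.
* DICOM (single-frame CT): read-only; the rescale transform
  ``HU = slope * stored + intercept`` is applied on read.

Write-then-read is the identity for integral-HU slices and for masks.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from PIL import Image

from .types import BinaryMask, CTSlice, SliceType

PNG_HU_OFFSET = 1024


class FormatError(ValueError):
    """File could not be parsed in any supported format."""


class DimensionalityError(ValueError):
    """Volume has more than one non-singleton slice."""


def _squeeze_2d(arr: np.ndarray) -> np.ndarray:
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise DimensionalityError(
            f"expected a single 2-D slice, got shape {arr.shape} after squeezing")
    return arr


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz") or name.endswith(".nii"):
        return "nifti"
    if name.endswith(".png"):
        return "png"
    if name.endswith(".dcm") or name.endswith(".dicom"):
        return "dicom"
    raise FormatError(f"unrecognized file extension: {path.name}")


# ---------------------------------------------------------------------------
# slices
# ---------------------------------------------------------------------------

def read_slice(path, slice_type) -> CTSlice:
    """Read a CT slice (NIfTI, 16-bit PNG, or single-frame DICOM) as HU."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kind = _suffix(path)
    spacing = None
    if kind == "nifti":
        try:
            img = nib.load(str(path))
        except Exception as exc:
            raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
        arr = _squeeze_2d(np.asanyarray(img.dataobj))
        zooms = img.header.get_zooms()[:2]
        spacing = (float(zooms[0]), float(zooms[1]))
    elif kind == "png":
        try:
            with Image.open(path) as im:
                stored = np.array(im)
        except Exception as exc:
            raise FormatError(f"cannot read PNG {path}: {exc}") from exc
        arr = _squeeze_2d(stored.astype(np.int32)) - PNG_HU_OFFSET
    else:  # dicom
        try:
            ds = pydicom.dcmread(str(path))
            stored = ds.pixel_array
        except Exception as exc:
            raise FormatError(f"cannot read DICOM {path}: {exc}") from exc
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = _squeeze_2d(stored).astype(np.float64) * slope + intercept
        if np.allclose(arr, np.round(arr)):
            arr = np.round(arr).astype(np.int32)
        if hasattr(ds, "PixelSpacing"):
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return CTSlice(arr, SliceType.coerce(slice_type), spacing)


def write_slice(slc: CTSlice, path) -> None:
    """Write a slice as int16 NIfTI or offset-encoded 16-bit PNG."""
    path = Path(path)
    kind = _suffix(path)
    if kind == "nifti":
        img = nib.Nifti1Image(np.asarray(slc.pixels, dtype=np.int16), np.eye(4))
        if slc.spacing is not None:
            img.header.set_zooms(slc.spacing)
        nib.save(img, str(path))
    elif kind == "png":
        stored = np.asarray(slc.pixels, dtype=np.int64) + PNG_HU_OFFSET
        if stored.min() < 0 or stored.max() > np.iinfo(np.uint16).max:
            raise ValueError("HU range not representable with the +1024 PNG offset")
        Image.fromarray(stored.astype(np.uint16)).save(path)
    else:
        raise FormatError("DICOM writing is not supported; use NIfTI or PNG")


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def read_mask(path, label: str = "mask") -> BinaryMask:
    """Read a mask; stored values must be {0,1} or {0,255}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kind = _suffix(path)
    if kind == "nifti":
        try:
            arr = _squeeze_2d(np.asanyarray(nib.load(str(path)).dataobj))
        except DimensionalityError:
            raise
        except Exception as exc:
            raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    elif kind == "png":
        try:
            with Image.open(path) as im:
                arr = _squeeze_2d(np.array(im))
        except DimensionalityError:
            raise
        except Exception as exc:
            raise FormatError(f"cannot read PNG {path}: {exc}") from exc
    else:
        raise FormatError("masks are stored as PNG or NIfTI only")
    values = np.unique(arr)
    on_value = values.max() if values.size and values.max() > 0 else 1
    if on_value not in (1, 255) or not np.all(np.isin(values, (0, on_value))):
        raise ValueError(f"mask {path} is not binary: found values {values[:10]}")
    return BinaryMask(arr == on_value if on_value else np.zeros_like(arr, bool), label=label)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as 8-bit PNG ({0,255}) or NIfTI ({0,1})."""
    path = Path(path)
    kind = _suffix(path)
    if kind == "png":
        Image.fromarray(np.where(mask.pixels, 255, 0).astype(np.uint8)).save(path)
    elif kind == "nifti":
        nib.save(nib.Nifti1Image(mask.pixels.astype(np.uint8), np.eye(4)), str(path))
    else:
        raise FormatError("masks are stored as PNG or NIfTI only")
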