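"""Grayscale image I/O and median-filter preprocessing.

Images are plain 2-D float64 arrays with intensities in [0, 1]
(row-major, 0-based (row, col) addressing).  Loading rescales by the
source format's full dynamic range (255 for 8-bit, 65535 for 16-bit),
so the downstream pipeline is independent of the stored bit depth.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

__all__ = [
    "FormatError",
    "MedianParams",
    "validate_image",
    "load_image",
    "load_nifti_slice",
    "load_dicom_slice",
    "save_mask",
    "save_image",
    "median_filter",
]

#: mapping from the public border-mode names to scipy.ndimage modes
_BORDER_MODES = {"replicate": "nearest", "reflect": "reflect"}


class FormatError(ValueError):
    """Raised when a raster cannot be interpreted as a grayscale image."""


@dataclasses.dataclass(frozen=True)
class MedianParams:
    """Square-window median filter configuration.

    Parameters
    ----------
    window:
        Odd side length of the square neighborhood.  An odd window gives
        an odd pixel count, so the median is always a single order
        statistic (even windows are rejected rather than averaged).
    border_mode:
        ``"replicate"`` (repeat edge pixels, the default — it never
        invents intensities) or ``"reflect"`` (mirror across the edge).
    """

    window: int = 3
    border_mode: str = "replicate"

    def __post_init__(self) -> None:
        if not isinstance(self.window, (int, np.integer)) or self.window < 1:
            raise ValueError(f"window must be a positive integer, got {self.window!r}")
        if self.window % 2 == 0:
            raise ValueError(f"window must be odd, got {self.window}")
        if self.border_mode not in _BORDER_MODES:
            raise ValueError(
                f"border_mode must be one of {sorted(_BORDER_MODES)}, got {self.border_mode!r}"
            )


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check that ``image`` is a finite 2-D [0, 1] intensity field."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]")
    return arr


def _rescale_to_unit(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer/float raster to [0, 1] by its dtype's full range."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if arr.dtype == np.int32:  # PIL mode "I" holding 16-bit data
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise FormatError(f"unsupported raster dtype {arr.dtype}")


def load_image(path: str | os.PathLike, format: str | None = None, *, allow_color: bool = False) -> np.ndarray:
    """Load a PNG/TIFF raster as a [0, 1] float64 grayscale image.

    Parameters
    ----------
    path:
        File to read.
    format:
        Optional explicit format name ("png" or "tiff"); inferred from
        the suffix when omitted.
    allow_color:
        Convert multi-channel images with the ITU-R 601 luma transform
        instead of raising :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("tif", "tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 3:
            if not allow_color:
                raise FormatError(f"{path} is multi-channel; pass allow_color=True to convert")
            arr = arr @ np.array([0.299, 0.587, 0.114])
    else:
        with Image.open(path) as im:
            if im.mode in ("RGB", "RGBA", "P"):
                if not allow_color:
                    raise FormatError(f"{path} is multi-channel; pass allow_color=True to convert")
                im = im.convert("L")
            elif im.mode == "I;16":
                im = im.convert("I")
            arr = np.asarray(im)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel raster, got shape {arr.shape}")
    return validate_image(_rescale_to_unit(arr))


def load_nifti_slice(path: str | os.PathLike, slice_index: int) -> np.ndarray:
    """Extract one axial slice from a NIfTI volume, rescaled to [0, 1]."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if vol.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got shape {vol.shape}")
    if not 0 <= slice_index < vol.shape[2]:
        raise ValueError(f"slice_index {slice_index} out of range [0, {vol.shape[2]})")
    sl = vol[:, :, slice_index]
    lo, hi = sl.min(), sl.max()
    return validate_image((sl - lo) / (hi - lo) if hi > lo else np.zeros_like(sl))


def load_dicom_slice(path: str | os.PathLike) -> np.ndarray:
    """Read a single DICOM slice, applying rescale slope/intercept."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = arr.min(), arr.max()
    return validate_image((arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr))


def save_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a {0,1} mask as an 8-bit PNG with values {0, 255}.

    Round-trips bit-exactly through :func:`load_image` (255 -> 1.0).
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    Image.fromarray((mask.astype(np.uint8) * 255)).save(Path(path), format="PNG")


def save_image(image: np.ndarray, path: str | os.PathLike, *, bit_depth: int = 16) -> None:
    """Write a [0, 1] image as an 8- or 16-bit PNG."""
    image = validate_image(image)
    if bit_depth == 8:
        Image.fromarray(np.round(image * 255).astype(np.uint8)).save(Path(path), format="PNG")
    elif bit_depth == 16:
        arr = np.round(image * 65535).astype(np.uint16)
        Image.fromarray(arr).save(Path(path), format="PNG")
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")


def median_filter(image: np.ndarray, params: MedianParams = MedianParams()) -> np.ndarray:
    """Exact square-window median filter.

    Each output pixel is the median of the ``window x window``
    neighborhood centered on it, with the configured border extension.
    The median is an order statistic, so the output range is contained
    in the input range and constant images are fixed points.
    """
    image = validate_image(image)
    return ndimage.median_filter(image, size=params.window, mode=_BORDER_MODES[params.border_mode])
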