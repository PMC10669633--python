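"""Loading, grayscale conversion, and square cropping of OCT B-scan exports.

OCT devices commonly export B-scans as 24-bit RGB TIFFs (the Triton exports
1024 x 992 px); the working representation downstream is an 8-bit grayscale
square raster.  Three steps get there: load the file, collapse the colour
channels with BT.601 luma weights, and crop the width symmetrically down to
the height.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from ._util import GrayImage, as_gray, quantize8

log = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


def load_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG B-scan into an 8-bit raster.

    Returns a 2-D array (grayscale) or an ``(H, W, 3)`` array (RGB).
    16-bit samples are rescaled to 8-bit by integer division by 257
    (65535 // 257 == 255, so the full range maps onto the full range).
    An alpha channel is dropped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(str(path))
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except OSError:
        raise
    except Exception as exc:  # wrap decoder-specific failures
        raise OSError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        log.warning("dropping alpha channel of %s", path)
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise OSError(f"unsupported image layout {arr.shape} in {path}")
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise OSError(f"unsupported sample type {arr.dtype} in {path}")
    return arr


def to_gray8(img: np.ndarray) -> GrayImage:
    """Convert a 1- or 3-channel 8-bit raster to 8-bit grayscale.

    Grayscale input passes through unchanged.  RGB collapses with the
    BT.601 luma weights 0.2989 R + 0.5870 G + 0.1140 B, rounded half away
    from zero.  Device exports are typically pseudo-grayscale (R = G = B),
    on which any normalized weights coincide.
    """
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        raise ValueError(f"expected uint8 samples, got {arr.dtype}")
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim == 3 and arr.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
        return quantize8(arr.astype(np.float64) @ w)
    raise ValueError(f"unsupported channel layout: shape {arr.shape}")


def crop_square(img: GrayImage) -> GrayImage:
    """Crop a landscape B-scan to a height x height square.

    Columns are removed symmetrically: ``floor((W - H) / 2)`` from the left
    and the remainder from the right, keeping a fovea-centred scan centred.
    A 1024 x 992 export therefore keeps columns 16..1007.
    """
    arr = as_gray(img)
    h, w = arr.shape
    if w < h:
        raise ValueError(
            f"image is taller ({h}) than wide ({w}); B-scans are landscape — "
            "inspect orientation or transpose explicitly, this function never rotates"
        )
    left = (w - h) // 2
    return arr[:, left : left + h].copy()


def save_gray(img: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale raster as TIFF or PNG (by extension)."""
    arr = as_gray(img)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), arr)
    else:
        Image.fromarray(arr, mode="L").save(path)
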