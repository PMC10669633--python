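"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

GrayImage = np.ndarray
"""2-D ``uint8`` raster; row index is depth into tissue, column is lateral position."""


def quantize8(values: np.ndarray) -> np.ndarray:
    """Round to the nearest integer (halves away from zero) and clip to [0, 255].

    All 8-bit re-quantization in the pipeline goes through this single
    function so that results are bit-identical across platforms.  On the
    non-negative range produced by clipping, half-away-from-zero coincides
    with ``floor(x + 0.5)``.
    """
    return np.clip(np.floor(np.asarray(values, dtype=np.float64) + 0.5), 0, 255).astype(np.uint8)


def as_gray(img: np.ndarray) -> np.ndarray:
    """Validate that ``img`` is a 2-D 8-bit grayscale raster and return it."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected uint8 samples, got {arr.dtype}")
    return arr
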