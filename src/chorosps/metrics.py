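"""Per-eye choroid metrics: area, optical image density, and their ratio.

Three quantities summarize a segmented choroid:

* CA — choroidal area, the number of pixels in the region of interest (px^2);
* COID — choroidal optical image density, the mean 8-bit gray level over
  the region, kept at float precision;
* CD — choroidal density, the dimensionless ratio CA / COID.

COID is measured on the plain converted grayscale scan, not on the
contrast-enhanced image used for clustering: histogram equalization is a
monotone remapping chosen per image, so gray levels after it no longer
compare across eyes, whereas the raw 8-bit level is the device's common
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import GrayImage, as_gray
from .segmentation import ChoroidMask


@dataclass(frozen=True)
class ChoroidMetrics:
    ca: int
    coid: float
    cd: float

    def __str__(self) -> str:  # display rounded to 2 dp; stored values stay exact
        return f"CA={self.ca} px^2, COID={self.coid:.2f}, CD={self.cd:.2f}"


def choroid_area(mask: ChoroidMask) -> int:
    """Number of pixels in the segmented region (px^2)."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    return int(m.sum())


def choroid_optical_image_density(img: GrayImage, mask: ChoroidMask) -> float:
    """Arithmetic mean gray level over the masked pixels, in float."""
    arr = as_gray(img)
    m = np.asarray(mask, dtype=bool)
    if arr.shape != m.shape:
        raise ValueError(f"shape mismatch: image {arr.shape} vs mask {m.shape}")
    if not m.any():
        raise ValueError("empty mask")
    return float(arr[m].astype(np.float64).mean())


def choroid_density(ca: float, coid: float) -> float:
    """CD = CA / COID, dimensionless."""
    if coid <= 0:
        raise ValueError("undefined density for zero-intensity region")
    return ca / coid


def compute_metrics(img: GrayImage, mask: ChoroidMask) -> ChoroidMetrics:
    """The consistent (CA, COID, CD) triple; CD from the unrounded COID."""
    ca = choroid_area(mask)
    coid = choroid_optical_image_density(img, mask)
    return ChoroidMetrics(ca=ca, coid=coid, cd=choroid_density(ca, coid))
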