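"""Denoising and contrast enhancement ahead of superpixel clustering.

Three stages, applied in a fixed order:

1. Gaussian low-pass filtering to attenuate speckle, the multiplicative
   granular noise inherent to coherent (OCT) imaging.
2. A frequency-domain median filter to suppress periodic power-line
   artifacts, which appear as isolated peaks in the 2-D spectrum: the
   log-magnitude spectrum is median-smoothed and the image is
   reconstructed from the filtered magnitude and the original phase.
   The DC bin and the axial-frequency column are held fixed — a B-scan's
   anatomy is layered, so its essential structure (the lateral-mean depth
   profile) lives on that column, while lateral periodic pickup lives on
   the orthogonal row and stays fully filterable.
3. Global histogram equalization to flatten the intensity histogram.

The pipeline's contract is 8-bit throughout: every stage re-quantizes its
output with half-away-from-zero rounding so that runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._util import GrayImage, as_gray, quantize8

_LOG_EPS = 1e-12  # floor under the magnitude before taking logs


@dataclass(frozen=True)
class PreprocessParams:
    """Knobs for the denoising chain.

    gaussian_sigma
        Standard deviation of the spatial Gaussian in pixels (0 disables).
    spectral_median_window
        Odd side length of the median window applied to the log-magnitude
        spectrum.
    equalize
        Whether to apply global histogram equalization last.
    """

    gaussian_sigma: float = 1.5
    spectral_median_window: int = 3
    equalize: bool = True

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.spectral_median_window < 3 or self.spectral_median_window % 2 == 0:
            raise ValueError("spectral_median_window must be odd and >= 3")


def gaussian_lowpass(img: GrayImage, sigma: float) -> GrayImage:
    """Convolve with a normalized Gaussian kernel of radius ceil(3*sigma).

    Boundary handling is reflective; ``sigma = 0`` is the identity.
    """
    arr = as_gray(img)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return arr.copy()
    out = ndimage.gaussian_filter(
        arr.astype(np.float64), sigma=sigma, mode="reflect", radius=math.ceil(3 * sigma)
    )
    return quantize8(out)


def spectral_median_filter(img: GrayImage, window: int = 3) -> GrayImage:
    """Median-smooth the log-magnitude spectrum; keep phase; pin DC and
    the axial-frequency column.

    A pure-tone stripe artifact concentrates its energy in an isolated
    pair of spectral bins; the median of each bin's window replaces such
    peaks with the local (much lower) background level, while broadband
    spectral content — ordinary image texture — is nearly a fixed point
    of the median.  Purely layered structure is *not* broadband: it
    concentrates on the axial-frequency (zero-lateral-frequency) column,
    which a 2-D median would wipe out, so that column is held fixed along
    with DC.  Lateral power-frequency pickup sits at zero axial frequency
    and nonzero lateral frequency — disjoint from the protected column —
    and is removed in full.  Pinning DC preserves the image mean exactly
    before re-quantization.
    """
    arr = as_gray(img)
    h, w = arr.shape
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 3 or window >= min(h, w):
        raise ValueError("window must be >= 3 and smaller than the image side")

    spectrum = np.fft.fft2(arr.astype(np.float64))
    magnitude = np.abs(spectrum)
    # The DFT is periodic, so a wrap-mode median window is the natural
    # neighbourhood; no fftshift needed.
    log_mag = np.log(magnitude + _LOG_EPS)
    filtered = ndimage.median_filter(log_mag, size=window, mode="wrap")
    new_mag = np.exp(filtered) - _LOG_EPS
    new_mag[:, 0] = magnitude[:, 0]  # axial-frequency column (and DC) pinned

    phase = np.exp(1j * np.angle(spectrum))
    recon = np.fft.ifft2(new_mag * phase).real
    return quantize8(recon)


def equalize_histogram(img: GrayImage) -> GrayImage:
    """Global histogram equalization by the cumulative-distribution mapping.

    ``T(v) = round(255 * (cdf(v) - cdf_min) / (N - cdf_min))`` with
    ``cdf_min`` the count of the lowest occupied gray level.  T is monotone
    non-decreasing, so pixel ordering is preserved; a constant image maps to
    a constant.
    """
    arr = as_gray(img)
    counts = np.bincount(arr.ravel(), minlength=256)
    cdf = np.cumsum(counts)
    n = arr.size
    cdf_min = cdf[np.nonzero(counts)[0][0]]
    if n == cdf_min:  # single occupied level: equalization is the identity
        return arr.copy()
    transfer = quantize8(255.0 * (cdf - cdf_min) / (n - cdf_min))
    return transfer[arr]


def preprocess(img: GrayImage, params: PreprocessParams | None = None) -> GrayImage:
    """Run the full chain: Gaussian low-pass, spectral median, equalization."""
    params = params or PreprocessParams()
    out = gaussian_lowpass(img, params.gaussian_sigma)
    out = spectral_median_filter(out, params.spectral_median_window)
    if params.equalize:
        out = equalize_histogram(out)
    return out
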