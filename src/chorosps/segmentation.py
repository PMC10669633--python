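"""Grouping selected superpixels into the choroidal region of interest.

The delineation protocol is semi-automatic: after superpixelation an
expert picks the numbered superpixels covering the choroid, and the union
of the chosen labels becomes the region of interest.  For batch runs and
testing, :func:`auto_select_band` stands in for the expert with a simple
surrogate: pick every superpixel whose mean gray level and depth fall in
a band characteristic of the choroid (optionally measured relative to the
bright retinal pigment epithelium, which makes the rule robust to a
tilted retina).

Connectivity convention: 4-connectivity everywhere (components,
boundaries, orphan merging).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._util import GrayImage, as_gray
from .superpixel import SuperpixelMap

log = logging.getLogger(__name__)

ChoroidMask = np.ndarray
"""Boolean raster marking the segmented choroidal region of interest."""

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class BandCriteria:
    """Surrogate selection rule standing in for the supervising expert.

    intensity_range
        Closed gray-level interval [lo, hi] the superpixel's mean must fall in,
        measured on the image passed to :func:`auto_select_band` (conventionally
        the unenhanced grayscale scan, so the range speaks the raw-intensity
        language of the tissue).
    depth_range
        Closed row interval [lo, hi] for the superpixel centroid.  When
        ``anchor`` is given the centroid row is taken relative to the anchor
        row of the centroid's column.
    anchor
        Optional per-column reference row profile, e.g. the depth of the
        brightest (RPE) band from :func:`rpe_anchor_profile`.
    """

    intensity_range: tuple[float, float]
    depth_range: tuple[float, float]
    anchor: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.intensity_range[0] > self.intensity_range[1]:
            raise ValueError("intensity_range must satisfy lo <= hi")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range must satisfy lo <= hi")


@dataclass(frozen=True)
class RegionProps:
    """Area, centroid, bounding box and component count of a mask."""

    area: int
    centroid: tuple[float, float]
    bounding_box: tuple[int, int, int, int]  # (top, left, height, width)
    n_components: int


def select_superpixels(sp: SuperpixelMap, chosen: list[int]) -> ChoroidMask:
    """Union of the pixels of the chosen superpixel labels.

    Duplicate ids are ignored (set semantics); unknown ids raise.
    """
    if not chosen:
        raise ValueError("no superpixels selected")
    k = sp.n_labels
    ids = sorted(set(int(c) for c in chosen))
    bad = [i for i in ids if i < 1 or i > k]
    if bad:
        raise ValueError(f"unknown superpixel ids {bad}; valid range is 1..{k}")
    return np.isin(sp.labels, ids)


def rpe_anchor_profile(img: GrayImage, smooth_cols: int = 15) -> np.ndarray:
    """Per-column row index of the brightest band (the hyper-reflective RPE).

    Columns are smoothed laterally with a uniform window before the
    per-column argmax so isolated bright speckle does not hijack the anchor.
    """
    arr = as_gray(img).astype(np.float64)
    sm = ndimage.uniform_filter1d(arr, size=max(1, smooth_cols), axis=1, mode="nearest")
    return np.argmax(sm, axis=0)


def auto_select_band(
    sp: SuperpixelMap, img: GrayImage, criteria: BandCriteria
) -> list[int]:
    """Labels whose mean intensity and centroid depth match the criteria.

    Mean intensity is computed per label on ``img`` (not on whatever image
    the superpixels were clustered on).  Returns a sorted list; empty with
    a logged warning when nothing matches.
    """
    arr = as_gray(img)
    if arr.shape != sp.labels.shape:
        raise ValueError(f"shape mismatch: image {arr.shape} vs labels {sp.labels.shape}")
    k = sp.n_labels
    flat = sp.labels.ravel()
    counts = np.bincount(flat, minlength=k + 1)[1:]
    sums = np.bincount(flat, weights=arr.ravel().astype(np.float64), minlength=k + 1)[1:]
    means = sums / np.maximum(counts, 1)

    h, w = arr.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    cent_r = np.bincount(flat, weights=rr.ravel(), minlength=k + 1)[1:] / np.maximum(counts, 1)
    cent_c = np.bincount(flat, weights=cc.ravel(), minlength=k + 1)[1:] / np.maximum(counts, 1)

    depth = cent_r.copy()
    if criteria.anchor is not None:
        anchor = np.asarray(criteria.anchor, dtype=np.float64)
        if anchor.shape != (w,):
            raise ValueError(f"anchor must have one row per column ({w}), got {anchor.shape}")
        depth = cent_r - anchor[np.clip(np.round(cent_c).astype(int), 0, w - 1)]

    ilo, ihi = criteria.intensity_range
    dlo, dhi = criteria.depth_range
    ok = (means >= ilo) & (means <= ihi) & (depth >= dlo) & (depth <= dhi) & (counts > 0)
    labels = sorted(np.nonzero(ok)[0] + 1)
    if not labels:
        log.warning("auto_select_band: no superpixel matched the criteria")
    return [int(x) for x in labels]


def region_properties(mask: ChoroidMask) -> RegionProps:
    """Area, centroid, tight bounding box and 4-connected component count."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    rows, cols = np.nonzero(m)
    top, left = int(rows.min()), int(cols.min())
    height = int(rows.max()) - top + 1
    width = int(cols.max()) - left + 1
    _, n_comp = ndimage.label(m, structure=_FOUR_CONN)
    return RegionProps(
        area=int(m.sum()),
        centroid=(float(rows.mean()), float(cols.mean())),
        bounding_box=(top, left, height, width),
        n_components=int(n_comp),
    )


def boundary_pixels(mask: ChoroidMask) -> np.ndarray:
    """Mask pixels with at least one 4-neighbour outside the mask.

    The image frame counts as outside, so a component touching the edge is
    bounded there too.
    """
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return m & ~interior


# Moore-neighbourhood scan order for a clockwise trace (dr, dc), starting
# east and turning clockwise from the backtrack direction.
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _trace_component(comp_mask: np.ndarray) -> np.ndarray:
    """Clockwise Moore boundary trace of one 4-connected component.

    The trace follows the outer boundary starting from the top-left-most
    pixel; the returned path is filtered to the 4-neighbour boundary pixel
    set, keeping first occurrences, so the contour contains exactly the
    outer boundary pixels in traversal order.
    """
    rows, cols = np.nonzero(comp_mask)
    start = (int(rows[0]), int(cols[0]))  # nonzero scans row-major: top-left-most
    if len(rows) == 1:
        return np.array([start])

    h, w = comp_mask.shape

    def inside(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and comp_mask[r, c]

    contour = [start]
    # backtrack starts pointing west of the start pixel (outside by choice of start)
    prev_dir = 6  # index of (0, -1) in _MOORE
    cur = start
    while True:
        found = False
        # start scanning one step clockwise from the backtrack direction
        for step in range(1, 9):
            d = (prev_dir + step) % 8
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if inside(nr, nc):
                # new backtrack: direction pointing back toward cur's side
                prev_dir = (d + 4) % 8
                # bias the next scan to resume just past the backtrack
                cur = (nr, nc)
                found = True
                break
        if not found:  # isolated pixel (cannot happen: handled above)
            break
        if cur == start and len(contour) > 1:
            break
        contour.append(cur)

    outer = boundary_pixels(comp_mask)
    seen: set[tuple[int, int]] = set()
    ordered = []
    for p in contour:
        if outer[p] and p not in seen:
            seen.add(p)
            ordered.append(p)
    return np.array(ordered)


def extract_boundary(mask: ChoroidMask) -> list[np.ndarray]:
    """Ordered outer contour of each 4-connected component.

    Returns one ``(n, 2)`` array of (row, col) per component, traced
    clockwise from the top-left-most boundary pixel.  Boundaries of
    interior holes are not traced.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    comp, n_comp = ndimage.label(m, structure=_FOUR_CONN)
    return [_trace_component(comp == i) for i in range(1, n_comp + 1)]
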