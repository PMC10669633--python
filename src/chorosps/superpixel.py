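"""Deterministic grayscale SLIC superpixel clustering.

SLIC (simple linear iterative clustering) is a grid-seeded, locally
windowed k-means in a joint intensity/position space.  This variant is
single-channel: the distance between pixel p and cluster centre k is

    D^2 = d_I^2 + (d_xy / S)^2 * m^2

with d_I the intensity difference to the cluster's mean gray level, d_xy
the Euclidean pixel distance to the cluster centroid, S the seeding grid
interval sqrt(N / K), and m the compactness weight trading intensity
fidelity against spatial regularity.

Everything is deterministic: seeds on a fixed grid, seed perturbation to
the lowest-gradient position in a 3x3 neighbourhood with row-major
tie-breaking, assignment ties broken by the lowest centre index, and all
per-cluster accumulations performed in row-major order so results are
bit-identical across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from ._util import GrayImage, as_gray


@dataclass(frozen=True)
class SuperpixelParams:
    """SLIC parameters: cluster count, iteration count, compactness m.

    Defaults (400 superpixels, 10 iterations, m = 10) give superpixels
    roughly 50 px across on a 992 x 992 B-scan — coarse enough that one
    label is a meaningful patch of tissue, fine enough to follow the
    choroid's irregular boundaries.
    """

    n_superpixels: int = 400
    iterations: int = 10
    compactness: float = 10.0

    def __post_init__(self) -> None:
        if self.n_superpixels < 1:
            raise ValueError("n_superpixels must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.compactness <= 0:
            raise ValueError("compactness must be > 0")


@dataclass
class SuperpixelMap:
    """A labelled partition of an image into superpixels.

    labels
        Integer raster, same shape as the source image, values 1..K.
    grid_interval
        The seeding interval S = sqrt(N / K_requested), kept because the
        connectivity-enforcement orphan threshold is S^2 / 4.
    centroids
        ``(K, 3)`` array of per-label (row, col, mean intensity).
    """

    labels: np.ndarray
    grid_interval: float
    centroids: np.ndarray = field(repr=False)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @classmethod
    def from_labels(
        cls, labels: np.ndarray, img: GrayImage | None = None
    ) -> "SuperpixelMap":
        """Wrap an existing 1..K label raster (e.g. a hand-built fixture)."""
        labels = np.asarray(labels, dtype=np.int64)
        if labels.min() < 1:
            raise ValueError("labels must start at 1")
        img_f = (
            as_gray(img).astype(np.float64)
            if img is not None
            else np.zeros(labels.shape, dtype=np.float64)
        )
        interval = math.sqrt(labels.size / int(labels.max()))
        return cls(labels=labels, grid_interval=interval, centroids=_centroids(labels, img_f))

    def label_sizes(self) -> np.ndarray:
        """Pixel count per label, index 0 unused (labels start at 1)."""
        return np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)


def _seed_centers(img_f: np.ndarray, interval: float) -> np.ndarray:
    """Grid-seed cluster centres and nudge each to its local gradient minimum.

    Returns an ``(K, 3)`` float array of (row, col, intensity).  The grid is
    ``max(1, floor(H/S)) x max(1, floor(W/S))`` so K never exceeds the
    requested count.
    """
    h, w = img_f.shape
    rows = max(1, int(h / interval))
    cols = max(1, int(w / interval))

    gy, gx = np.gradient(img_f)
    grad = gy * gy + gx * gx

    centers = []
    for i in range(rows):
        for j in range(cols):
            r = int((i + 0.5) * h / rows)
            c = int((j + 0.5) * w / cols)
            # lowest-gradient position in the 3x3 neighbourhood; scan order
            # (row-major) breaks ties on the first minimum
            best = (r, c)
            best_g = math.inf
            for rr in range(max(0, r - 1), min(h, r + 2)):
                for cc in range(max(0, c - 1), min(w, c + 2)):
                    if grad[rr, cc] < best_g:
                        best_g = grad[rr, cc]
                        best = (rr, cc)
            centers.append((float(best[0]), float(best[1]), float(img_f[best])))
    return np.asarray(centers, dtype=np.float64)


def slic_segment(img: GrayImage, params: SuperpixelParams | None = None) -> SuperpixelMap:
    """Partition a grayscale image into superpixels.

    Each iteration assigns every pixel within a window of reach 2S around
    a centre to the centre minimizing D (ties to the lowest centre index,
    comparisons on D^2), then
    recomputes each centre as its cluster's mean (row, col, intensity).
    Labels are renumbered 1..K at the end, dropping empty clusters.

    The label raster is not guaranteed connected; run
    :func:`enforce_connectivity` afterwards for the partition invariant.
    """
    arr = as_gray(img)
    params = params or SuperpixelParams()
    h, w = arr.shape
    n = h * w
    if params.n_superpixels > n:
        raise ValueError(f"n_superpixels={params.n_superpixels} exceeds pixel count {n}")

    interval = math.sqrt(n / params.n_superpixels)
    img_f = arr.astype(np.float64)
    centers = _seed_centers(img_f, interval)
    k = len(centers)
    m2_over_s2 = (params.compactness * params.compactness) / (interval * interval)

    rr_full, cc_full = np.mgrid[0:h, 0:w].astype(np.float64)

    # initial assignment: grid cell of the seed lattice (guarantees every
    # pixel is labelled even if a window misses it)
    rows = max(1, int(h / interval))
    cols = max(1, int(w / interval))
    cell_r = np.minimum((np.arange(h) * rows) // h, rows - 1)
    cell_c = np.minimum((np.arange(w) * cols) // w, cols - 1)
    labels = (cell_r[:, None] * cols + cell_c[None, :]).astype(np.int64)

    for _ in range(params.iterations):
        dist2 = np.full((h, w), np.inf)
        new_labels = labels.copy()
        reach = 2.0 * interval  # search window: pixels within 2S of the centre
        for ki in range(k):
            cr, cc, ci = centers[ki]
            r_lo = max(0, int(cr - reach))
            r_hi = min(h, int(cr + reach) + 1)
            c_lo = max(0, int(cc - reach))
            c_hi = min(w, int(cc + reach) + 1)
            if r_lo >= r_hi or c_lo >= c_hi:
                continue
            patch = img_f[r_lo:r_hi, c_lo:c_hi]
            dr = rr_full[r_lo:r_hi, c_lo:c_hi] - cr
            dc = cc_full[r_lo:r_hi, c_lo:c_hi] - cc
            di = patch - ci
            d2 = di * di + (dr * dr + dc * dc) * m2_over_s2
            better = d2 < dist2[r_lo:r_hi, c_lo:c_hi]
            dist2[r_lo:r_hi, c_lo:c_hi][better] = d2[better]
            new_labels[r_lo:r_hi, c_lo:c_hi][better] = ki
        labels = new_labels

        flat = labels.ravel()
        counts = np.bincount(flat, minlength=k)
        sum_r = np.bincount(flat, weights=rr_full.ravel(), minlength=k)
        sum_c = np.bincount(flat, weights=cc_full.ravel(), minlength=k)
        sum_i = np.bincount(flat, weights=img_f.ravel(), minlength=k)
        occupied = counts > 0
        centers[occupied, 0] = sum_r[occupied] / counts[occupied]
        centers[occupied, 1] = sum_c[occupied] / counts[occupied]
        centers[occupied, 2] = sum_i[occupied] / counts[occupied]

    # renumber to 1..K in centre-index order, dropping empty clusters
    counts = np.bincount(labels.ravel(), minlength=k)
    remap = np.zeros(k, dtype=np.int64)
    remap[counts > 0] = np.arange(1, int((counts > 0).sum()) + 1)
    labels = remap[labels]
    return SuperpixelMap(
        labels=labels, grid_interval=interval, centroids=_centroids(labels, img_f)
    )


def _centroids(labels: np.ndarray, img_f: np.ndarray) -> np.ndarray:
    """(row, col, mean intensity) per label, labels assumed 1..K."""
    k = int(labels.max())
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=k + 1)[1:]
    h, w = labels.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    sum_r = np.bincount(flat, weights=rr.ravel(), minlength=k + 1)[1:]
    sum_c = np.bincount(flat, weights=cc.ravel(), minlength=k + 1)[1:]
    sum_i = np.bincount(flat, weights=img_f.ravel(), minlength=k + 1)[1:]
    with np.errstate(invalid="ignore"):
        out = np.stack([sum_r / counts, sum_c / counts, sum_i / counts], axis=1)
    return out


def enforce_connectivity(sp: SuperpixelMap, img: GrayImage | None = None) -> SuperpixelMap:
    """Split disconnected labels and absorb orphan fragments.

    Every 4-connected component of the label raster becomes its own label;
    components smaller than S^2 / 4 pixels are merged into the largest
    4-adjacent neighbouring component (ties to the smallest component id).
    Final labels are renumbered 1..K in row-major order of first
    appearance, so each label's pixel set is 4-connected by construction.
    """
    labels = sp.labels
    min_size = sp.grid_interval * sp.grid_interval / 4.0
    comp = measure.label(labels, connectivity=1)
    n_comp = int(comp.max())
    sizes = np.bincount(comp.ravel(), minlength=n_comp + 1)

    # adjacency over 4-neighbour pairs
    neighbours: dict[int, set[int]] = {i: set() for i in range(1, n_comp + 1)}
    for a, b in (
        (comp[:, :-1].ravel(), comp[:, 1:].ravel()),
        (comp[:-1, :].ravel(), comp[1:, :].ravel()),
    ):
        diff = a != b
        for x, y in zip(a[diff].tolist(), b[diff].tolist()):
            neighbours[x].add(y)
            neighbours[y].add(x)

    # union-find over components; merge small ones smallest-first
    parent = list(range(n_comp + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merged_sizes = sizes.astype(np.int64).copy()
    pending = sorted(
        (i for i in range(1, n_comp + 1) if sizes[i] < min_size),
        key=lambda i: (sizes[i], i),
    )
    for c in pending:
        root = find(c)
        if merged_sizes[root] >= min_size:
            continue
        nbr_roots = {find(x) for x in neighbours[c]} - {root}
        if not nbr_roots:
            continue
        target = max(nbr_roots, key=lambda r: (merged_sizes[r], -r))
        parent[root] = target
        merged_sizes[target] += merged_sizes[root]
        neighbours[target] |= neighbours[c]

    roots = np.array([find(i) for i in range(n_comp + 1)], dtype=np.int64)
    merged = roots[comp]

    # renumber by row-major first appearance
    _, first = np.unique(merged.ravel(), return_index=True)
    order = np.argsort(first)
    remap = np.zeros(n_comp + 1, dtype=np.int64)
    for new, old in enumerate(np.unique(merged.ravel())[order], start=1):
        remap[old] = new
    out = remap[merged]

    img_f = (
        as_gray(img).astype(np.float64)
        if img is not None
        else np.zeros(labels.shape, dtype=np.float64)
    )
    return SuperpixelMap(
        labels=out, grid_interval=sp.grid_interval, centroids=_centroids(out, img_f)
    )


# --- visualization -------------------------------------------------------

# 3x5 bitmap digits for centroid label rendering (no font dependencies,
# byte-identical output everywhere)
_DIGITS = {
    "0": ["111", "101", "101", "101", "111"],
    "1": ["010", "110", "010", "010", "111"],
    "2": ["111", "001", "111", "100", "111"],
    "3": ["111", "001", "111", "001", "111"],
    "4": ["101", "101", "111", "001", "001"],
    "5": ["111", "100", "111", "001", "111"],
    "6": ["111", "100", "111", "101", "111"],
    "7": ["111", "001", "010", "010", "010"],
    "8": ["111", "101", "111", "101", "111"],
    "9": ["111", "101", "111", "001", "111"],
}


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Pixels having at least one 4-neighbour with a different label."""
    b = np.zeros(labels.shape, dtype=bool)
    b[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    b[:, 1:] |= labels[:, :-1] != labels[:, 1:]
    b[:-1, :] |= labels[:-1, :] != labels[1:, :]
    b[1:, :] |= labels[:-1, :] != labels[1:, :]
    return b


def overlay_labels(img: GrayImage, sp: SuperpixelMap) -> np.ndarray:
    """Render superpixel boundaries and label numbers over the image.

    Returns an ``(H, W, 3)`` uint8 RGB raster: source image in gray,
    boundaries in yellow, the numeric label at each centroid in red.  The
    image frame is always drawn so a single-label map still shows its
    extent.  Purely a visualization aid for supervised label selection;
    nothing downstream consumes it.
    """
    arr = as_gray(img)
    if arr.shape != sp.labels.shape:
        raise ValueError(f"shape mismatch: image {arr.shape} vs labels {sp.labels.shape}")
    rgb = np.stack([arr] * 3, axis=2).copy()
    b = boundary_mask(sp.labels)
    b[0, :] = b[-1, :] = True
    b[:, 0] = b[:, -1] = True
    rgb[b] = (255, 255, 0)
    h, w = arr.shape
    for lab in range(1, sp.n_labels + 1):
        r, c = sp.centroids[lab - 1, 0], sp.centroids[lab - 1, 1]
        text = str(lab)
        width = 4 * len(text) - 1
        r0 = int(round(r)) - 2
        c0 = int(round(c)) - width // 2
        for i, ch in enumerate(text):
            glyph = _DIGITS[ch]
            for dr in range(5):
                for dc in range(3):
                    if glyph[dr][dc] == "1":
                        rr2, cc2 = r0 + dr, c0 + 4 * i + dc
                        if 0 <= rr2 < h and 0 <= cc2 < w:
                            rgb[rr2, cc2] = (255, 32, 32)
    return rgb
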