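"""Independent brute-force grayscale SLIC for cross-checking small instances.

Plain-Python loops, no windowing: every pixel is compared against every
cluster centre each round, using the same distance
``D^2 = d_I^2 + (d_xy^2 / S^2) * m^2``, the same grid seeding with 3x3
lowest-gradient perturbation, lowest-index tie-breaking, and cluster-mean
updates, iterated to convergence.  Only practical for tiny images.
"""

import math

import numpy as np


def _gradient_sq(img_f):
    """Squared gradient magnitude with np.gradient's conventions
    (central differences inside, one-sided at the borders)."""
    h, w = img_f.shape
    g = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            if 0 < r < h - 1:
                gy = (img_f[r + 1, c] - img_f[r - 1, c]) / 2.0
            elif r == 0:
                gy = img_f[1, c] - img_f[0, c]
            else:
                gy = img_f[r, c] - img_f[r - 1, c]
            if 0 < c < w - 1:
                gx = (img_f[r, c + 1] - img_f[r, c - 1]) / 2.0
            elif c == 0:
                gx = img_f[r, 1] - img_f[r, 0]
            else:
                gx = img_f[r, c] - img_f[r, c - 1]
            g[r, c] = gy * gy + gx * gx
    return g


def brute_force_slic(img, n_superpixels, compactness, max_rounds=200):
    """Return a 1..K label raster by exhaustive assignment to convergence."""
    img_f = np.asarray(img, dtype=np.float64)
    h, w = img_f.shape
    n = h * w
    interval = math.sqrt(n / n_superpixels)
    rows = max(1, int(h / interval))
    cols = max(1, int(w / interval))
    grad = _gradient_sq(img_f)

    centers = []
    for i in range(rows):
        for j in range(cols):
            r = int((i + 0.5) * h / rows)
            c = int((j + 0.5) * w / cols)
            best, best_g = (r, c), math.inf
            for rr in range(max(0, r - 1), min(h, r + 2)):
                for cc in range(max(0, c - 1), min(w, c + 2)):
                    if grad[rr, cc] < best_g:
                        best_g = grad[rr, cc]
                        best = (rr, cc)
            centers.append([float(best[0]), float(best[1]), float(img_f[best])])

    k = len(centers)
    m2_over_s2 = (compactness * compactness) / (interval * interval)
    labels = np.zeros((h, w), dtype=np.int64)
    for _ in range(max_rounds):
        new_labels = np.zeros((h, w), dtype=np.int64)
        for r in range(h):
            for c in range(w):
                best_k, best_d = 0, math.inf
                for ki in range(k):
                    cr, cc, ci = centers[ki]
                    di = img_f[r, c] - ci
                    d2 = di * di + ((r - cr) * (r - cr) + (c - cc) * (c - cc)) * m2_over_s2
                    if d2 < best_d:
                        best_d = d2
                        best_k = ki
                new_labels[r, c] = best_k
        # cluster-mean updates, accumulated in row-major order
        sums = [[0.0, 0.0, 0.0, 0] for _ in range(k)]
        for r in range(h):
            for c in range(w):
                s = sums[new_labels[r, c]]
                s[0] += r
                s[1] += c
                s[2] += img_f[r, c]
                s[3] += 1
        for ki in range(k):
            if sums[ki][3]:
                centers[ki] = [
                    sums[ki][0] / sums[ki][3],
                    sums[ki][1] / sums[ki][3],
                    sums[ki][2] / sums[ki][3],
                ]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels

    # renumber occupied clusters to 1..K in centre-index order
    occupied = sorted(set(labels.ravel().tolist()))
    remap = {old: new for new, old in enumerate(occupied, start=1)}
    out = np.zeros((h, w), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            out[r, c] = remap[labels[r, c]]
    return out
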