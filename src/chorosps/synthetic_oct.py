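"""Seeded synthetic OCT B-scans with ground-truth choroid masks.

A real B-scan of the posterior eye is, from top to bottom: dark vitreous,
brighter neuroretina, a thin hyper-reflective retinal pigment epithelium
(RPE) band, the darker textured choroid containing hypo-reflective vessel
lumina, and the sclera below.  The generator emulates exactly that layered
geometry plus the three nuisance effects the preprocessing chain targets:

* multiplicative speckle, modelled as unit-mean gamma noise with L looks
  (``I' = I * g``, ``g ~ Gamma(L, 1/L)``) — the standard coherent-imaging
  speckle model;
* an additive horizontal sinusoidal stripe emulating a power-line
  artifact;
* a linear retinal tilt (column-wise vertical shear), the acquisition
  posture issue segmentation must be robust to.

The ground-truth mask is the exact choroid band, vessels included —
the anatomical choroid encompasses both stroma and vessel lumina — taken
before any noise, and ``true_COID`` is the mean of the noise-free image
over that mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from ._util import quantize8
from .segmentation import ChoroidMask
from ._util import GrayImage


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic B-scan.

    layer_rows are the four interface depths (vitreous/retina, retina/RPE,
    RPE/choroid, choroid/sclera) as fractions of the height; the defaults
    put a 0.20 H-thick choroid band in the lower half of the frame, with
    band gray levels matching the qualitative reflectivity ordering of the
    tissues (RPE brightest, vitreous darkest, choroid darker than sclera).
    """

    size: int = 496
    layer_rows: tuple[float, float, float, float] = (0.20, 0.50, 0.55, 0.75)
    layer_intensities: tuple[float, float, float, float, float] = (10, 120, 210, 60, 90)
    vessel_count: int = 12
    vessel_radius_range: tuple[float, float] = (4.0, 12.0)
    vessel_intensity: float = 30.0
    speckle_looks: float | None = None  # None = speckle off
    artifact_amplitude: float = 0.0
    artifact_period: float = 32.0
    tilt_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        rows = self.layer_rows
        if not all(0 < a < 1 for a in rows) or any(
            rows[i] >= rows[i + 1] for i in range(3)
        ):
            raise ValueError("layer_rows must be strictly increasing fractions in (0, 1)")
        if not all(0 <= v <= 255 for v in self.layer_intensities):
            raise ValueError("layer_intensities must lie in [0, 255]")
        if self.speckle_looks is not None and self.speckle_looks < 1:
            raise ValueError("speckle_looks must be >= 1 (or None for off)")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")
        if self.vessel_radius_range[0] > self.vessel_radius_range[1]:
            raise ValueError("vessel_radius_range must satisfy lo <= hi")
        if self.artifact_period <= 0:
            raise ValueError("artifact_period must be > 0")


@dataclass
class SyntheticScan:
    """A generated B-scan with its ground truth."""

    image: GrayImage
    choroid_mask: ChoroidMask
    true_ca: int
    true_coid: float
    spec: SyntheticSpec = field(repr=False)


def generate_bscan(spec: SyntheticSpec) -> SyntheticScan:
    """Render one seeded synthetic B-scan.

    Construction order (all randomness from ``spec.seed``): layered bands
    with the column-wise tilt shear, vessel ellipses inside the choroid
    band, ground truth recorded, then speckle, stripe artifact, clipping
    and 8-bit quantization.
    """
    h = w = spec.size
    rng = np.random.default_rng(spec.seed)

    interfaces = np.array([_round_half_up(f * h) for f in spec.layer_rows])
    if spec.tilt_px and w > 1:
        shift = np.array(
            [_round_half_up(spec.tilt_px * c / (w - 1)) for c in range(w)]
        )
    else:
        shift = np.zeros(w, dtype=int)

    rows = np.arange(h)[:, None] - shift[None, :]  # depth in the sheared frame
    band = np.searchsorted(interfaces, rows, side="right")  # 0..4
    intensities = np.asarray(spec.layer_intensities, dtype=np.float64)
    clean = intensities[band]

    mask = (rows >= interfaces[2]) & (rows < interfaces[3])

    # vessel lumina: dark ellipses fully parameterized by the seeded rng,
    # clipped to the choroid band so the ground-truth mask stays the band
    band_height = interfaces[3] - interfaces[2]
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(spec.vessel_count):
        c0 = rng.uniform(0, w)
        depth = rng.uniform(0.15, 0.85)  # keep centres away from band edges
        a = rng.uniform(*spec.vessel_radius_range)  # lateral semi-axis
        b = rng.uniform(*spec.vessel_radius_range)  # axial semi-axis
        col_idx = min(w - 1, int(c0))
        r0 = interfaces[2] + depth * band_height + shift[col_idx]
        ellipse = ((rr - r0) / b) ** 2 + ((cc - c0) / a) ** 2 <= 1.0
        clean[ellipse & mask] = spec.vessel_intensity

    true_ca = int(mask.sum())
    true_coid = float(clean[mask].mean()) if true_ca else 0.0

    noisy = clean
    if spec.speckle_looks is not None and math.isfinite(spec.speckle_looks):
        looks = spec.speckle_looks
        # speckle is generated in tissue coordinates and sheared with the
        # structure: the pattern arises from the tissue microstructure, so
        # a tilted acquisition of the same eye carries the same speckle,
        # displaced along with the layers (rows wrap at the frame edge)
        g = rng.gamma(shape=looks, scale=1.0 / looks, size=(h, w))
        noisy = noisy * np.take_along_axis(g, rows % h, axis=0)
    if spec.artifact_amplitude:
        stripe = spec.artifact_amplitude * np.sin(
            2 * np.pi * np.arange(w) / spec.artifact_period
        )
        noisy = noisy + stripe[None, :]

    return SyntheticScan(
        image=quantize8(noisy),
        choroid_mask=mask,
        true_ca=true_ca,
        true_coid=true_coid,
        spec=spec,
    )


def shrink_choroid(spec: SyntheticSpec, fraction: float) -> SyntheticSpec:
    """Spec with the choroid band thinned symmetrically by ``fraction``."""
    r = spec.layer_rows
    half = fraction * (r[3] - r[2]) / 2.0
    return replace(spec, layer_rows=(r[0], r[1], r[2] + half, r[3] - half))


def table_direction_deltas(
    base: SyntheticSpec | None = None,
    ms_shrink: float = 0.10,
    pd_shrink: float = 0.20,
    ms_coid_shift: float = 5.0,
    pd_coid_shift: float = 10.0,
) -> dict[str, SyntheticSpec]:
    """Group specs encoding the disease-effect directions: thinner choroid
    band (smaller CA) and brighter choroid (higher COID) in MS, more so in
    Parkinson disease, relative to controls."""
    base = base or SyntheticSpec()

    def brighten(spec: SyntheticSpec, delta: float) -> SyntheticSpec:
        li = list(spec.layer_intensities)
        li[3] = min(255.0, li[3] + delta)
        return replace(spec, layer_intensities=tuple(li))

    return {
        "control": base,
        "MS": brighten(shrink_choroid(base, ms_shrink), ms_coid_shift),
        "PD": brighten(shrink_choroid(base, pd_shrink), pd_coid_shift),
    }


def simulate_cohort(
    n_per_group: int,
    group_specs: Mapping[str, SyntheticSpec],
    seed: int,
    depth_jitter_sd: float = 0.01,
    intensity_jitter_sd: float = 3.0,
) -> list[tuple[str, SyntheticScan]]:
    """Generate a labelled cohort of scans with per-subject variability.

    Each subject's spec jitters the group spec's interface depths
    (``N(0, depth_jitter_sd)`` in height fractions, order preserved by
    construction of the sd scale) and band intensities (``N(0,
    intensity_jitter_sd)`` gray levels), with a fresh sub-seed per subject.
    Fully reproducible from ``seed``.  An empty mapping simulates nothing.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    master = np.random.default_rng(seed)
    out: list[tuple[str, SyntheticScan]] = []
    for group, spec in group_specs.items():
        for _ in range(n_per_group):
            sub_seed = int(master.integers(0, 2**31 - 1))
            jit = np.random.default_rng(sub_seed)
            rows = np.array(spec.layer_rows) + jit.normal(0, depth_jitter_sd, size=4)
            rows = np.clip(rows, 0.01, 0.98)
            # restore strict ordering if an extreme draw crossed interfaces
            rows = np.maximum.accumulate(rows) + np.arange(4) * 1e-6
            li = np.clip(
                np.array(spec.layer_intensities)
                + jit.normal(0, intensity_jitter_sd, size=5),
                0,
                255,
            )
            subject = replace(
                spec,
                layer_rows=tuple(float(x) for x in rows),
                layer_intensities=tuple(float(x) for x in li),
                seed=sub_seed,
            )
            out.append((group, generate_bscan(subject)))
    return out
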