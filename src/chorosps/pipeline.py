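"""End-to-end processing: conversion, enhancement, superpixels, selection,
metrics — with per-run provenance.

The five-stage chain per image: (1) grayscale conversion and square crop;
(2) denoising and contrast enhancement; (3) superpixel clustering;
(4) choroid selection — either a user-supplied label list (the supervised
protocol) or the band-criteria surrogate; (5) metric computation on the
unenhanced cropped scan.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import GrayImage
from .io_conversion import crop_square, load_image, save_gray, to_gray8
from .metrics import ChoroidMetrics, compute_metrics
from .preprocess import PreprocessParams, preprocess
from .segmentation import (
    BandCriteria,
    auto_select_band,
    rpe_anchor_profile,
    select_superpixels,
)
from .superpixel import SuperpixelParams, enforce_connectivity, overlay_labels, slic_segment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """How the choroid superpixels are picked.

    mode "labels": ``labels`` holds the expert's chosen superpixel ids.
    mode "band": the surrogate rule — mean raw gray level within
    ``intensity_range`` and centroid depth within ``depth_range`` (rows,
    relative to the per-column RPE anchor when ``use_rpe_anchor``).
    """

    mode: str = "band"
    labels: tuple[int, ...] = ()
    intensity_range: tuple[float, float] = (40.0, 80.0)
    depth_range: tuple[float, float] = (5.0, 200.0)
    use_rpe_anchor: bool = True

    def __post_init__(self) -> None:
        if self.mode not in {"labels", "band"}:
            raise ValueError(f"selection mode must be 'labels' or 'band', got {self.mode!r}")
        if self.mode == "labels" and not self.labels:
            raise ValueError("mode 'labels' needs a non-empty label list")


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    superpixel: SuperpixelParams = field(default_factory=SuperpixelParams)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    output_dir: Path = Path("chorosps_out")
    seed: int = 0
    save_intermediates: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise OSError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def tupled(d: dict) -> dict:
            return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

        kwargs: dict = {}
        if "preprocess" in raw:
            kwargs["preprocess"] = PreprocessParams(**raw["preprocess"])
        if "superpixel" in raw:
            kwargs["superpixel"] = SuperpixelParams(**raw["superpixel"])
        if "selection" in raw:
            kwargs["selection"] = SelectionConfig(**tupled(raw["selection"]))
        for key in ("output_dir", "seed", "save_intermediates"):
            if key in raw:
                kwargs[key] = Path(raw[key]) if key == "output_dir" else raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(self.output_dir)
        return d


@dataclass
class ProcessResult:
    eye_id: str
    metrics: ChoroidMetrics
    selected_labels: list[int]
    mask: np.ndarray = field(repr=False)
    n_superpixels: int = 0


def process_image(gray: GrayImage, config: PipelineConfig) -> ProcessResult:
    """Run stages 1b-5 on an already-loaded grayscale raster."""
    cropped = crop_square(gray)
    enhanced = preprocess(cropped, config.preprocess)
    sp = enforce_connectivity(slic_segment(enhanced, config.superpixel), enhanced)

    sel = config.selection
    if sel.mode == "labels":
        chosen = list(sel.labels)
    else:
        anchor = rpe_anchor_profile(cropped) if sel.use_rpe_anchor else None
        criteria = BandCriteria(
            intensity_range=sel.intensity_range,
            depth_range=sel.depth_range,
            anchor=anchor,
        )
        chosen = auto_select_band(sp, cropped, criteria)
        if not chosen:
            raise ValueError("band criteria selected no superpixels")

    mask = select_superpixels(sp, chosen)
    metrics = compute_metrics(cropped, mask)
    return ProcessResult(
        eye_id="",
        metrics=metrics,
        selected_labels=chosen,
        mask=mask,
        n_superpixels=sp.n_labels,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_process(
    config: PipelineConfig, image_paths: Sequence[str | Path]
) -> tuple[pd.DataFrame, int]:
    """Process a batch of scans; returns (metrics table, failure count).

    Writes ``metrics.csv`` plus one JSON provenance sidecar per image under
    ``config.output_dir``.  Per-image failures are logged and skipped.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    failures = 0
    for path in image_paths:
        path = Path(path)
        eye_id = path.stem
        try:
            gray = to_gray8(load_image(path))
            result = process_image(gray, config)
        except Exception as exc:
            failures += 1
            log.error("failed to process %s: %s", path, exc)
            continue
        m = result.metrics
        rows.append(
            {"eye_id": eye_id, "CA_px2": m.ca, "COID": m.coid, "CD": m.cd}
        )
        sidecar = {
            "eye_id": eye_id,
            "input": str(path),
            "input_sha256": _sha256(path),
            "software": f"chorosps {__version__}",
            "config": config.to_dict(),
            "selected_labels": result.selected_labels,
            "n_superpixels": result.n_superpixels,
            "metrics": {"CA_px2": m.ca, "COID": m.coid, "CD": m.cd},
        }
        (out_dir / f"{eye_id}.json").write_text(json.dumps(sidecar, indent=2))
        if config.save_intermediates:
            save_gray((result.mask * 255).astype(np.uint8), out_dir / f"{eye_id}_mask.png")
    table = pd.DataFrame(rows, columns=["eye_id", "CA_px2", "COID", "CD"])
    table.to_csv(out_dir / "metrics.csv", index=False, float_format="%.6f")
    return table, failures


def save_overlay(gray: GrayImage, config: PipelineConfig, path: str | Path) -> None:
    """Write the numbered-superpixel overlay used for supervised selection."""
    from PIL import Image

    cropped = crop_square(gray)
    enhanced = preprocess(cropped, config.preprocess)
    sp = enforce_connectivity(slic_segment(enhanced, config.superpixel), enhanced)
    Image.fromarray(overlay_labels(cropped, sp), mode="RGB").save(path)
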