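"""End-to-end runs: proximal single-image mode and aerial orthomosaic mode.

Proximal images (tripod/pole, ~1.6-2.2 m AGL) are processed fully
automatically: radiometric correction (when a panel is given) -> canopy
segmentation -> flower-candidate thresholding -> morphology and
canopy-adjacency noise removal -> features.  Aerial orthomosaics are
processed semi-automatically: the user supplies the four field corners and
grid shape, the plots are interpolated, and features come from each plot's
edge-trimmed ROI.  Either mode can swap the threshold path for the k-means
path; outputs are schema-identical so downstream analysis is
method-agnostic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster import KMeansSpec, kmeans_flower_mask
from .grid import PlotGridSpec, interpolate_plot_grid, per_plot_features
from .noise import denoise_report
from .raster import (
    PanelSpec,
    RasterImage,
    load_image,
    radiometric_correct,
    save_mask,
    save_overlay,
)
from .rules import CropSensorProfile, segment_canopy, segment_flower_candidates
from .stats import flowers_percentage

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs; CLI flags override YAML which overrides defaults."""

    mode: str  # proximal | aerial | simulate
    profile: str = "pea"  # built-in crop name or a YAML path
    method: str = "threshold"  # threshold | kmeans
    inputs: list[str] = field(default_factory=list)
    output_dir: str = "floralquant_out"
    panel: PanelSpec | None = None
    grid: PlotGridSpec | None = None
    kmeans: KMeansSpec = field(default_factory=KMeansSpec)
    ring_width: int = 1
    connectivity: int = 8
    seed: int = 0

    def load_profile(self) -> CropSensorProfile:
        p = Path(self.profile)
        if p.suffix in (".yaml", ".yml") and p.exists():
            return CropSensorProfile.from_yaml(p)
        return CropSensorProfile.builtin(self.profile)


def _write_manifest(config: RunConfig, outdir: Path, extra: dict | None = None) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items()}
        return str(o)

    manifest = {
        "floralquant_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        **(extra or {}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_default))


def process_image(
    img: RasterImage,
    profile: CropSensorProfile,
    method: str = "threshold",
    panel: PanelSpec | None = None,
    kmeans_spec: KMeansSpec | None = None,
    ring_width: int = 1,
    connectivity: int = 8,
):
    """Single-image pipeline: returns (flower_mask, canopy_mask, report_df).

    With a panel the image is radiometrically corrected first and the
    profile's reflectance-scale rules apply; without one the raw_8bit rules
    apply directly.  The k-means path performs no noise removal (flower
    area is its only feature), so its report is empty.
    """
    if panel is not None:
        img = radiometric_correct(img, panel)
    canopy = segment_canopy(img, profile)
    if method == "kmeans":
        flowers = kmeans_flower_mask(img, kmeans_spec or KMeansSpec(), profile.kmeans_color_rule)
        report = pd.DataFrame(
            columns=["label", "area_px", "axis_ratio", "solidity", "kept", "drop_reason"]
        )
    elif method == "threshold":
        candidates = segment_flower_candidates(img, profile)
        flowers, report = denoise_report(
            candidates, canopy, profile.morphology,
            connectivity=connectivity, ring_width=ring_width,
        )
    else:
        raise ValueError("method must be 'threshold' or 'kmeans'")
    return flowers, canopy, report


def run_proximal(config: RunConfig) -> pd.DataFrame:
    """Process every input image; write masks, overlays and a feature CSV.

    Per-image failures are logged and skipped; the run fails only if no
    image succeeds.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile = config.load_profile()
    paths = [Path(p) for p in config.inputs]
    if not paths:
        raise ValueError("proximal mode needs at least one input image")
    rows = []
    for path in paths:
        try:
            img = load_image(path)
            flowers, canopy, report = process_image(
                img, profile, method=config.method, panel=config.panel,
                kmeans_spec=config.kmeans, ring_width=config.ring_width,
                connectivity=config.connectivity,
            )
        except Exception:
            log.exception("failed to process %s; skipping", path)
            continue
        stem = path.stem
        save_mask(flowers, outdir / f"{stem}_flowers.png")
        save_mask(canopy, outdir / f"{stem}_canopy.png")
        save_overlay(img, flowers, outdir / f"{stem}_overlay.png")
        if len(report):
            report.to_csv(outdir / f"{stem}_components.csv", index=False)
        rows.append(
            {
                "image": path.name,
                "flower_area_px": int(flowers.sum()),
                "canopy_area_px": int((canopy | flowers).sum()),
                "flowers_pct": flowers_percentage(flowers, canopy),
            }
        )
        log.info("%s: flower_area=%d flowers_pct=%.2f", path.name,
                 rows[-1]["flower_area_px"], rows[-1]["flowers_pct"])
    if not rows:
        raise RuntimeError("all input images failed to process")
    features = pd.DataFrame(rows)
    features.to_csv(outdir / "features.csv", index=False)
    _write_manifest(config, outdir, {"n_images": len(rows)})
    return features


def run_aerial(config: RunConfig) -> pd.DataFrame:
    """Orthomosaic mode: plot-grid interpolation then per-plot ROI features."""
    if config.grid is None:
        raise ValueError("aerial mode needs a plot-grid spec (four corners)")
    if len(config.inputs) != 1:
        raise ValueError("aerial mode takes exactly one orthomosaic image")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile = config.load_profile()
    img = load_image(config.inputs[0])
    if config.panel is not None:
        img = radiometric_correct(img, config.panel)
    cells = interpolate_plot_grid(config.grid)
    records = per_plot_features(
        img, cells, profile, method=config.method,
        kmeans_spec=config.kmeans, ring_width=config.ring_width,
    )
    features = pd.DataFrame([asdict(r) for r in records])
    features.to_csv(outdir / "plot_features.csv", index=False)
    flowers, canopy, _ = process_image(
        img, profile, method=config.method, kmeans_spec=config.kmeans,
        ring_width=config.ring_width, connectivity=config.connectivity,
    )
    save_overlay(img, flowers, outdir / "orthomosaic_overlay.png")
    _write_manifest(config, outdir, {"n_plots": len(records)})
    return features
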