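"""Synthetic field scenes with exact pixel-level ground truth.

Real plot photographs come with no per-pixel truth; every pipeline stage is
therefore exercised on generated scenes that emulate the imaging situation:
green crop canopy on brown soil, white (pea/chickpea-like) or yellow
(canola/camelina-like) flower ellipses growing *on* the canopy, plus the
noise classes the thresholds are known to admit — elongated wheat-straw
lines and bright soil glints lying *off* the canopy — and optionally a
bright reference panel for radiometric correction.

Archetype colors are chosen so the published white-flower rule
(R,G,B > 200, G-R <= 20) and the green-canopy rule (a* < -13) classify every
painted class unambiguously: canopy (40,130,50) has a* = -43.6, soil
(120,85,60) has a* = +11.3, and flowers/straw/glints all pass the flower
color rule (so straw and glints must be removed by shape and canopy
adjacency, exactly as in the field).  Every pixel of every object class is
recorded, so detected areas can be compared to truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as _skdraw

from .grid import PlotCell, PlotGridSpec, interpolate_plot_grid, rasterize_polygon
from .raster import RAW_8BIT, PanelSpec, RasterImage

WHITE_FLOWER = (230, 230, 230)
YELLOW_FLOWER = (230, 210, 40)


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed under the requested constraints."""


@dataclass
class SceneParams:
    """Knobs of one synthetic proximal plot image.

    Colors are 8-bit RGB; ``canopy_coverage`` is the target canopy fraction
    of the frame; ``illumination`` is a global gain emulating exposure or
    sun differences (undone by radiometric correction via the panel).
    """

    height: int = 200
    width: int = 200
    soil_color: tuple[int, int, int] = (120, 85, 60)
    canopy_color: tuple[int, int, int] = (40, 130, 50)
    canopy_coverage: float = 0.5
    flower_color: tuple[int, int, int] = WHITE_FLOWER
    flower_count: int = 30
    flower_radius: tuple[float, float] = (3.0, 5.0)
    straw_count: int = 0
    straw_length: tuple[int, int] = (15, 35)
    straw_color: tuple[int, int, int] = (220, 215, 205)
    glint_count: int = 0
    glint_radius: tuple[float, float] = (2.0, 3.0)
    glint_color: tuple[int, int, int] = (235, 230, 224)
    include_panel: bool = False
    panel_size: int = 20
    panel_value: int = 252
    panel_reflectance: float = 0.99
    illumination: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for c in (self.soil_color, self.canopy_color, self.flower_color,
                  self.straw_color, self.glint_color):
            if min(c) < 0 or max(c) > 255:
                raise ValueError("colors must be 8-bit RGB")
        if not (0 <= self.canopy_coverage <= 1):
            raise ValueError("canopy_coverage must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Exact painted-pixel record of a generated scene."""

    canopy_mask: np.ndarray
    flower_mask: np.ndarray
    flower_labels: np.ndarray  # 0 background, i>0 for flower i
    straw_mask: np.ndarray
    glint_mask: np.ndarray
    panel: PanelSpec | None = None
    flowers: list[dict] = field(default_factory=list)
    per_plot_flower_area: dict[int, int] = field(default_factory=dict)

    @property
    def flower_area_px(self) -> int:
        return int(self.flower_mask.sum())


def _disk_structure(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1), bool)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy * yy + xx * xx <= radius * radius


def _grow_canopy(
    shape: tuple[int, int],
    coverage: float,
    reserved: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Union of random ellipses approaching the target coverage fraction."""
    h, w = shape
    canopy = np.zeros(shape, bool)
    target = coverage * h * w
    r_lo, r_hi = max(6, min(h, w) // 12), max(10, min(h, w) // 4)
    for _ in range(600):
        if canopy.sum() >= target:
            break
        rc = rng.integers(0, h), rng.integers(0, w)
        radii = rng.uniform(r_lo, r_hi), rng.uniform(r_lo, r_hi)
        rr, cc = _skdraw.ellipse(
            rc[0], rc[1], radii[0], radii[1], shape=shape, rotation=rng.uniform(0, np.pi)
        )
        canopy[rr, cc] = True
        canopy &= ~reserved
    return canopy


def _place_flowers(
    canopy: np.ndarray,
    count: int,
    radius: tuple[float, float],
    rng: np.random.Generator,
    flower_mask: np.ndarray,
    flower_labels: np.ndarray,
    label_offset: int = 0,
) -> list[dict]:
    """Paint ``count`` elliptical flowers fully inside canopy, 3 px apart.

    Centers come from the canopy eroded by the maximal flower radius + 2, so
    every flower keeps a pure-canopy ring around it; flowers never touch
    each other (their unions would distort per-object shape statistics).
    """
    r_lo, r_hi = radius
    margin = int(np.ceil(r_hi)) + 4
    valid = ndimage.binary_erosion(canopy, structure=_disk_structure(margin))
    placed: list[dict] = []
    coords = np.argwhere(valid)
    if len(coords) == 0 and count > 0:
        raise PlacementError("no canopy region can host a flower of this size")
    for i in range(count):
        for attempt in range(500):
            r0, c0 = coords[rng.integers(len(coords))]
            a = rng.uniform(r_lo, r_hi)
            b = a * rng.uniform(0.75, 1.0)
            ok = all(
                (r0 - p["center"][0]) ** 2 + (c0 - p["center"][1]) ** 2
                >= (a + p["radii"][0] + 3) ** 2
                for p in placed
            )
            if not ok:
                continue
            rr, cc = _skdraw.ellipse(
                r0, c0, a, b, shape=flower_mask.shape, rotation=rng.uniform(0, np.pi)
            )
            flower_mask[rr, cc] = True
            flower_labels[rr, cc] = label_offset + i + 1
            placed.append(
                {"center": (int(r0), int(c0)), "radii": (float(a), float(b)),
                 "area_px": len(rr), "label": label_offset + i + 1}
            )
            break
        else:
            raise PlacementError(f"could not place flower {i + 1} of {count}")
    return placed


def generate_plot_image(params: SceneParams) -> tuple[RasterImage, GroundTruth]:
    """One proximal plot scene plus its exact ground truth.

    All randomness flows from ``params.seed``; the same parameters always
    produce a bit-identical image.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    shape = (h, w)
    img = np.tile(np.asarray(params.soil_color, float), (h, w, 1))

    panel: PanelSpec | None = None
    reserved = np.zeros(shape, bool)
    if params.include_panel:
        s = params.panel_size
        panel = PanelSpec(4, 4 + s, 4, 4 + s, params.panel_reflectance)
        reserved[: 4 + s + 6, : 4 + s + 6] = True  # soil buffer keeps panel off-canopy

    canopy = _grow_canopy(shape, params.canopy_coverage, reserved, rng)
    img[canopy] = params.canopy_color

    flower_mask = np.zeros(shape, bool)
    flower_labels = np.zeros(shape, np.int32)
    flowers = _place_flowers(
        canopy, params.flower_count, params.flower_radius, rng, flower_mask, flower_labels
    )
    img[flower_mask] = params.flower_color
    canopy = canopy & ~flower_mask  # truth = visibly green pixels

    # noise goes off-canopy with a >=3 px soil gap so the adjacency rule
    # (and not color) distinguishes it from true flowers
    off_canopy = ~ndimage.binary_dilation(
        canopy | flower_mask, structure=_disk_structure(3)
    ) & ~reserved
    off_canopy[:2, :] = off_canopy[-2:, :] = False
    off_canopy[:, :2] = off_canopy[:, -2:] = False

    straw_mask = np.zeros(shape, bool)
    straw_coords = np.argwhere(off_canopy)
    for i in range(params.straw_count):
        for attempt in range(500):
            if len(straw_coords) == 0:
                raise PlacementError("no off-canopy room for straw")
            r0, c0 = straw_coords[rng.integers(len(straw_coords))]
            length = int(rng.integers(params.straw_length[0], params.straw_length[1] + 1))
            ang = rng.uniform(0, np.pi)
            r1 = int(round(r0 + length * np.sin(ang)))
            c1 = int(round(c0 + length * np.cos(ang)))
            if not (0 <= r1 < h and 0 <= c1 < w):
                continue
            rr, cc = _skdraw.line(int(r0), int(c0), r1, c1)
            if not np.all(off_canopy[rr, cc] & ~straw_mask[rr, cc]):
                continue
            straw_mask[rr, cc] = True
            break
        else:
            raise PlacementError(f"could not place straw line {i + 1}")
    img[straw_mask] = params.straw_color

    glint_mask = np.zeros(shape, bool)
    for i in range(params.glint_count):
        for attempt in range(500):
            r0, c0 = straw_coords[rng.integers(len(straw_coords))]
            rad = rng.uniform(*params.glint_radius)
            rr, cc = _skdraw.disk((r0, c0), rad, shape=shape)
            if not np.all(off_canopy[rr, cc] & ~straw_mask[rr, cc] & ~glint_mask[rr, cc]):
                continue
            glint_mask[rr, cc] = True
            break
        else:
            raise PlacementError(f"could not place glint {i + 1}")
    img[glint_mask] = params.glint_color

    if panel is not None:
        rs, cs = panel.slices()
        img[rs, cs] = float(params.panel_value)

    img = np.clip(img * params.illumination, 0.0, 255.0)
    raster = RasterImage(img, bands=("R", "G", "B"), scale=RAW_8BIT)
    truth = GroundTruth(
        canopy_mask=canopy,
        flower_mask=flower_mask,
        flower_labels=flower_labels,
        straw_mask=straw_mask,
        glint_mask=glint_mask,
        panel=panel,
        flowers=flowers,
    )
    return raster, truth


def generate_orthomosaic(
    grid: PlotGridSpec,
    per_plot_flowers: Sequence[int],
    params: SceneParams | None = None,
    pad: int = 10,
) -> tuple[RasterImage, GroundTruth]:
    """A plot-grid orthomosaic with a known flower count in every plot.

    Each interpolated cell receives a canopy patch (cell trimmed by 8% per
    edge) and ``per_plot_flowers[i]`` flowers placed inside it; alleys and
    surround stay soil.  Ground truth records the exact per-plot areas.
    """
    params = params or SceneParams()
    cells = interpolate_plot_grid(grid)
    if len(per_plot_flowers) != len(cells):
        raise ValueError("need one flower count per plot cell")
    h = int(np.ceil(grid.corners[:, 1].max())) + pad
    w = int(np.ceil(grid.corners[:, 0].max())) + pad
    shape = (h, w)
    rng = np.random.default_rng(params.seed)
    img = np.tile(np.asarray(params.soil_color, float), (h, w, 1))
    canopy = np.zeros(shape, bool)
    flower_mask = np.zeros(shape, bool)
    flower_labels = np.zeros(shape, np.int32)
    truth = GroundTruth(
        canopy_mask=canopy,
        flower_mask=flower_mask,
        flower_labels=flower_labels,
        straw_mask=np.zeros(shape, bool),
        glint_mask=np.zeros(shape, bool),
    )
    inner = replace(grid, margin_frac=0.08)
    label_offset = 0
    for cell, inner_cell, n_fl in zip(cells, interpolate_plot_grid(inner), per_plot_flowers):
        cell_canopy = rasterize_polygon(inner_cell.roi_polygon, shape)
        canopy |= cell_canopy
        img[cell_canopy] = params.canopy_color
        placed = _place_flowers(
            cell_canopy, n_fl, params.flower_radius, rng, flower_mask, flower_labels,
            label_offset=label_offset,
        )
        label_offset += n_fl
        area = int(sum(p["area_px"] for p in placed))
        truth.per_plot_flower_area[cell.plot_id] = area
        truth.flowers.extend(placed)
    img[flower_mask] = params.flower_color
    canopy &= ~flower_mask  # truth = visibly green pixels
    raster = RasterImage(np.clip(img, 0, 255), bands=("R", "G", "B"), scale=RAW_8BIT)
    return raster, truth


def degrade_resolution(img: RasterImage, factor: int) -> RasterImage:
    """Block-mean downsampling emulating higher-altitude acquisition.

    A flower smaller than the block mixes spectrally with canopy/soil and
    stops passing its color rule — the mechanism that caps usable altitude
    for small-flowered crops.  ``gsd_mm`` (when set) is multiplied by the
    factor.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    h, w = img.shape
    if factor > min(h, w):
        raise ValueError("factor exceeds the image size")
    if factor == 1:
        return RasterImage(img.pixels.copy(), bands=img.bands, scale=img.scale, gsd_mm=img.gsd_mm)
    h2, w2 = h // factor, w // factor
    px = img.pixels[: h2 * factor, : w2 * factor]
    px = px.reshape(h2, factor, w2, factor, 3).mean(axis=(1, 3))
    gsd = img.gsd_mm * factor if img.gsd_mm is not None else None
    return RasterImage(px, bands=img.bands, scale=img.scale, gsd_mm=gsd)


def block_fraction(mask: np.ndarray, factor: int) -> np.ndarray:
    """Per-block true-pixel fraction of a mask under the same downsampling."""
    mask = np.asarray(mask, float)
    h2, w2 = mask.shape[0] // factor, mask.shape[1] // factor
    return mask[: h2 * factor, : w2 * factor].reshape(h2, factor, w2, factor).mean(axis=(1, 3))


def simulated_ratings(
    truth: GroundTruth,
    scale: str = "0-10",
    seed: int = 0,
    yield_noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Visual-rating and yield table matching an orthomosaic's ground truth.

    Ratings are the true per-plot flower areas rescaled onto the requested
    scale (0-10 or 0-100); yield is proportional to flower area with a
    little multiplicative noise, mimicking harvest data.
    """
    if not truth.per_plot_flower_area:
        raise ValueError("ground truth carries no per-plot areas (not an orthomosaic)")
    top = {"0-10": 10.0, "0-100": 100.0}[scale]
    rng = np.random.default_rng(seed)
    ids = sorted(truth.per_plot_flower_area)
    areas = np.array([truth.per_plot_flower_area[i] for i in ids], float)
    peak = areas.max() if areas.max() > 0 else 1.0
    return pd.DataFrame(
        {
            "plot_id": ids,
            "visual_rating": np.round(areas / peak * top, 1),
            "yield": np.round(areas * (1.0 + rng.normal(0, yield_noise_sd, len(ids))), 1),
        }
    )
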