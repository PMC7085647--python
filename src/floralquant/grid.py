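"""Plot separation from orthomosaics via four field corners.

Stitched field imagery is divided into breeding plots by bilinear
interpolation of a user-marked corner quadrilateral (top-left, top-right,
bottom-right, bottom-left, in pixel x/y coordinates) into an
``n_rows x n_cols`` grid.  Feature extraction then uses only the central
part of each plot: every cell is trimmed by ``margin_frac`` per edge so
that plot borders, alleys and neighbor spill-over stay out of the
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import draw as _skdraw

from .raster import RasterImage


class GeometryError(ValueError):
    """Degenerate or self-intersecting corner quadrilateral, or out-of-bounds cell."""


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _segments_intersect(p1, p2, p3, p4) -> bool:
    d1 = _cross(p3, p4, p1)
    d2 = _cross(p3, p4, p2)
    d3 = _cross(p1, p2, p3)
    d4 = _cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


@dataclass
class PlotGridSpec:
    """Four ordered field corners plus grid shape and edge-trim fractions.

    ``corners`` is a 4x2 array of (x, y) pixel coordinates in the order
    top-left, top-right, bottom-right, bottom-left.  ``margin_frac`` trims
    that fraction of each plot from every edge before feature extraction;
    ``alley_frac`` reserves an inter-plot gap of that fraction of the cell
    pitch on every cell side.
    """

    corners: np.ndarray
    n_rows: int
    n_cols: int
    margin_frac: float = 0.1
    alley_frac: float = 0.0
    serpentine: bool = False

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float)
        if self.corners.shape != (4, 2):
            raise GeometryError("corners must be a 4 x 2 array of (x, y) points")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("grid must have at least one row and one column")
        if not (0 <= self.margin_frac < 0.5):
            raise GeometryError("margin_frac must lie in [0, 0.5)")
        if not (0 <= self.alley_frac < 0.5):
            raise GeometryError("alley_frac must lie in [0, 0.5)")
        tl, tr, br, bl = self.corners
        # simple quadrilateral: opposite edges must not cross, corners not collinear
        if _segments_intersect(tl, tr, br, bl) or _segments_intersect(tr, br, bl, tl):
            raise GeometryError("corner quadrilateral is self-intersecting")
        area2 = abs(_cross(tl, tr, br)) + abs(_cross(tl, br, bl))
        if area2 < 1e-9:
            raise GeometryError("corners are collinear (degenerate quadrilateral)")

    def point(self, u: float | np.ndarray, v: float | np.ndarray) -> np.ndarray:
        """Bilinear map of unit-square (u, v) into the corner quadrilateral.

        u runs left->right along the top/bottom edges, v top->bottom.
        """
        tl, tr, br, bl = self.corners
        u = np.asarray(u, dtype=float)[..., None]
        v = np.asarray(v, dtype=float)[..., None]
        return (1 - v) * ((1 - u) * tl + u * tr) + v * ((1 - u) * bl + u * br)


@dataclass
class PlotCell:
    """One plot: full quadrilateral and its margin-trimmed ROI polygon."""

    plot_id: int
    row: int
    col: int
    polygon: np.ndarray  # 4 x 2 (x, y), TL TR BR BL order
    roi_polygon: np.ndarray


def interpolate_plot_grid(spec: PlotGridSpec) -> list[PlotCell]:
    """Divide the corner quadrilateral into ``n_rows x n_cols`` plot cells.

    Plot ids are serial starting at 1, row-major; with ``serpentine`` the
    column direction alternates per row (common field-book ordering).
    """
    cells: list[PlotCell] = []
    du, dv = 1.0 / spec.n_cols, 1.0 / spec.n_rows
    au, av = spec.alley_frac * du / 2.0, spec.alley_frac * dv / 2.0
    serial = 0
    for i in range(spec.n_rows):
        col_order = range(spec.n_cols)
        if spec.serpentine and i % 2 == 1:
            col_order = reversed(col_order)  # type: ignore[assignment]
        for j in col_order:
            serial += 1
            u0, u1 = j * du + au, (j + 1) * du - au
            v0, v1 = i * dv + av, (i + 1) * dv - av
            poly = np.vstack(
                [spec.point(u0, v0), spec.point(u1, v0), spec.point(u1, v1), spec.point(u0, v1)]
            )
            mu = spec.margin_frac * (u1 - u0)
            mv = spec.margin_frac * (v1 - v0)
            roi = np.vstack(
                [
                    spec.point(u0 + mu, v0 + mv),
                    spec.point(u1 - mu, v0 + mv),
                    spec.point(u1 - mu, v1 - mv),
                    spec.point(u0 + mu, v1 - mv),
                ]
            )
            cells.append(PlotCell(plot_id=serial, row=i, col=j, polygon=poly, roi_polygon=roi))
    return cells


def rasterize_polygon(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels inside an (x, y) polygon on an image of ``shape``."""
    rr, cc = _skdraw.polygon(polygon[:, 1], polygon[:, 0], shape=shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def extract_plot_roi(orthomosaic: RasterImage, cell: PlotCell) -> np.ndarray:
    """Rasterized margin-trimmed ROI mask for one plot cell."""
    h, w = orthomosaic.shape
    xy = cell.polygon
    if xy[:, 0].min() < -0.5 or xy[:, 1].min() < -0.5 or xy[:, 0].max() > w - 0.5 or xy[:, 1].max() > h - 0.5:
        raise GeometryError(f"plot {cell.plot_id} extends outside the orthomosaic")
    return rasterize_polygon(cell.roi_polygon, (h, w))


def per_plot_features(
    orthomosaic: RasterImage,
    cells: Sequence[PlotCell],
    profile,
    method: str = "threshold",
    kmeans_spec=None,
    ring_width: int = 1,
):
    """Flower area and flowers% of every plot cell, from whole-image masks.

    Canopy and flowers are segmented once on the full orthomosaic (threshold
    path with noise removal, or the k-means path) and then intersected with
    each cell's margin-trimmed ROI.  Returns a list of
    :class:`~floralquant.stats.PlotFeatureRecord`.
    """
    from . import cluster as _cluster
    from . import noise as _noise
    from . import rules as _rules
    from .stats import PlotFeatureRecord, flowers_percentage

    canopy = _rules.segment_canopy(orthomosaic, profile)
    if method == "threshold":
        candidates = _rules.segment_flower_candidates(orthomosaic, profile)
        flowers = _noise.denoise(candidates, canopy, profile.morphology, ring_width=ring_width)
    elif method == "kmeans":
        flowers = _cluster.kmeans_flower_mask(
            orthomosaic, kmeans_spec or _cluster.KMeansSpec(), profile.kmeans_color_rule
        )
    else:
        raise ValueError("method must be 'threshold' or 'kmeans'")

    records = []
    for cell in cells:
        roi = extract_plot_roi(orthomosaic, cell)
        roi_area = int(roi.sum())
        fl = int((flowers & roi).sum())
        cv = int(((canopy | flowers) & roi).sum())
        records.append(
            PlotFeatureRecord(
                plot_id=cell.plot_id,
                row=cell.row,
                col=cell.col,
                flower_area_px=fl,
                canopy_area_px=cv,
                flowers_pct=flowers_percentage(flowers, canopy, roi),
                roi_area_px=roi_area,
                empty_roi=roi_area == 0,
            )
        )
    return records
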