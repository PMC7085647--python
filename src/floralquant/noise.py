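"""Connected-component noise removal for flower-candidate masks.

Color thresholds alone admit non-flower objects — wheat straw, bare soil
glints, senescent leaves, cloth, poles — whose reflectance resembles white or
yellow petals.  Two per-component predicates remove them:

* morphology: a component must fall inside an area window, must not be too
  elongated (straw and stems have a high major/minor moment-ellipse axis
  ratio) and must be reasonably solid (area / convex-hull area);
* canopy adjacency: flowers grow on the crop, so a component is kept only if
  it touches or lies inside the canopy mask — its exterior pixel ring (the
  "peripheral pixels") must intersect canopy.

Both predicates are independent per-component keep/drop decisions, so their
composition order does not change the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .rules import MorphologyLimits


@dataclass
class ComponentRecord:
    """One connected component with the morphometrics the filters use."""

    label: int
    coords: np.ndarray  # (n, 2) row/col pixel coordinates
    area_px: int = 0
    major_axis: float = 0.0
    minor_axis: float = 0.0
    axis_ratio: float = 1.0
    solidity: float = 1.0
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # min_row, min_col, max_row, max_col


def moment_ellipse_axes(coords: np.ndarray) -> tuple[float, float]:
    """Axis lengths of the ellipse with the same second central moments.

    Follows the normalized-central-moment convention: axis length =
    4 * sqrt(eigenvalue of the coordinate covariance matrix).  A single pixel
    has zero-length axes.
    """
    coords = np.asarray(coords, dtype=float)
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / len(coords)
    eig = np.linalg.eigvalsh(cov)  # ascending
    eig = np.clip(eig, 0.0, None)
    return 4.0 * float(np.sqrt(eig[1])), 4.0 * float(np.sqrt(eig[0]))


def component_properties(rec: ComponentRecord) -> ComponentRecord:
    """Fill area, moment-ellipse axes, axis ratio and convex-hull solidity.

    Degenerate conventions: a single pixel has axis_ratio 1 and solidity 1;
    a perfectly collinear multi-pixel component has minor axis 0 and
    axis_ratio infinity (maximally elongated).
    """
    coords = np.asarray(rec.coords)
    if len(coords) == 0:
        raise ValueError("component has no pixels")
    rec.area_px = len(coords)
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    rec.bbox = (int(rmin), int(cmin), int(rmax) + 1, int(cmax) + 1)
    if rec.area_px == 1:
        rec.major_axis = rec.minor_axis = 0.0
        rec.axis_ratio = 1.0
        rec.solidity = 1.0
        return rec
    rec.major_axis, rec.minor_axis = moment_ellipse_axes(coords)
    rec.axis_ratio = (
        rec.major_axis / rec.minor_axis if rec.minor_axis > 0 else float("inf")
    )
    patch = np.zeros((rec.bbox[2] - rec.bbox[0], rec.bbox[3] - rec.bbox[1]), bool)
    patch[coords[:, 0] - rec.bbox[0], coords[:, 1] - rec.bbox[1]] = True
    props = measure.regionprops(patch.astype(np.uint8))[0]
    rec.solidity = float(props.solidity)
    return rec


def label_components(mask: np.ndarray, connectivity: int = 8) -> list[ComponentRecord]:
    """Partition the true pixels of a binary mask into maximal components."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, bool)
    labeled = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    out = []
    for p in measure.regionprops(labeled):
        rec = ComponentRecord(label=int(p.label), coords=np.asarray(p.coords))
        out.append(component_properties(rec))
    return out


def _paint(components: Iterable[ComponentRecord], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, bool)
    for rec in components:
        mask[rec.coords[:, 0], rec.coords[:, 1]] = True
    return mask


def morphology_keep(rec: ComponentRecord, limits: MorphologyLimits, image_area_px: int) -> str | None:
    """Return None if the component passes, else the first failed limit name."""
    if rec.area_px < limits.min_area_px:
        return "min_area"
    if rec.area_px > limits.resolve_max_area(image_area_px):
        return "max_area"
    if rec.axis_ratio > limits.max_axis_ratio:
        return "axis_ratio"
    if rec.solidity < limits.min_solidity:
        return "solidity"
    return None


def filter_by_morphology(
    components: Sequence[ComponentRecord],
    limits: MorphologyLimits,
    shape: tuple[int, int],
) -> np.ndarray:
    """Mask of components inside the area window, elongation and solidity limits."""
    area = shape[0] * shape[1]
    keep = [c for c in components if morphology_keep(c, limits, area) is None]
    return _paint(keep, shape)


def touches_canopy(rec: ComponentRecord, canopy: np.ndarray, ring_width: int = 1) -> bool:
    """True if the component overlaps canopy or its exterior pixel ring does.

    The ring is the 8-connected dilation of the component by ``ring_width``
    minus the component itself; width > 1 suits coarser (aerial) imagery
    where a mixed-pixel rim separates petals from pure canopy.
    """
    r0, c0, r1, c1 = rec.bbox
    pad = ring_width
    r0p, c0p = max(r0 - pad, 0), max(c0 - pad, 0)
    r1p, c1p = min(r1 + pad, canopy.shape[0]), min(c1 + pad, canopy.shape[1])
    patch = np.zeros((r1p - r0p, c1p - c0p), bool)
    patch[rec.coords[:, 0] - r0p, rec.coords[:, 1] - c0p] = True
    canopy_patch = canopy[r0p:r1p, c0p:c1p]
    if bool(np.any(patch & canopy_patch)):
        return True
    ring = ndimage.binary_dilation(patch, structure=np.ones((3, 3), bool), iterations=ring_width) & ~patch
    return bool(np.any(ring & canopy_patch))


def filter_by_canopy_adjacency(
    components: Sequence[ComponentRecord],
    canopy: np.ndarray,
    ring_width: int = 1,
) -> np.ndarray:
    """Mask of components whose peripheral pixels neighbor (or lie in) canopy."""
    canopy = np.asarray(canopy, bool)
    keep = [c for c in components if touches_canopy(c, canopy, ring_width)]
    return _paint(keep, canopy.shape)


def denoise(
    candidates: np.ndarray,
    canopy: np.ndarray,
    limits: MorphologyLimits | None = None,
    connectivity: int = 8,
    ring_width: int = 1,
) -> np.ndarray:
    """Candidate mask with both per-component noise filters applied."""
    mask, _ = denoise_report(candidates, canopy, limits, connectivity, ring_width)
    return mask


def denoise_report(
    candidates: np.ndarray,
    canopy: np.ndarray,
    limits: MorphologyLimits | None = None,
    connectivity: int = 8,
    ring_width: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Denoised mask plus a per-component keep/drop table.

    The table has one row per candidate component: label, area_px,
    axis_ratio, solidity, kept and drop_reason (morphology limit name or
    ``no_canopy_neighbor``; empty when kept).
    """
    candidates = np.asarray(candidates, bool)
    canopy = np.asarray(canopy, bool)
    if candidates.shape != canopy.shape:
        raise ValueError("candidate and canopy masks must share a shape")
    limits = limits or MorphologyLimits()
    image_area = candidates.size
    components = label_components(candidates, connectivity)
    rows, kept = [], []
    for rec in components:
        reason = morphology_keep(rec, limits, image_area)
        if reason is None and not touches_canopy(rec, canopy, ring_width):
            reason = "no_canopy_neighbor"
        if reason is None:
            kept.append(rec)
        rows.append(
            {
                "label": rec.label,
                "area_px": rec.area_px,
                "axis_ratio": rec.axis_ratio,
                "solidity": rec.solidity,
                "kept": reason is None,
                "drop_reason": reason or "",
            }
        )
    report = pd.DataFrame(
        rows, columns=["label", "area_px", "axis_ratio", "solidity", "kept", "drop_reason"]
    )
    return _paint(kept, candidates.shape), report
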