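"""Flower features, correlation with ground truth, and GSD arithmetic.

Two features summarize flowering intensity per image or per plot: flower
area in pixels, and flowers% — flower area as a percentage of the canopy
area *including* the flower pixels (petals rarely satisfy the green canopy
rule, so the denominator is the union of the two masks).  Features are
related to manual visual ratings and seed yield by Pearson product-moment
correlation.

Ground sample distance (GSD, mm per pixel) scales linearly with flight
altitude; imagery resolves a flower reliably only when the flower is at
least 2-3 times larger than the GSD, otherwise petals mix spectrally with
canopy and soil inside single pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation input has zero variance (r is undefined)."""


@dataclass
class PlotFeatureRecord:
    """Per-plot flower intensity features keyed for joining with field data."""

    plot_id: int
    row: int
    col: int
    flower_area_px: int
    canopy_area_px: int  # union of canopy and flower pixels inside the ROI
    flowers_pct: float
    roi_area_px: int = 0
    empty_roi: bool = False


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int


class AdequacyResult(NamedTuple):
    adequate: bool
    ratio: float


def flowers_percentage(
    flower: np.ndarray, canopy: np.ndarray, roi: np.ndarray | None = None
) -> float:
    """100 x |flower| / |canopy union flower|, restricted to an optional ROI.

    Returns 0.0 when the denominator is empty.
    """
    flower = np.asarray(flower, bool)
    canopy = np.asarray(canopy, bool)
    union = canopy | flower
    if roi is not None:
        roi = np.asarray(roi, bool)
        flower = flower & roi
        union = union & roi
    denom = int(union.sum())
    return 100.0 * int(flower.sum()) / denom if denom else 0.0


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment r with a two-sided t-test p-value.

    Zero variance in either vector raises :class:`UndefinedCorrelationError`
    rather than returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("at least 3 pairs are needed for a p-value")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    res = _sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


def significance_stars(p: float) -> str:
    """Conventional significance stars: *** <0.001, ** <0.01, * <0.05, ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def correlate_features_with_ground_truth(
    features: pd.DataFrame,
    truth: pd.DataFrame,
    feature_cols: Iterable[str] = ("flower_area_px", "flowers_pct"),
    truth_cols: Iterable[str] = ("visual_rating", "yield"),
    key: str = "plot_id",
) -> pd.DataFrame:
    """Pearson r of every feature against every ground-truth column.

    Tables are inner-joined on ``key``; each pair uses pairwise-complete
    (non-missing) observations.  Rating scales (0-10 vs 0-100%) pass
    through untransformed — r is scale-invariant.
    """
    merged = features.merge(truth, on=key, how="inner")
    if merged.empty:
        raise ValueError(f"no overlapping {key} values between features and truth")
    rows = []
    for fc in feature_cols:
        for tc in truth_cols:
            if tc not in merged.columns:
                continue
            pair = merged[[fc, tc]].dropna()
            res = pearson_correlation(pair[fc].to_numpy(), pair[tc].to_numpy())
            rows.append(
                {
                    "feature": fc,
                    "truth": tc,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                    "stars": significance_stars(res.p),
                }
            )
    return pd.DataFrame(rows, columns=["feature", "truth", "r", "p", "n", "stars"])


@dataclass(frozen=True)
class GsdSpec:
    """Imaging geometry for GSD: altitude, focal length and pixel pitch.

    Either give the three geometric quantities or a direct ``gsd_mm``.
    """

    altitude_m: float | None = None
    focal_length_mm: float | None = None
    pixel_pitch_um: float | None = None
    gsd_mm: float | None = None

    def __post_init__(self) -> None:
        geo = (self.altitude_m, self.focal_length_mm, self.pixel_pitch_um)
        if self.gsd_mm is None and any(v is None for v in geo):
            raise ValueError("give altitude_m, focal_length_mm and pixel_pitch_um, or gsd_mm")
        for v in (*geo, self.gsd_mm):
            if v is not None and v <= 0:
                raise ValueError("GSD quantities must be positive")


def compute_gsd(spec: GsdSpec) -> float:
    """Ground sample distance in mm/pixel: altitude x pixel pitch / focal length."""
    if spec.gsd_mm is not None:
        return float(spec.gsd_mm)
    # altitude [m -> mm] * pitch [um -> mm] / focal [mm]  ->  mm on the ground
    return float(spec.altitude_m * 1000.0 * spec.pixel_pitch_um * 1e-3 / spec.focal_length_mm)


def scale_gsd_with_altitude(gsd_ref_mm: float, alt_ref_m: float, alt_new_m: float) -> float:
    """GSD at a new altitude: linear in altitude for a fixed sensor."""
    if gsd_ref_mm <= 0 or alt_ref_m <= 0 or alt_new_m <= 0:
        raise ValueError("GSD scaling requires positive inputs")
    return gsd_ref_mm * alt_new_m / alt_ref_m


def resolution_adequacy(
    flower_size_mm: float, gsd_mm: float, factor: float = 2.0
) -> AdequacyResult:
    """Is the pixel footprint small enough to resolve a flower of this size?

    ``ratio`` = flower size / GSD; adequate when the flower spans at least
    ``factor`` (default 2, conservative end of the 2-3x rule) pixels.
    """
    if flower_size_mm <= 0 or gsd_mm <= 0 or factor <= 0:
        raise ValueError("sizes, GSD and factor must be positive")
    ratio = flower_size_mm / gsd_mm
    return AdequacyResult(adequate=ratio >= factor, ratio=ratio)
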