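"""Per-kernel size and shape descriptors, in pixels and calibrated mm.

Fifteen descriptors per kernel: five extracted directly from the segmented
region (projected area A, perimeter P, solidity, fitted-ellipse major and
minor diameters M and m) and ten derived from them —

========================  =============================================
extent                    A / (bbox height · bbox width)
rect_to_perimeter         P / (2 · (bbox height + bbox width))
feret diameter            2·√(A/π)   (equal-area circle diameter)
circulation factor        P / π      (equal-perimeter circle diameter)
compactness               4πA / P²   (1 for a circle, π/4 for a square)
elongation                (M − m) / (M + m)   (0 circle → 1 needle)
aspect ratio              bbox height / bbox width
sa_to_cubic_volume        A / M³     (units 1/px)
mbr_fill                  A / area of minimum rotated bounding rectangle
eccentricity              √(1 − (m/M)²) of the fitted ellipse
========================  =============================================

Lengths calibrate by mm_per_px, areas by its square; dimensionless ratios
are scale-free.  Per-kernel failures (degenerate ellipse fits) produce NaN
fields plus an error flag instead of aborting a lot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import GrainMorphError
from .image_io import Calibration
from .segmentation import KernelRegion, min_area_rect

#: The 15 shape feature columns of the canonical feature table (pixel units).
SHAPE_FEATURE_COLUMNS = (
    "area_px2",
    "perimeter_px",
    "solidity",
    "major_px",
    "minor_px",
    "extent",
    "rect_to_perimeter",
    "feret_px",
    "circulation_px",
    "compactness",
    "elongation",
    "aspect_ratio",
    "sa_to_cubic_volume",
    "mbr_fill",
    "eccentricity",
)


@dataclass
class ShapeFeatures:
    area_px2: float
    area_mm2: float
    perimeter_px: float
    perimeter_mm: float
    solidity: float
    major_px: float
    major_mm: float
    minor_px: float
    minor_mm: float
    rect_height_px: int
    rect_width_px: int
    extent: float
    rect_to_perimeter: float
    feret_px: float
    feret_mm: float
    circulation_px: float
    circulation_mm: float
    compactness: float
    elongation: float
    aspect_ratio: float
    sa_to_cubic_volume: float
    mbr_fill: float
    eccentricity: float
    error: Optional[str] = None


def mbr_fill(region: KernelRegion) -> float:
    """Pixel count over the area of the minimum rotated bounding rectangle.

    The rectangle is fitted to the contour pixel centres (the coordinates
    classical contour routines work in), so a digitized inscribed ellipse
    fills ~π/4 of it; the half-pixel rim a centre-based rectangle misses can
    push a perfectly rectangular region a few percent above 1, so the ratio
    is clamped to (0, 1] — a filled rectangle reads exactly 1.
    """
    _, _, h, w = region.bounding_rect
    if h <= 0 or w <= 0:
        raise GrainMorphError("degenerate bounding rectangle")
    _, _, rect_area = min_area_rect(region.contour.points)
    rect_area = max(rect_area, 1.0)  # single-pixel / collinear degeneracy
    return min(1.0, region.area_px / rect_area)


def shape_features(
    region: KernelRegion,
    calib: Calibration,
    rotation_invariant_aspect: bool = False,
) -> ShapeFeatures:
    """All fifteen size/shape descriptors for one segmented kernel.

    With ``rotation_invariant_aspect`` the aspect ratio uses the larger
    bounding-rectangle side as the length regardless of orientation.
    """
    top, left, h, w = region.bounding_rect
    A = float(region.area_px)
    P = float(region.perimeter_px)
    if A <= 0 or P <= 0:
        raise GrainMorphError("region must have positive area and perimeter")
    if region.hull_area_px2 <= 0:
        raise GrainMorphError("region must have positive hull area")

    err = region.error
    if region.ellipse is not None:
        M, m, _ = region.ellipse
    else:
        M = m = float("nan")

    mm = calib.mm_per_px
    feret = 2.0 * math.sqrt(A / math.pi)
    if rotation_invariant_aspect:
        aspect = max(h, w) / min(h, w)
    else:
        aspect = h / w

    with np.errstate(all="ignore"):
        elong = (M - m) / (M + m)
        ecc = math.sqrt(max(0.0, 1.0 - (m / M) ** 2)) if M == M and M > 0 else float("nan")
        sa_cub = A / M**3

    return ShapeFeatures(
        area_px2=A,
        area_mm2=A * calib.mm2_per_px2,
        perimeter_px=P,
        perimeter_mm=P * mm,
        solidity=A / region.hull_area_px2,
        major_px=M,
        major_mm=M * mm,
        minor_px=m,
        minor_mm=m * mm,
        rect_height_px=h,
        rect_width_px=w,
        extent=A / (h * w),
        rect_to_perimeter=P / (2.0 * (h + w)),
        feret_px=feret,
        feret_mm=feret * mm,
        circulation_px=P / math.pi,
        circulation_mm=P / math.pi * mm,
        compactness=4.0 * math.pi * A / P**2,
        elongation=float(elong),
        aspect_ratio=float(aspect),
        sa_to_cubic_volume=float(sa_cub),
        mbr_fill=mbr_fill(region),
        eccentricity=float(ecc),
        error=err,
    )


def feature_table(regions: list[KernelRegion], calib: Calibration) -> pd.DataFrame:
    """One row per kernel with px and mm variants of every shape feature.

    Rows follow the deterministic region order (top-to-bottom, left-to-right);
    kernel_id is 1-based in that order.
    """
    cols = [
        "kernel_id",
        "area_px2", "area_mm2", "perimeter_px", "perimeter_mm", "solidity",
        "major_px", "major_mm", "minor_px", "minor_mm",
        "rect_height_px", "rect_width_px",
        "extent", "rect_to_perimeter", "feret_px", "feret_mm",
        "circulation_px", "circulation_mm", "compactness", "elongation",
        "aspect_ratio", "sa_to_cubic_volume", "mbr_fill", "eccentricity",
        "error",
    ]
    rows = []
    for i, region in enumerate(regions, start=1):
        sf = shape_features(region, calib)
        row = {"kernel_id": i, **sf.__dict__}
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
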