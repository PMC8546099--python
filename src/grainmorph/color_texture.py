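"""Colour indices and gray-level co-occurrence texture per segmented kernel.

Colour features (9): masked mean R/G/B channel intensities; three
normalized differential indices NDI_xy = |x − y| / (x + y) on those means;
and masked mean hue, saturation, value in the 8-bit HSV convention (hue
halved into [0, 180), S and V in [0, 255]).  A nearest-colour lookup against
a user-supplied chart (code → sRGB) names the kernel colour by minimum
Euclidean distance in sRGB; the proprietary horticultural reference chart is
not shipped, so a synthetic or user chart stands in.

Texture features (6) come from the gray-level co-occurrence matrix (GLCM)
P[i, j]: the normalized count of pixel pairs at offset (distance d, angle θ)
having gray levels i and j.  The GLCM here supports a region mask — both
members of a pair must lie inside the kernel — which the stock library
routine does not, hence the in-package implementation (cross-checked against
it on unmasked images in the tests).  Properties:

    contrast       Σ P_ij (i − j)²
    dissimilarity  Σ P_ij |i − j|
    homogeneity    Σ P_ij / (1 + (i − j)²)
    ASM            Σ P_ij²
    energy         √ASM
    correlation    Σ P_ij (i − μ_i)(j − μ_j) / (σ_i σ_j)

Zero-variance (constant) regions define correlation = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GrainMorphError
from .image_io import GrainImage

__all__ = [
    "ColorFeatures",
    "GLCMMatrix",
    "TextureFeatures",
    "mean_channels",
    "ndi",
    "rgb_to_hsv_means",
    "nearest_chart_color",
    "glcm",
    "glcm_props",
    "read_chart_csv",
    "write_chart_csv",
]


@dataclass
class ColorFeatures:
    mean_red: float
    mean_green: float
    mean_blue: float
    ndi_rg: float
    ndi_rb: float
    ndi_gb: float
    hue: float
    saturation: float
    value: float
    chart_code: Optional[str] = None
    chart_distance: Optional[float] = None


@dataclass
class GLCMMatrix:
    P: np.ndarray
    d: int
    theta: float
    levels: int
    symmetric: bool
    normalized: bool


@dataclass
class TextureFeatures:
    contrast: float
    dissimilarity: float
    homogeneity: float
    asm: float
    energy: float
    correlation: float


def _foreground(mask) -> np.ndarray:
    m = mask.bool_mask if hasattr(mask, "bool_mask") else np.asarray(mask) > 0
    if not m.any():
        raise GrainMorphError("mask has no foreground pixels")
    return m


def mean_channels(image: GrainImage, mask) -> tuple[float, float, float]:
    """Masked channel means (red, green, blue); background pixels excluded."""
    m = _foreground(mask)
    rgb = image.rgb
    if m.shape != rgb.shape[:2]:
        raise GrainMorphError("mask and image shapes differ")
    sel = rgb[m]
    means = sel.mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def ndi(mean_red: float, mean_green: float, mean_blue: float) -> tuple[float, float, float]:
    """Normalized differential indices (rg, rb, gb) of the channel means."""
    pairs = [(mean_red, mean_green), (mean_red, mean_blue), (mean_green, mean_blue)]
    out = []
    for x, y in pairs:
        if x + y <= 0:
            raise GrainMorphError("NDI undefined: channel pair sums to zero")
        out.append(abs(x - y) / (x + y))
    return tuple(out)  # type: ignore[return-value]


def _rgb_to_hsv_8bit(rgb: np.ndarray) -> np.ndarray:
    """Vectorized RGB→HSV with 8-bit conventions (H in [0,180), S,V in [0,255])."""
    arr = rgb.astype(np.float64)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    maxc = arr.max(axis=-1)
    minc = arr.min(axis=-1)
    delta = maxc - minc
    v = maxc
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(maxc > 0, 255.0 * delta / maxc, 0.0)
        hue = np.zeros_like(maxc)
        nz = delta > 0
        rmax = nz & (maxc == r)
        gmax = nz & ~rmax & (maxc == g)
        bmax = nz & ~rmax & ~gmax
        hue[rmax] = 60.0 * ((g - b)[rmax] / delta[rmax])
        hue[gmax] = 120.0 + 60.0 * ((b - r)[gmax] / delta[gmax])
        hue[bmax] = 240.0 + 60.0 * ((r - g)[bmax] / delta[bmax])
    hue = np.mod(hue, 360.0) / 2.0  # halved 8-bit hue
    return np.stack([hue, s, v], axis=-1)


def rgb_to_hsv_means(image: GrainImage, mask) -> tuple[float, float, float]:
    """Masked means of per-pixel hue, saturation, value (8-bit conventions)."""
    m = _foreground(mask)
    hsv = _rgb_to_hsv_8bit(image.rgb)
    sel = hsv[m]
    means = sel.mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def nearest_chart_color(
    mean_rgb: Sequence[float], chart: Sequence[tuple[str, Sequence[float]]]
) -> tuple[str, float]:
    """Chart code minimizing Euclidean distance in sRGB; ties → first entry."""
    if len(chart) == 0:
        raise GrainMorphError("colour chart is empty")
    codes = [c for c, _ in chart]
    arr = np.asarray([rgb for _, rgb in chart], dtype=float)
    q = np.asarray(mean_rgb, dtype=float)
    dists = np.sqrt(((arr - q) ** 2).sum(axis=1))
    i = int(np.argmin(dists))  # argmin takes the first minimizer
    return codes[i], float(dists[i])


def glcm(
    gray: np.ndarray,
    mask=None,
    d: int = 1,
    theta: float = 0.0,
    levels: int = 256,
    symmetric: bool = False,
    normed: bool = True,
) -> GLCMMatrix:
    """Gray-level co-occurrence matrix at offset (distance d, angle θ).

    The offset convention matches the standard library routine: a pair is
    (p, p + (round(d·sinθ), round(d·cosθ))), counted when both pixels lie
    inside the image and — if a mask is given — inside the mask.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise GrainMorphError("glcm expects a 2-D gray plane")
    if d < 1:
        raise GrainMorphError("distance d must be >= 1")
    if levels < 2:
        raise GrainMorphError("levels must be >= 2")
    if gray.max(initial=0) >= levels:
        raise GrainMorphError(f"gray values must be < levels={levels}")
    dr = int(round(math.sin(theta) * d))
    dc = int(round(math.cos(theta) * d))
    h, w = gray.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise GrainMorphError("image smaller than the requested offset")

    # source window and shifted window
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = gray[r0:r1, c0:c1]
    dst = gray[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if mask is not None:
        m = _foreground(mask)
        if m.shape != gray.shape:
            raise GrainMorphError("mask and image shapes differ")
        valid = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        src, dst = src[valid], dst[valid]
    P = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(P, (src.ravel().astype(np.intp), dst.ravel().astype(np.intp)), 1.0)
    if symmetric:
        P = P + P.T
    if normed:
        total = P.sum()
        if total > 0:
            P = P / total
    return GLCMMatrix(P=P, d=d, theta=theta, levels=levels,
                      symmetric=symmetric, normalized=normed)


def glcm_props(g: GLCMMatrix, verbatim_correlation: bool = False) -> TextureFeatures:
    """Texture properties of a normalized GLCM.

    ``verbatim_correlation`` divides by the variances σ_i²·σ_j² instead of
    the standard σ_i·σ_j (fidelity experiments only; it breaks the
    |correlation| ≤ 1 bound).
    """
    if not g.normalized or not math.isclose(g.P.sum(), 1.0, abs_tol=1e-9):
        raise GrainMorphError("glcm_props requires a normalized GLCM")
    P = g.P
    idx = np.arange(g.levels, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    diff = i - j
    contrast = float((P * diff**2).sum())
    dissimilarity = float((P * np.abs(diff)).sum())
    homogeneity = float((P / (1.0 + diff**2)).sum())
    asm = float((P**2).sum())
    energy = math.sqrt(asm)
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    var_i = float((P * (i - mu_i) ** 2).sum())
    var_j = float((P * (j - mu_j) ** 2).sum())
    cov = float((P * (i - mu_i) * (j - mu_j)).sum())
    if var_i <= 0 or var_j <= 0:
        corr = 1.0  # constant region: perfectly correlated by convention
    elif verbatim_correlation:
        corr = cov / (var_i * var_j)
    else:
        corr = cov / math.sqrt(var_i * var_j)
    return TextureFeatures(
        contrast=contrast,
        dissimilarity=dissimilarity,
        homogeneity=homogeneity,
        asm=asm,
        energy=energy,
        correlation=corr,
    )


def read_chart_csv(path: str | Path) -> list[tuple[str, tuple[int, int, int]]]:
    """Read a colour chart CSV with columns code, R, G, B."""
    df = pd.read_csv(path)
    missing = {"code", "R", "G", "B"} - set(df.columns)
    if missing:
        raise GrainMorphError(f"chart CSV missing columns: {sorted(missing)}")
    return [
        (str(row.code), (int(row.R), int(row.G), int(row.B)))
        for row in df.itertuples(index=False)
    ]


def write_chart_csv(chart: Sequence[tuple[str, Sequence[int]]], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c, int(rgb[0]), int(rgb[1]), int(rgb[2])) for c, rgb in chart],
        columns=["code", "R", "G", "B"],
    )
    df.to_csv(path, index=False)
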