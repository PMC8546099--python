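"""Synthetic flatbed-scanner scenes of wheat kernels with exact ground truth.

Real scenes are 24-bit, 200-dpi scans of ~100 manually placed kernels on a
near-black background.  The generator emulates that: each kernel is an
ellipse-like convex blob (optionally with a sinusoidal radial perturbation
for the wrinkled profile of shriveled grain), filled with its class mean
colour plus per-pixel Gaussian noise, rendered on a uniform dark background.
Kernels are placed on a jittered grid — scanner operators lay kernels out in
rough rows — with orientations nearly aligned to the scan axis, pairwise
disjoint, with at least a 2 px margin to the image border.

Ground truth records, per kernel, the generating spec, the exact rendered
pixel area, and the perimeter measured by the package's own boundary tracer
on the rendered mask (a self-consistency oracle for the segmentation stage).

Class conditions (axial dimensions in mm scaled by dpi/25.4 px/mm, mean
colours, weights) come from :mod:`grainmorph.reference`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import reference
from .errors import GrainMorphError, PlacementError
from .image_io import save_png
from .segmentation import trace_boundary, _corner_points, _hull_vertices, _polygon_perimeter

__all__ = [
    "SyntheticKernelSpec",
    "KernelTruth",
    "SyntheticScene",
    "render_scene",
    "sample_class_scene",
    "make_color_chart",
    "write_truth_csv",
    "write_scene_png",
]

#: Default boundary irregularity per class: only shriveled kernels deviate
#: from a pure ellipse (wrinkled outline).
CLASS_IRREGULARITY = {"sound": 0.0, "damaged": 0.0, "shriveled": 0.12, "broken": 0.0}

#: Default per-pixel RGB noise sd inside kernels (gray levels); gives the
#: non-constant interiors that co-occurrence texture needs.
DEFAULT_RGB_NOISE_SD = 8.0

#: Background gray level: near-black, not 0, so an automatic threshold sees a
#: genuinely bimodal histogram.
DEFAULT_BACKGROUND = 8

#: Minimum margin (gray levels) between a kernel's mean colour and the
#: effective segmentation level (background, or the class's fixed threshold),
#: keeping every rendered kernel segmentable.
MIN_COLOR_MARGIN = 30


@dataclass
class SyntheticKernelSpec:
    refraction_class: str
    major_axis_px: float
    minor_axis_px: float
    center: tuple[float, float]  # (row, col)
    orientation_deg: float
    mean_rgb: tuple[int, int, int]
    rgb_noise_sd: float = 0.0
    boundary_irregularity: float = 0.0
    n_lobes: int = 6
    lobe_phase: float = 0.0

    def __post_init__(self) -> None:
        if not (self.major_axis_px >= self.minor_axis_px > 0):
            raise GrainMorphError(
                f"require major >= minor > 0, got ({self.major_axis_px}, {self.minor_axis_px})"
            )
        if not 0.0 <= self.boundary_irregularity <= 1.0:
            raise GrainMorphError("boundary_irregularity must be in [0, 1]")
        if self.rgb_noise_sd < 0:
            raise GrainMorphError("rgb_noise_sd must be non-negative")
        self.orientation_deg = float(self.orientation_deg) % 180.0


@dataclass
class KernelTruth:
    kernel_id: int
    spec: SyntheticKernelSpec
    area_px: int
    perimeter_px: float


@dataclass
class SyntheticScene:
    image: np.ndarray  # H×W×3 uint8, RGB
    dpi: int
    truth: list[KernelTruth]
    background_level: int

    @property
    def labels(self) -> np.ndarray:
        return self._labels

    _labels: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _kernel_mask_window(
    spec: SyntheticKernelSpec, image_shape: tuple[int, int]
) -> tuple[slice, slice, np.ndarray]:
    """Rasterize one kernel; returns (row slice, col slice, local bool mask)."""
    a = spec.major_axis_px / 2.0
    b = spec.minor_axis_px / 2.0
    irr = spec.boundary_irregularity
    reach = a * (1.0 + irr) + 1.0
    r0c, c0c = spec.center
    th = math.radians(spec.orientation_deg)
    h, w = image_shape
    rlo = int(math.floor(r0c - reach))
    rhi = int(math.ceil(r0c + reach)) + 1
    clo = int(math.floor(c0c - reach))
    chi = int(math.ceil(c0c + reach)) + 1
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr = rr - r0c
    dc = cc - c0c
    # u along the major axis (measured from +col toward +row), v along minor
    u = dc * math.cos(th) + dr * math.sin(th)
    v = -dc * math.sin(th) + dr * math.cos(th)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if irr > 0:
        phi = np.arctan2(v / b, u / a)
        limit = 1.0 + irr * np.sin(spec.n_lobes * phi + spec.lobe_phase)
    else:
        limit = 1.0
    local = rho <= limit
    return slice(rlo, rhi), slice(clo, chi), local


def render_scene(
    specs: Sequence[SyntheticKernelSpec],
    image_size: tuple[int, int],
    background_level: int = DEFAULT_BACKGROUND,
    dpi: int = 200,
    seed: int = 0,
) -> SyntheticScene:
    """Render kernels onto a uniform background; exact truth per kernel.

    Deterministic for a fixed seed.  Rejects overlapping or out-of-bounds
    placements, naming the offending spec index.
    """
    h, w = image_size
    if h < 1 or w < 1:
        raise GrainMorphError("image_size must be positive")
    if not 0 <= background_level <= 255:
        raise GrainMorphError("background_level must be in [0, 255]")
    rng = np.random.default_rng(seed)
    image = np.full((h, w, 3), background_level, dtype=np.uint8)
    labels = np.zeros((h, w), dtype=np.int32)
    truth: list[KernelTruth] = []
    for k, spec in enumerate(specs):
        rsl, csl, local = _kernel_mask_window(spec, (h, w))
        if rsl.start < 2 or csl.start < 2 or rsl.stop > h - 2 or csl.stop > w - 2:
            raise PlacementError(
                f"kernel {k} at center {spec.center} does not fit inside the "
                f"{h}×{w} image with a 2 px margin",
                spec_index=k,
            )
        window = labels[rsl, csl]
        if (window[local] != 0).any():
            other = int(window[local][window[local] != 0][0]) - 1
            raise PlacementError(
                f"kernel {k} overlaps previously placed kernel {other}", spec_index=k
            )
        window[local] = k + 1
        n_px = int(local.sum())
        if n_px == 0:
            raise PlacementError(f"kernel {k} rasterized to zero pixels", spec_index=k)
        colors = np.asarray(spec.mean_rgb, dtype=np.float64)
        if spec.rgb_noise_sd > 0:
            vals = colors[None, :] + rng.normal(0.0, spec.rgb_noise_sd, size=(n_px, 3))
        else:
            vals = np.broadcast_to(colors, (n_px, 3))
        vals = np.clip(np.rint(vals), 0, 255).astype(np.uint8)
        image[rsl, csl][local] = vals
        boundary = trace_boundary(local)
        perim = _polygon_perimeter(_hull_vertices(_corner_points(boundary)))
        truth.append(KernelTruth(kernel_id=k + 1, spec=spec, area_px=n_px, perimeter_px=perim))
    scene = SyntheticScene(image=image, dpi=dpi, truth=truth,
                           background_level=background_level)
    scene._labels = labels
    return scene


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal (the truncation window is wide)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def sample_class_scene(
    refraction_class: str,
    n_kernels: int,
    seed: int = 0,
    dpi: int = 200,
    rgb_noise_sd: float = DEFAULT_RGB_NOISE_SD,
    boundary_irregularity: Optional[float] = None,
    orientation_sd_deg: float = 2.5,
    color_sd_scale: float = 1.0,
    background_level: int = DEFAULT_BACKGROUND,
    canvas: Optional[tuple[int, int]] = None,
    gap_px: int = 14,
) -> SyntheticScene:
    """A scanner scene of ``n_kernels`` kernels of one refraction class.

    Axis lengths are drawn from the class caliper distribution (mm means/sds
    truncated to [0.6, 1.4]×mean) converted at ``dpi``; mean colours from the
    class channel distribution, kept at least 30 gray levels above the
    background.  Kernels sit on a jittered grid, nearly axis-aligned
    (orientation N(0, ``orientation_sd_deg``²) clipped at ±6°), emulating
    manual row placement on the scanner glass.  ``color_sd_scale`` scales the
    between-kernel colour spread (0 renders every kernel at the class mean —
    a fully noise-free scene when ``rgb_noise_sd`` is also 0).
    """
    if refraction_class not in reference.REFRACTION_CLASSES:
        raise GrainMorphError(f"unknown refraction class: {refraction_class!r}")
    if n_kernels < 1:
        raise GrainMorphError("n_kernels must be >= 1")
    rng = np.random.default_rng(seed)
    px_per_mm = dpi / 25.4
    L_mean, W_mean, _ = reference.AXIAL_MM_MEAN[refraction_class]
    L_sd, W_sd, _ = reference.AXIAL_MM_SD[refraction_class]
    rgb_mean = reference.MEAN_RGB[refraction_class]
    rgb_sd = reference.RGB_SD[refraction_class]
    irr = (
        CLASS_IRREGULARITY[refraction_class]
        if boundary_irregularity is None
        else boundary_irregularity
    )

    max_major = 1.4 * L_mean * px_per_mm * (1.0 + irr)
    cell = int(math.ceil(max_major)) + gap_px
    ncols = int(math.ceil(math.sqrt(n_kernels)))
    nrows = int(math.ceil(n_kernels / ncols))
    margin = cell // 2 + 4
    need_h = nrows * cell + 2 * margin
    need_w = ncols * cell + 2 * margin
    if canvas is None:
        h, w = need_h, need_w
    else:
        h, w = canvas
        if h < need_h or w < need_w:
            raise PlacementError(
                f"cannot place {n_kernels} kernels of class {refraction_class!r} in a "
                f"{h}×{w} canvas; need at least {need_h}×{need_w} — use a larger canvas"
            )

    specs: list[SyntheticKernelSpec] = []
    jitter = max(1.0, gap_px / 4.0)
    for k in range(n_kernels):
        gi, gj = divmod(k, ncols)
        L_mm = _truncnorm(rng, L_mean, L_sd, 0.6 * L_mean, 1.4 * L_mean)
        W_mm = _truncnorm(rng, W_mean, W_sd, 0.6 * W_mean, 1.4 * W_mean)
        # kernel allometry: length and width are not independent; keep the
        # L/W ratio inside the class ±3σ band (bounded to a sane range)
        r_mean, r_sd = reference.ASPECT_RATIO[refraction_class]
        r_lo = max(1.05, r_mean - 3.0 * r_sd)
        r_hi = min(4.0, r_mean + 3.0 * r_sd)
        W_mm = float(np.clip(W_mm, L_mm / r_hi, L_mm / r_lo))
        major = L_mm * px_per_mm
        minor = min(W_mm * px_per_mm, 0.95 * major)
        center = (
            margin + (gi + 0.5) * cell + rng.uniform(-jitter, jitter),
            margin + (gj + 0.5) * cell + rng.uniform(-jitter, jitter),
        )
        orient = float(np.clip(rng.normal(0.0, orientation_sd_deg), -6.0, 6.0)) % 180.0
        # colour draws truncated to ±2σ and floored a full margin above the
        # level the segmentation stage thresholds at (green channel; the
        # other channels only need to clear the background)
        seg_level = max(background_level, reference.CLASS_THRESHOLDS.get(refraction_class, 0))
        floors = (
            background_level + MIN_COLOR_MARGIN,
            seg_level + MIN_COLOR_MARGIN,
            background_level + MIN_COLOR_MARGIN,
        )
        mean_rgb = []
        for mu, sd, floor in zip(rgb_mean, rgb_sd, floors):
            lo = max(floor, mu - 2.0 * color_sd_scale * sd)
            hi = max(lo, min(255.0, mu + 2.0 * color_sd_scale * sd))
            mean_rgb.append(int(np.clip(np.rint(rng.normal(mu, color_sd_scale * sd)), lo, hi)))
        mean_rgb = tuple(mean_rgb)
        specs.append(
            SyntheticKernelSpec(
                refraction_class=refraction_class,
                major_axis_px=major,
                minor_axis_px=minor,
                center=center,
                orientation_deg=orient,
                mean_rgb=mean_rgb,  # type: ignore[arg-type]
                rgb_noise_sd=rgb_noise_sd,
                boundary_irregularity=irr,
                lobe_phase=float(rng.uniform(0.0, 2.0 * math.pi)),
            )
        )
    render_seed = int(rng.integers(0, 2**31 - 1))
    return render_scene(specs, (h, w), background_level=background_level,
                        dpi=dpi, seed=render_seed)


def scene_to_grain_image(scene: SyntheticScene):
    """View a rendered scene as a GrainImage, as if loaded from disk."""
    from .image_io import GrainImage

    return GrainImage(pixels=scene.image[:, :, ::-1].copy(), dpi=scene.dpi,
                      source_path="<synthetic>")


def truth_to_manual(
    scene: SyntheticScene,
    extended: pd.DataFrame,
    weight_g_per_mm2: Optional[float] = None,
) -> pd.DataFrame:
    """Align scene ground truth to extracted kernels, as a caliper-style table.

    Extracted regions are ordered by bounding-rectangle origin, not placement
    order, so truth kernels are matched to image kernels by nearest centre
    (one-to-one).  Returns a table keyed by the image kernel_id with the
    generating axes as L_mm / W_mm, the true rendered area in mm², and —
    if ``weight_g_per_mm2`` is given — a kernel weight proportional to the
    true projected area, emulating a balance reading.
    """
    from scipy.spatial import cKDTree

    required = {"kernel_id", "top", "left", "rect_height_px", "rect_width_px"}
    missing = required - set(extended.columns)
    if missing:
        raise GrainMorphError(f"extended table missing columns: {sorted(missing)}")
    mm = 25.4 / scene.dpi
    img_centers = np.column_stack(
        [
            extended["top"].to_numpy(float) + extended["rect_height_px"].to_numpy(float) / 2.0,
            extended["left"].to_numpy(float) + extended["rect_width_px"].to_numpy(float) / 2.0,
        ]
    )
    truth_centers = np.asarray([t.spec.center for t in scene.truth], dtype=float)
    tree = cKDTree(truth_centers)
    _, idx = tree.query(img_centers)
    if len(set(idx.tolist())) != len(idx):
        raise GrainMorphError("truth-to-region matching is not one-to-one")
    rows = []
    for kid, j in zip(extended["kernel_id"], idx):
        t = scene.truth[j]
        row = dict(
            kernel_id=kid,
            L_mm=t.spec.major_axis_px * mm,
            W_mm=t.spec.minor_axis_px * mm,
            area_true_mm2=t.area_px * mm * mm,
        )
        if weight_g_per_mm2 is not None:
            row["weight_g"] = weight_g_per_mm2 * row["area_true_mm2"]
        rows.append(row)
    return pd.DataFrame(rows)


def make_color_chart(
    n_entries: int, seed: int = 0
) -> list[tuple[str, tuple[int, int, int]]]:
    """A synthetic colour chart: unique codes mapped to random sRGB triples.

    Stands in for a proprietary printed reference chart; deterministic for a
    fixed seed.
    """
    if n_entries < 1:
        raise GrainMorphError("n_entries must be >= 1")
    rng = np.random.default_rng(seed)
    letters = "ABCD"
    chart = []
    for i in range(n_entries):
        code = f"{i // 4 + 1}{letters[i % 4]}"
        rgb = tuple(int(v) for v in rng.integers(0, 256, size=3))
        chart.append((code, rgb))
    return chart


def write_truth_csv(scene: SyntheticScene, path: str | Path) -> None:
    """Ground-truth table: one row per kernel with spec and measured truth."""
    rows = []
    for t in scene.truth:
        s = t.spec
        rows.append(
            dict(
                kernel_id=t.kernel_id,
                **{"class": s.refraction_class},
                center_row=s.center[0],
                center_col=s.center[1],
                major_px=s.major_axis_px,
                minor_px=s.minor_axis_px,
                orientation_deg=s.orientation_deg,
                area_px=t.area_px,
                perimeter_px=t.perimeter_px,
            )
        )
    cols = ["kernel_id", "class", "center_row", "center_col", "major_px",
            "minor_px", "orientation_deg", "area_px", "perimeter_px"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_scene_png(scene: SyntheticScene, path: str | Path) -> None:
    save_png(scene.image, path)
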