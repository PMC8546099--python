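"""End-to-end feature extraction: image → segmentation → 30 features.

The canonical per-kernel feature table has exactly 30 feature columns —
15 size/shape + 9 colour + 6 texture — plus the kernel_id.  An extended
table adds calibrated mm variants, bounding-rectangle geometry, the chart
colour match and per-kernel error flags.  Runs are deterministic for a fixed
configuration and seed, and exported CSVs are byte-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import pandas as pd

from . import color_texture as ct
from . import morphometry, segmentation
from .errors import ConfigError, GrainMorphError
from .image_io import GrainImage, load_image, make_calibration, split_channels
from .reference import REFRACTION_CLASSES
from .segmentation import ThresholdMode, ThresholdSpec

logger = logging.getLogger("grainmorph")

#: The frozen 30-column feature contract (15 shape + 9 colour + 6 texture).
FEATURE_COLUMNS = (
    morphometry.SHAPE_FEATURE_COLUMNS
    + (
        "mean_red", "mean_green", "mean_blue",
        "ndi_rg", "ndi_rb", "ndi_gb",
        "hue", "saturation", "value",
    )
    + ("contrast", "dissimilarity", "homogeneity", "asm", "energy", "correlation")
)


@dataclass
class PipelineConfig:
    """Settings for a pipeline run; defaults are the standard scan protocol
    (200 dpi, 5×5 Gaussian, Otsu for sound grain, fixed 37/74/35 otherwise)."""

    image_path: Optional[str] = None
    refraction_class: str = "sound"
    dpi: int = 200
    threshold_mode: Optional[str] = None  # None → per-class default
    threshold: Optional[int] = None
    gaussian_kernel_size: int = 5
    min_area_px2: float = 20.0
    channel: str = "green"
    glcm_distance: int = 1
    glcm_theta: float = 0.0
    glcm_levels: int = 256
    glcm_symmetric: bool = False
    chart_path: Optional[str] = None
    output_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"


def validate_config(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a flat mapping, rejecting unknown keys and
    out-of-range values before any processing starts."""
    known = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if cfg.dpi <= 0:
        raise ConfigError(f"dpi must be positive, got {cfg.dpi}")
    if cfg.refraction_class not in REFRACTION_CLASSES:
        raise ConfigError(f"refraction_class must be one of {REFRACTION_CLASSES}")
    if cfg.threshold is not None and not 0 <= cfg.threshold <= 255:
        raise ConfigError(f"threshold must be in [0, 255], got {cfg.threshold}")
    if cfg.gaussian_kernel_size < 1 or cfg.gaussian_kernel_size % 2 == 0:
        raise ConfigError("gaussian_kernel_size must be an odd integer >= 1")
    if cfg.channel not in ("blue", "green", "red"):
        raise ConfigError("channel must be blue, green or red")
    if cfg.glcm_levels < 2 or cfg.glcm_levels > 256:
        raise ConfigError("glcm_levels must be in [2, 256]")
    if cfg.glcm_distance < 1:
        raise ConfigError("glcm_distance must be >= 1")
    if cfg.min_area_px2 < 0:
        raise ConfigError("min_area_px2 must be non-negative")
    return cfg


def _threshold_spec(cfg: PipelineConfig) -> ThresholdSpec:
    if cfg.threshold_mode is None:
        if cfg.threshold is not None:
            return ThresholdSpec(mode=ThresholdMode.FIXED, thresh=cfg.threshold)
        return segmentation.default_threshold_spec(cfg.refraction_class)
    mode = ThresholdMode(cfg.threshold_mode)
    if mode is ThresholdMode.FIXED:
        thresh = cfg.threshold
        if thresh is None:
            from .reference import CLASS_THRESHOLDS

            thresh = CLASS_THRESHOLDS.get(cfg.refraction_class)
        if thresh is None:
            raise ConfigError("fixed_binary mode requires an explicit threshold")
        return ThresholdSpec(mode=mode, thresh=thresh)
    return ThresholdSpec(mode=mode)


@dataclass
class PipelineResult:
    features: pd.DataFrame           # kernel_id + the 30 canonical columns
    extended: pd.DataFrame           # mm variants, bbox, chart match, errors
    regions: list
    chosen_threshold: int
    config: PipelineConfig


def extract_features(
    image: GrainImage,
    config: Optional[PipelineConfig] = None,
    chart=None,
) -> PipelineResult:
    """Segment one scanner image and compute all 30 features per kernel."""
    cfg = config or PipelineConfig()
    calib = make_calibration(image.dpi)
    blue, green, red = split_channels(image)
    plane = {"blue": blue, "green": green, "red": red}[cfg.channel]
    smoothed = segmentation.gaussian_smooth(plane, cfg.gaussian_kernel_size)
    spec = _threshold_spec(cfg)
    chosen, mask = segmentation.threshold(smoothed, spec)
    logger.info("threshold mode=%s chosen=%d", spec.mode.value, chosen)
    regions = segmentation.extract_regions(mask, cfg.min_area_px2)
    if not regions:
        logger.warning("no kernels found in %s", image.source_path or "<image>")

    nan = float("nan")
    shape_rows, color_rows, ext_rows = [], [], []
    for i, region in enumerate(regions, start=1):
        sf = morphometry.shape_features(region, calib)
        top, left, h, w = region.bounding_rect
        # colour/texture work on the bounding-box crop; the region mask is local
        crop = GrainImage(
            pixels=image.pixels[top : top + h, left : left + w].copy(),
            dpi=image.dpi,
            channel_order=image.channel_order,
        )
        err = sf.error
        try:
            mr, mg, mb = ct.mean_channels(crop, region.mask)
            n_rg, n_rb, n_gb = ct.ndi(mr, mg, mb)
            hue, sat, val = ct.rgb_to_hsv_means(crop, region.mask)
        except GrainMorphError as exc:
            mr = mg = mb = n_rg = n_rb = n_gb = hue = sat = val = nan
            err = f"{err}; {exc}" if err else str(exc)
        try:
            g = ct.glcm(
                green[top : top + h, left : left + w],
                mask=region.mask,
                d=cfg.glcm_distance,
                theta=cfg.glcm_theta,
                levels=cfg.glcm_levels,
                symmetric=cfg.glcm_symmetric,
            )
            tex = ct.glcm_props(g)
        except GrainMorphError as exc:
            tex = ct.TextureFeatures(nan, nan, nan, nan, nan, nan)
            err = f"{err}; {exc}" if err else str(exc)
        sf.error = err
        shape_rows.append({"kernel_id": i, **{k: getattr(sf, k) for k in
                           morphometry.SHAPE_FEATURE_COLUMNS}})
        color_rows.append(
            dict(
                kernel_id=i,
                mean_red=mr, mean_green=mg, mean_blue=mb,
                ndi_rg=n_rg, ndi_rb=n_rb, ndi_gb=n_gb,
                hue=hue, saturation=sat, value=val,
                contrast=tex.contrast, dissimilarity=tex.dissimilarity,
                homogeneity=tex.homogeneity, asm=tex.asm, energy=tex.energy,
                correlation=tex.correlation,
            )
        )
        ext = dict(
            kernel_id=i,
            top=top, left=left, rect_height_px=h, rect_width_px=w,
            length_mm=max(h, w) * calib.mm_per_px,
            width_mm=min(h, w) * calib.mm_per_px,
            area_mm2=sf.area_mm2,
            perimeter_mm=sf.perimeter_mm,
            major_mm=sf.major_mm, minor_mm=sf.minor_mm,
            feret_mm=sf.feret_mm,
            perimeter_chain_px=region.perimeter_chain_px,
            error=err or "",
        )
        if chart is not None and mr == mr:  # skip chart match on NaN colour
            code, dist = ct.nearest_chart_color((mr, mg, mb), chart)
            ext["chart_code"] = code
            ext["chart_distance"] = dist
        ext_rows.append(ext)

    feat_cols = ["kernel_id", *FEATURE_COLUMNS]
    if regions:
        shape_df = pd.DataFrame(shape_rows)
        color_df = pd.DataFrame(color_rows)
        features = shape_df.merge(color_df, on="kernel_id")[feat_cols]
        extended = pd.DataFrame(ext_rows)
    else:
        features = pd.DataFrame(columns=feat_cols)
        extended = pd.DataFrame(
            columns=["kernel_id", "top", "left", "rect_height_px", "rect_width_px",
                     "length_mm", "width_mm", "area_mm2", "perimeter_mm",
                     "major_mm", "minor_mm", "feret_mm", "perimeter_chain_px", "error"]
        )
    return PipelineResult(
        features=features,
        extended=extended,
        regions=regions,
        chosen_threshold=chosen,
        config=cfg,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load the configured image, extract features and optionally export CSVs."""
    cfg = config
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    if cfg.image_path is None:
        raise ConfigError("run_pipeline requires image_path (use synth + extract for scenes)")
    image = load_image(cfg.image_path, cfg.dpi)
    chart = ct.read_chart_csv(cfg.chart_path) if cfg.chart_path else None
    result = extract_features(image, cfg, chart=chart)
    if cfg.output_dir:
        export_results(result, cfg.output_dir)
    return result


def export_results(result: PipelineResult, output_dir: str | Path,
                   html: bool = False) -> None:
    """Write features.csv / extended.csv (and optional HTML mirrors)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False)
    result.extended.to_csv(out / "extended.csv", index=False)
    if html:
        result.features.to_html(out / "features.html", index=False)
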