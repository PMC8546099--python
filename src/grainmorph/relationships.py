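"""Linear image-vs-manual relationships with R².

The validation question for scanner morphometry is whether cheap image
measurements track the reference manual ones.  Four ordinary-least-squares
fits are made per refraction class:

1. caliper length L (mm)  vs  image length  (fitted-ellipse major diameter, mm)
2. caliper width W (mm)   vs  image width   (fitted-ellipse minor diameter, mm)
3. kernel weight (g)      vs  calibrated projected area (mm²)
4. prolate-spheroid volume 4/3·π·L·W² from caliper dims (mm³)
                          vs  calibrated projected area (mm²)

The image-domain dimensions default to the fitted-ellipse diameters (the
major/minor-diameter features, sub-pixel and rotation-invariant); the
calibrated bounding-rectangle sides are available as an alternative measure.
R² = 1 − SS_res/SS_tot is reported per fit.  Fits go through
scipy.stats.linregress.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RegressionError

__all__ = ["RegressionResult", "fit_linear", "relationship_report",
            "perturb_measurements", "results_to_table", "plot_relationship"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    x_label: str
    y_label: str
    class_label: str = ""


def fit_linear(
    x: Sequence[float],
    y: Sequence[float],
    x_label: str = "x",
    y_label: str = "y",
    class_label: str = "",
) -> RegressionResult:
    """Ordinary least squares y = slope·x + intercept with R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise RegressionError(f"x and y lengths differ: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise RegressionError(f"need at least 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise RegressionError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    # rvalue² equals 1 - SS_res/SS_tot for simple OLS; guard degenerate y
    r2 = 0.0 if np.ptp(y) == 0 else float(res.rvalue**2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n=len(x),
        x_label=x_label,
        y_label=y_label,
        class_label=class_label,
    )


def perturb_measurements(
    manual: pd.DataFrame,
    rel_sd: float,
    seed: int,
    columns: Sequence[str] = ("L_mm", "W_mm", "weight_g"),
) -> pd.DataFrame:
    """Add multiplicative Gaussian measurement noise to manual columns.

    Each value x becomes x · (1 + N(0, rel_sd²)); used to probe how the
    image-vs-manual R² degrades with caliper/balance error.
    """
    if rel_sd < 0:
        raise RegressionError("rel_sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = manual.copy()
    for col in columns:
        if col in out.columns:
            vals = out[col].to_numpy(dtype=float)
            out[col] = vals * (1.0 + rng.normal(0.0, rel_sd, size=len(vals)))
    return out


def relationship_report(
    manual: pd.DataFrame,
    image_features: pd.DataFrame,
    class_label: str = "",
    image_measure: str = "ellipse",
) -> list[RegressionResult]:
    """The four image-vs-manual fits for one refraction class.

    ``manual`` needs kernel_id, L_mm, W_mm and (optionally) weight_g and/or
    volume_mm3; a missing volume is derived from the caliper dims via the
    prolate-spheroid formula.  ``image_features`` is the extended feature
    table (kernel_id, major_mm/minor_mm, length_mm/width_mm, area_mm2).
    ``image_measure`` selects the image-side dimensions: ``"ellipse"`` for
    the fitted-ellipse diameters, ``"bbox"`` for bounding-rectangle sides.
    """
    if image_measure not in ("ellipse", "bbox"):
        raise RegressionError("image_measure must be 'ellipse' or 'bbox'")
    for df, name in ((manual, "manual"), (image_features, "image_features")):
        if "kernel_id" not in df.columns:
            raise RegressionError(f"{name} table lacks a kernel_id column")
    m_ids = set(manual["kernel_id"])
    i_ids = set(image_features["kernel_id"])
    orphans = m_ids.symmetric_difference(i_ids)
    if orphans:
        raise RegressionError(f"unmatched kernel ids between tables: {sorted(orphans)[:10]}")
    merged = manual.merge(image_features, on="kernel_id", suffixes=("_man", "_img"))

    len_col, wid_col = (
        ("major_mm", "minor_mm") if image_measure == "ellipse" else ("length_mm", "width_mm")
    )
    for col in (len_col, wid_col, "area_mm2"):
        if col not in merged.columns:
            raise RegressionError(f"image_features must provide {col}")

    results = []
    results.append(
        fit_linear(merged["L_mm"], merged[len_col],
                   "caliper length (mm)", "image length (mm)", class_label)
    )
    results.append(
        fit_linear(merged["W_mm"], merged[wid_col],
                   "caliper width (mm)", "image width (mm)", class_label)
    )
    if "weight_g" in merged.columns:
        results.append(
            fit_linear(merged["weight_g"], merged["area_mm2"],
                       "kernel weight (g)", "projected area (mm2)", class_label)
        )
    if "volume_mm3" in merged.columns:
        vol = merged["volume_mm3"].to_numpy(dtype=float)
    else:
        vol = (4.0 / 3.0) * math.pi * merged["L_mm"].to_numpy(dtype=float) * \
            merged["W_mm"].to_numpy(dtype=float) ** 2
    results.append(
        fit_linear(vol, merged["area_mm2"].to_numpy(dtype=float),
                   "prolate volume (mm3)", "projected area (mm2)", class_label)
    )
    return results


def results_to_table(results: Sequence[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                **{"class": r.class_label},
                relationship=f"{r.y_label} ~ {r.x_label}",
                slope=r.slope,
                intercept=r.intercept,
                r_squared=r.r_squared,
                n=r.n,
            )
            for r in results
        ],
        columns=["class", "relationship", "slope", "intercept", "r_squared", "n"],
    )


def plot_relationship(
    result: RegressionResult,
    x: Sequence[float],
    y: Sequence[float],
    path: str | Path,
) -> None:
    """Scatter plot of one relationship with its fitted line (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=12, alpha=0.7)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, result.slope * xs + result.intercept, "r-",
            label=f"y = {result.slope:.3g}x + {result.intercept:.3g}\nR² = {result.r_squared:.3f}")
    ax.set_xlabel(result.x_label)
    ax.set_ylabel(result.y_label)
    if result.class_label:
        ax.set_title(result.class_label)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
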