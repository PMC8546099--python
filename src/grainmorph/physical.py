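"""Physical properties of kernels from caliper axial dimensions.

Given per-kernel length L, width W and thickness T (mm, measured with a
vernier caliper) and optionally single-kernel weight (g), this module
computes the classical grain-engineering quantities:

* arithmetic mean diameter      Da = (L + W + T) / 3
* geometric mean diameter       Dg = (L·W·T)^(1/3)
* lateral geometric mean        B  = (W·T)^(1/2)
* sphericity                    Dg / L            (1 for a sphere)
* roundness ratio               L / B             (sharpness indicator)
* prolate surface area          Sp = π·B·L³ / (2L − B)
* oblate surface area           So (closed form, see below)
* prolate spheroid volume       Vp = 4/3·π·L·W²
* oblate spheroid volume        Vo = 4/3·π·L²·W
* ellipsoid volume              Ve = 4/3·π·L·W·T
* aspect ratio                  a/b  and ellipsoid ratio b/c, where a ≥ b ≥ c
  are the sorted dimensions

plus thousand-grain weight (10 × the mass of 100 kernels) and per-lot
mean ± sd summaries.

Scaling conventions.  These field formulas plug the full axial *diameters*
into spheroid expressions (note Sp scales as length³ although reported in
mm²); they are retained verbatim as the conventional quantities.  Correctly
scaled surface areas on semi-axes L/2, W/2 are available as
``prolate_surface_area_exact`` / ``oblate_surface_area_exact``.  The oblate
surface So has no conventional printed form here; it uses the exact oblate
closed form with L (equatorial) and B (polar) in place of the semi-axes,
matching the diameter convention of Vp/Vo/Ve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence
import warnings

import numpy as np
import pandas as pd

from .errors import MeasurementError

__all__ = [
    "AxialDims",
    "PhysicalProps",
    "mean_diameters",
    "sphericity_roundness",
    "surfaces_volumes",
    "shape_ratios",
    "physical_properties",
    "thousand_grain_weight",
    "lot_summary",
    "prolate_surface_area_exact",
    "oblate_surface_area_exact",
    "read_measurements_csv",
]


@dataclass(frozen=True)
class AxialDims:
    """Caliper measurements of one kernel: L ≥ W ≥ T expected, in mm."""

    L: float
    W: float
    T: float
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.L, self.W, self.T) <= 0:
            raise MeasurementError(
                f"axial dimensions must be positive, got ({self.L}, {self.W}, {self.T})"
            )
        if not (self.L >= self.W >= self.T):
            # broken kernels legitimately violate the ordering; warn, don't fail
            warnings.warn(
                f"axial dimensions not ordered L >= W >= T: ({self.L}, {self.W}, {self.T})",
                stacklevel=2,
            )
        if self.weight is not None and self.weight < 0:
            raise MeasurementError(f"weight must be non-negative, got {self.weight}")


@dataclass(frozen=True)
class PhysicalProps:
    Da: float
    Dg: float
    B: float
    sphericity: float
    roundness: float
    Sp: float
    So: float
    Vp: float
    Vo: float
    Ve: float
    AR: float
    ER: float
    L_over_T: float
    L_over_Dg: float
    W_over_T: float


def mean_diameters(d: AxialDims) -> tuple[float, float, float]:
    """Arithmetic mean, geometric mean and lateral geometric mean diameters."""
    Da = (d.L + d.W + d.T) / 3.0
    Dg = (d.L * d.W * d.T) ** (1.0 / 3.0)
    B = math.sqrt(d.W * d.T)
    return Da, Dg, B


def sphericity_roundness(d: AxialDims) -> tuple[float, float]:
    """Sphericity Dg/L and roundness ratio L/√(W·T)."""
    _, Dg, B = mean_diameters(d)
    return Dg / d.L, d.L / B


def prolate_surface_area_exact(length_mm: float, width_mm: float) -> float:
    """Surface of a prolate spheroid with polar diameter L, equatorial W (mm²)."""
    a, c = length_mm / 2.0, width_mm / 2.0  # a = polar semi-axis (larger)
    if a <= c:
        return 4.0 * math.pi * a * c  # sphere limit
    e = math.sqrt(1.0 - (c / a) ** 2)
    return 2.0 * math.pi * c**2 * (1.0 + (a / (c * e)) * math.asin(e))


def oblate_surface_area_exact(equatorial_mm: float, polar_mm: float) -> float:
    """Surface of an oblate spheroid with equatorial diameter a, polar c (mm²)."""
    a, c = equatorial_mm / 2.0, polar_mm / 2.0
    if a <= c:
        return 4.0 * math.pi * a * c
    e = math.sqrt(1.0 - (c / a) ** 2)
    return 2.0 * math.pi * a**2 + math.pi * (c**2 / e) * math.log((1.0 + e) / (1.0 - e))


def _oblate_surface_diameter_convention(L: float, B: float) -> float:
    """Oblate closed form with diameters plugged in for the semi-axes."""
    a, c = L, B
    if a <= c:
        return 4.0 * math.pi * a * c
    e = math.sqrt(1.0 - (c / a) ** 2)
    return 2.0 * math.pi * a**2 + math.pi * (c**2 / e) * math.log((1.0 + e) / (1.0 - e))


def surfaces_volumes(d: AxialDims) -> tuple[float, float, float, float, float]:
    """(Sp, So, Vp, Vo, Ve): spheroid surfaces and volumes, diameter convention."""
    _, _, B = mean_diameters(d)
    denom = 2.0 * d.L - B
    if denom <= 0:
        raise MeasurementError(
            f"prolate surface undefined: 2L - B = {denom:.4g} must be positive"
        )
    Sp = math.pi * B * d.L**3 / denom
    So = _oblate_surface_diameter_convention(d.L, B)
    Vp = (4.0 / 3.0) * math.pi * d.L * d.W**2
    Vo = (4.0 / 3.0) * math.pi * d.L**2 * d.W
    Ve = (4.0 / 3.0) * math.pi * d.L * d.W * d.T
    return Sp, So, Vp, Vo, Ve


def shape_ratios(d: AxialDims) -> tuple[float, float, float, float, float]:
    """(AR, ER, L/T, L/Dg, W/T) with a ≥ b ≥ c assigned by sorting the dims."""
    a, b, c = sorted((d.L, d.W, d.T), reverse=True)
    _, Dg, _ = mean_diameters(d)
    return a / b, b / c, d.L / d.T, d.L / Dg, d.W / d.T


def physical_properties(d: AxialDims) -> PhysicalProps:
    """All derived physical quantities for one kernel."""
    Da, Dg, B = mean_diameters(d)
    sph, rnd = sphericity_roundness(d)
    Sp, So, Vp, Vo, Ve = surfaces_volumes(d)
    AR, ER, L_T, L_Dg, W_T = shape_ratios(d)
    return PhysicalProps(
        Da=Da, Dg=Dg, B=B, sphericity=sph, roundness=rnd,
        Sp=Sp, So=So, Vp=Vp, Vo=Vo, Ve=Ve,
        AR=AR, ER=ER, L_over_T=L_T, L_over_Dg=L_Dg, W_over_T=W_T,
    )


def thousand_grain_weight(weights_g: Sequence[float], expected_n: int = 100) -> float:
    """Thousand-grain weight from a counted sample of single-kernel weights.

    With the standard 100-kernel sample, TGW = 10 × the sample mass; a
    different counted sample size scales proportionally.
    """
    if expected_n < 1:
        raise MeasurementError("expected_n must be >= 1")
    weights = np.asarray(list(weights_g), dtype=float)
    if len(weights) != expected_n:
        raise MeasurementError(
            f"thousand-grain weight requires exactly n={expected_n} weights, got {len(weights)}"
        )
    if (weights < 0).any():
        raise MeasurementError("weights must be non-negative")
    return float((1000.0 / expected_n) * weights.sum())


_SUMMARY_FIELDS = (
    "L", "W", "T", "Da", "Dg", "B", "sphericity", "roundness",
    "Sp", "So", "Vp", "Vo", "Ve", "AR", "ER", "L_over_T", "L_over_Dg", "W_over_T",
)


@dataclass
class LotSummary:
    """Per-class mean ± sd of every kernel-level quantity, plus TGW."""

    class_label: str
    n: int
    table: pd.DataFrame  # index = quantity, columns = mean, sd
    thousand_grain_weight: Optional[float] = None

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        return self.table.round(decimals)


def lot_summary(dims: Iterable[AxialDims], class_label: str = "") -> LotSummary:
    """Summarize a lot: per-kernel properties first, then mean ± sd over kernels.

    The sample (n−1) standard deviation is used.  If every kernel carries a
    weight and the lot has exactly 100 kernels, thousand-grain weight is
    reported too.
    """
    dims = list(dims)
    if len(dims) < 2:
        raise MeasurementError("lot summary needs at least 2 kernels (sd undefined)")
    records = []
    for d in dims:
        p = physical_properties(d)
        rec = {"L": d.L, "W": d.W, "T": d.T}
        rec.update({k: getattr(p, k) for k in _SUMMARY_FIELDS if k not in rec})
        if d.weight is not None:
            rec["weight"] = d.weight
        records.append(rec)
    df = pd.DataFrame(records)
    table = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
    tgw = None
    if "weight" in df.columns and df["weight"].notna().all() and len(dims) == 100:
        tgw = thousand_grain_weight(df["weight"].tolist())
    return LotSummary(class_label=class_label, n=len(dims), table=table,
                      thousand_grain_weight=tgw)


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    """Read a caliper table: kernel_id, class, L_mm, W_mm, T_mm[, weight_g]."""
    df = pd.read_csv(path)
    required = {"kernel_id", "class", "L_mm", "W_mm", "T_mm"}
    missing = required - set(df.columns)
    if missing:
        raise MeasurementError(f"measurement CSV missing columns: {sorted(missing)}")
    return df
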