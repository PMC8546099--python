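"""Raster image I/O and pixel-to-millimetre calibration.

Scanner images are 24-bit colour rasters (BMP or PNG) of kernels on a
near-black background.  Internally channels are kept in (blue, green, red)
order — the order in which the processing chain consumes them — with the
order recorded on the container.  Physical calibration derives from the scan
resolution alone: at ``dpi`` dots per inch one pixel spans ``25.4 / dpi`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import CalibrationError, ImageFormatError


@dataclass
class GrainImage:
    """A 24-bit scanner image with its scan resolution.

    ``pixels`` is an H×W×3 uint8 array in the order named by
    ``channel_order`` (``"bgr"`` after loading).
    """

    pixels: np.ndarray
    dpi: int
    source_path: str = ""
    channel_order: str = "bgr"

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ImageFormatError(f"expected H×W×3 pixel array, got shape {p.shape}")
        if p.dtype != np.uint8:
            raise ImageFormatError(f"expected 8-bit channels, got dtype {p.dtype}")
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise ImageFormatError("image must have at least one row and one column")
        if self.dpi <= 0:
            raise CalibrationError(f"dpi must be positive, got {self.dpi}")
        self.pixels = p

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def rgb(self) -> np.ndarray:
        """Pixels in (red, green, blue) order."""
        if self.channel_order == "rgb":
            return self.pixels
        return self.pixels[:, :, ::-1]


@dataclass(frozen=True)
class Calibration:
    """Pixel→millimetre conversion factors implied by the scan resolution."""

    dpi: int
    mm_per_px: float = field(init=False)
    mm2_per_px2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise CalibrationError(f"dpi must be positive, got {self.dpi}")
        object.__setattr__(self, "mm_per_px", 25.4 / self.dpi)
        object.__setattr__(self, "mm2_per_px2", (25.4 / self.dpi) ** 2)


def make_calibration(dpi: int) -> Calibration:
    """Return the calibration for a scan at ``dpi`` dots per inch."""
    return Calibration(dpi=int(dpi))


def load_image(path: str | Path, dpi: int) -> GrainImage:
    """Load a 24-bit BMP or PNG and attach the scan resolution.

    The resolution is taken from the caller, not from file metadata, because
    raster metadata is unreliable; flatbed scans are acquired at a known dpi.
    """
    if dpi <= 0:
        raise CalibrationError(f"dpi must be positive, got {dpi}")
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable / truncated file
        raise ImageFormatError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise ImageFormatError(
            f"{path} is not a 24-bit colour image (shape {arr.shape}, dtype {arr.dtype})"
        )
    # files store RGB; normalize to the internal blue/green/red order
    return GrainImage(pixels=arr[:, :, ::-1].copy(), dpi=int(dpi), source_path=str(path))


def save_png(image: GrainImage | np.ndarray, path: str | Path) -> None:
    """Write a GrainImage (or an RGB uint8 array) as a 24-bit PNG."""
    if isinstance(image, GrainImage):
        rgb = image.rgb
    else:
        rgb = np.asarray(image)
        if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.dtype != np.uint8:
            raise ImageFormatError("save_png expects an H×W×3 uint8 RGB array")
    iio.imwrite(Path(path), rgb)


def split_channels(image: GrainImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split into three 8-bit planes, returned in (blue, green, red) order."""
    if image.channel_order == "bgr":
        b, g, r = (image.pixels[:, :, i].copy() for i in range(3))
    else:
        r, g, b = (image.pixels[:, :, i].copy() for i in range(3))
    return b, g, r


def merge_channels(
    blue: np.ndarray, green: np.ndarray, red: np.ndarray, dpi: int
) -> GrainImage:
    """Recombine three 8-bit planes into a GrainImage (inverse of split)."""
    return GrainImage(
        pixels=np.stack([blue, green, red], axis=-1), dpi=dpi, channel_order="bgr"
    )
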