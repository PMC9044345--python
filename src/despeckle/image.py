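"""Grayscale image container and file plumbing.

Every stage of the pipeline exchanges :class:`GrayImage` objects: a 2-D float
array of intensities together with an explicit scale declaration.  Two scales
exist — ``unit`` ([0, 1], the internal computation convention) and
``eight_bit`` ([0, 255], the interchange convention of 8-bit files).  Being
explicit about the scale avoids the classic denoising-benchmark bug of mixing
[0, 1] tensors with 0–255 noise levels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["Scale", "GrayImage", "read_image", "write_image"]


class Scale(str, enum.Enum):
    """Intensity scale convention of a :class:`GrayImage`."""

    UNIT = "unit"
    EIGHT_BIT = "eight_bit"

    @property
    def vmax(self) -> float:
        return 1.0 if self is Scale.UNIT else 255.0


@dataclass(frozen=True)
class GrayImage:
    """A single-channel intensity raster on a declared scale.

    Parameters
    ----------
    pixels
        2-D float array of intensities, shape ``(height, width)``.
    scale
        Which closed interval the intensities are declared to live in.
    """

    pixels: np.ndarray
    scale: Scale = Scale.UNIT

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        object.__setattr__(self, "pixels", px)
        if not isinstance(self.scale, Scale):
            object.__setattr__(self, "scale", Scale(self.scale))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def vmax(self) -> float:
        return self.scale.vmax

    def clipped(self) -> "GrayImage":
        """Return a copy clipped to the declared scale's closed interval."""
        return GrayImage(np.clip(self.pixels, 0.0, self.vmax), self.scale)

    def to_unit(self) -> "GrayImage":
        if self.scale is Scale.UNIT:
            return self
        return GrayImage(self.pixels / 255.0, Scale.UNIT)

    def to_eight_bit(self) -> "GrayImage":
        if self.scale is Scale.EIGHT_BIT:
            return self
        return GrayImage(self.pixels * 255.0, Scale.EIGHT_BIT)


def read_image(path: str | Path) -> GrayImage:
    """Read a grayscale PNG/TIFF into a unit-scale :class:`GrayImage`.

    8-bit files map to [0, 1] by division by 255; 16-bit by 65535; float TIFF
    files are taken as already unit-scale.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:  # collapse RGB(A) via luminance-free mean of color planes
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype == np.uint8:
        px = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        px = arr.astype(np.float64) / 65535.0
    else:
        px = arr.astype(np.float64)
    return GrayImage(px, Scale.UNIT)


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write to PNG (8-bit) or TIFF (32-bit float) chosen by file suffix.

    8-bit quantization uses round-half-even on ``pixels * 255`` after clipping,
    the inverse of :func:`read_image`'s division convention.
    """
    path = Path(path)
    unit = image.to_unit().clipped()
    if path.suffix.lower() in {".tif", ".tiff"}:
        iio.imwrite(path, unit.pixels.astype(np.float32))
    else:
        quantized = np.rint(unit.pixels * 255.0).astype(np.uint8)
        iio.imwrite(path, quantized)
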