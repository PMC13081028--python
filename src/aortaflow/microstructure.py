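"""Elastic-fiber porosity from en-face images.

Porosity is the percent image area classified as elastin-void after
thresholding an en-face elastin channel.  Images are expected
pore-highlighted (bright = void); the default threshold is Otsu's method
with a fixed-cut override for protocols that prescribe one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from imageio.v3 import imread as _imread
from skimage.filters import threshold_otsu

__all__ = ["GrayImage", "PorosityResult", "porosity", "load_image"]


@dataclass
class GrayImage:
    """2D grayscale intensity image with physical pixel size metadata."""

    data: np.ndarray
    pixel_size_um: float | None = None
    channel: str = "elastin"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("data must be a non-empty 2D array")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class PorosityResult:
    percent: float
    threshold: float
    method: str
    polarity: str  # 'above' -> bright pixels counted as pores

    def to_dict(self) -> dict:
        return {
            "percent": self.percent,
            "threshold": self.threshold,
            "method": self.method,
            "polarity": self.polarity,
        }


def porosity(
    image: GrayImage,
    method: str = "otsu",
    fixed_cut: float = 0.5,
    polarity: str = "above",
) -> PorosityResult:
    """Percent thresholded area of an en-face image.

    ``polarity="above"`` counts pixels strictly above the threshold as
    pores (the pore-highlighted convention); ``"below"`` inverts.  A
    constant image defeats Otsu and falls back to ``fixed_cut`` with a
    warning.
    """
    if polarity not in ("above", "below"):
        raise ValueError("polarity must be 'above' or 'below'")
    data = image.data
    if method == "fixed":
        cut, used = float(fixed_cut), "fixed"
    elif method == "otsu":
        if np.ptp(data) == 0:
            warnings.warn("constant image: Otsu undefined, falling back to fixed_cut")
            cut, used = float(fixed_cut), "fixed(fallback)"
        else:
            cut, used = float(threshold_otsu(data)), "otsu"
    else:
        raise ValueError("method must be 'otsu' or 'fixed'")
    white = data > cut if polarity == "above" else data < cut
    pct = 100.0 * float(np.count_nonzero(white)) / data.size
    return PorosityResult(percent=pct, threshold=cut, method=used, polarity=polarity)


def load_image(path: str | Path, pixel_size_um: float | None = None) -> GrayImage:
    """Read a TIFF/PNG image as a grayscale :class:`GrayImage`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = _imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    return GrayImage(data=arr, pixel_size_um=pixel_size_um)
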