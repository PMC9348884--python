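"""Adaptive local thresholding of the cropped region of interest.

The greyscale ROI is reduced to a {0,1} jet mask by comparing each pixel
against a Gaussian-weighted mean of its WxW neighbourhood minus a fixed
offset C (defaults W=13, C=7 on the 16-bit scale). A *local* threshold makes
the mask robust to the slow illumination non-uniformities that a global
threshold would turn into spatially varying bias.

Polarity: in the raw shadowgraph the jet is *dark* on a bright background,
but the downstream break scan expects jet pixels to carry the value 1
(white). With the default ``dark_jet`` polarity a pixel is jet when it is
darker than its local mean by more than C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .errors import ParameterError
from .frame_io import Frame, PipelineConfig


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} jet mask with the shape of its source crop."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ParameterError("mask must be 2-D")
        if not np.isin(v, (0, 1)).all():
            raise ParameterError("mask values must be 0 or 1")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def gaussian_kernel_1d(window: int, sigma: float) -> np.ndarray:
    """Symmetric 1-D Gaussian sampled on a window, normalised to unit sum."""
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and positive, got {window}")
    if not sigma > 0:
        raise ParameterError("sigma must be positive")
    half = window // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    return g / g.sum()


def local_gaussian_mean(img: np.ndarray | Frame, window: int, sigma: float) -> np.ndarray:
    """Per-pixel Gaussian-weighted mean over the WxW window centred on it.

    Weights are a normalised 2-D Gaussian (the outer product of two 1-D
    kernels, applied separably); borders use half-sample symmetric
    reflection (the edge row/column is repeated) so edge pixels are averaged
    against mirrored image content rather than an arbitrary constant.
    """
    pixels = img.pixels if isinstance(img, Frame) else np.asarray(img)
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if window > min(pixels.shape):
        raise ParameterError(
            f"window {window} exceeds image extent {pixels.shape}"
        )
    g = gaussian_kernel_1d(window, sigma)
    out = pixels.astype(np.float64)
    out = correlate1d(out, g, axis=0, mode="reflect")
    out = correlate1d(out, g, axis=1, mode="reflect")
    return out


def write_mask_png(mask: BinaryMask, path) -> None:
    """Debug output: the mask as an 8-bit PNG with jet pixels at 255."""
    from imageio.v3 import imwrite

    imwrite(path, (mask.values * 255).astype(np.uint8))


def binarize(img: Frame, cfg: PipelineConfig) -> BinaryMask:
    """Threshold a greyscale crop into a jet mask.

    ``dark_jet`` polarity: mask = 1 where pixel < local mean - C.
    ``bright_jet`` polarity: mask = 1 where pixel > local mean + C.
    """
    mean = local_gaussian_mean(img, cfg.threshold_window, cfg.sigma)
    pixels = img.pixels.astype(np.float64)
    if cfg.polarity == "dark_jet":
        mask = pixels < mean - cfg.threshold_offset
    else:
        mask = pixels > mean + cfg.threshold_offset
    return BinaryMask(values=mask.astype(np.uint8))
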