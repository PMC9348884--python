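"""Frame and configuration I/O.

Frames are single-channel images in the unsigned 16-bit range. The side
microscope that motivates this package records 16-bit greyscale frames at a
fixed rate; 8-bit inputs are accepted and rescaled to the 16-bit range by
multiplication with 257 so the rest of the pipeline sees one intensity scale.

Coordinates are 0-based, row-major, origin at the top-left; boxes are
half-open ``[top, top+h) x [left, left+w)``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile
import yaml
from imageio.v3 import imread, imwrite

from .errors import ConfigError, DimensionError, FormatError

MIN_FRAME_SIDE = 32
U16_MAX = 65535


@dataclass(frozen=True)
class Frame:
    """One greyscale microscope frame with acquisition metadata.

    Parameters
    ----------
    pixels
        2-D intensity array, values within [0, 65535].
    index
        Non-negative position of the frame within its sequence.
    pixel_size_um
        Physical size of one pixel in micrometres. Required because the
        break-distance rule is stated in micrometres.
    """

    pixels: np.ndarray
    index: int = 0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"frame must be single-channel 2-D, got shape {px.shape}")
        if px.shape[0] < MIN_FRAME_SIDE or px.shape[1] < MIN_FRAME_SIDE:
            raise DimensionError(
                f"frame must be at least {MIN_FRAME_SIDE}x{MIN_FRAME_SIDE}, got {px.shape}"
            )
        if self.index < 0:
            raise ValueError("frame index must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if px.min() < 0 or px.max() > U16_MAX:
            raise ValueError("intensities must lie within [0, 65535]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


_POLARITIES = ("dark_jet", "bright_jet")
_WINDOW_MODES = ("sliding", "tumbling")
_SCAN_AXES = ("rows", "columns")


@dataclass
class PipelineConfig:
    """All tunable parameters of the hit/miss pipeline.

    Defaults reproduce the reference algorithm settings: a 13x13
    Gaussian-weighted local threshold window with offset C=7, a maximum
    accepted gap of 20 px, breaks counted only within 200 um of the nozzle,
    and a 10-frame sliding FIFO window for instance decisions.
    """

    pixel_size_um: float
    template_path: str | None = None
    roi_length_px: int = 400
    roi_halfwidth_px: int = 100
    threshold_window: int = 13
    threshold_offset: float = 7.0
    threshold_sigma: float | None = None  # None -> 0.3*((W-1)/2 - 1) + 0.8
    max_gap_px: int = 20
    max_break_distance_um: float = 200.0
    min_run: int = 2
    sma_window: int = 10
    polarity: str = "dark_jet"
    window_mode: str = "sliding"
    scan_axis: str = "rows"
    rematch_every: int = 0  # 0 -> match template once, on the first frame

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ConfigError("pixel_size_um must be positive")
        if self.threshold_window < 3 or self.threshold_window % 2 == 0:
            raise ConfigError(
                f"threshold window W must be an odd integer >= 3, got {self.threshold_window}"
            )
        if self.max_gap_px < 1:
            raise ConfigError("max_gap_px must be >= 1")
        if self.sma_window < 1:
            raise ConfigError("sma_window must be >= 1")
        if self.min_run < 1:
            raise ConfigError("min_run must be >= 1")
        if self.roi_length_px < 1 or self.roi_halfwidth_px < 1:
            raise ConfigError("ROI extents must be positive")
        if not self.max_break_distance_um > 0:
            raise ConfigError("max_break_distance_um must be positive")
        if self.polarity not in _POLARITIES:
            raise ConfigError(f"polarity must be one of {_POLARITIES}")
        if self.window_mode not in _WINDOW_MODES:
            raise ConfigError(f"window_mode must be one of {_WINDOW_MODES}")
        if self.scan_axis not in _SCAN_AXES:
            raise ConfigError(f"scan_axis must be one of {_SCAN_AXES}")

    @property
    def sigma(self) -> float:
        """Gaussian width used for the local-mean weights.

        When unset, follows the conventional window-to-sigma mapping of
        imaging toolkits: ``0.3*((W-1)/2 - 1) + 0.8``.
        """
        if self.threshold_sigma is not None:
            return self.threshold_sigma
        return 0.3 * ((self.threshold_window - 1) / 2 - 1) + 0.8

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_frame(path: str | os.PathLike, index: int = 0, pixel_size_um: float = 1.0) -> Frame:
    """Read one greyscale frame from a TIFF or PNG file.

    8-bit inputs are rescaled to the 16-bit range (x257, so 255 -> 65535);
    native 16-bit data pass through losslessly. Multi-channel images are
    rejected rather than converted: the pipeline is defined on the raw
    single-channel microscope signal.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such image file: {path}")
    try:
        data = imread(path)
    except Exception as exc:  # decoder failure -> I/O error per contract
        raise IOError(f"could not decode image {path}: {exc}") from exc
    if data.ndim == 3:
        raise FormatError(f"{path}: expected single-channel image, got shape {data.shape}")
    if data.dtype == np.uint8:
        data = data.astype(np.uint16) * 257
    elif data.dtype != np.uint16:
        arr = np.asarray(data)
        if arr.min() < 0 or arr.max() > U16_MAX:
            raise FormatError(f"{path}: intensities outside the unsigned 16-bit range")
        data = arr.astype(np.uint16)
    return Frame(pixels=data, index=index, pixel_size_um=pixel_size_um)


def write_frame(frame: Frame, path: str | os.PathLike) -> None:
    """Write a frame as 16-bit TIFF or PNG (chosen from the file suffix)."""
    path = Path(path)
    data = frame.pixels.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        imwrite(path, data)


def iterate_sequence(
    directory: str | os.PathLike, pattern: str = "*.tif*", pixel_size_um: float = 1.0
) -> Iterator[Frame]:
    """Yield frames from a directory in lexicographic filename order.

    The sequence index is assigned 0,1,2,... in that order regardless of
    filesystem creation order; an empty directory yields nothing.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"no such directory: {directory}")
    for i, path in enumerate(sorted(directory.glob(pattern))):
        yield read_frame(path, index=i, pixel_size_um=pixel_size_um)


_CONFIG_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load a PipelineConfig from a YAML key:value file.

    Unspecified keys fall back to the reference defaults; ``pixel_size_um``
    has no default and must be present (the micrometre-valued break rule is
    meaningless without the optical scale).
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such config file: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a key:value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "pixel_size_um" not in raw:
        raise ConfigError(f"{path}: pixel_size_um is required (um per pixel)")
    return PipelineConfig(**raw)
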