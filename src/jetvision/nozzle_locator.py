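"""Nozzle localisation by template matching and region-of-interest derivation.

The nozzle is the one stable landmark in a jet-monitoring image: the
background and nozzle silhouette stay essentially constant over an
experiment while the jet below it moves and changes character. Matching a
geometric outline of the nozzle against each frame therefore anchors a
region of interest (ROI) that contains the jet and the beam interaction
point, and all further analysis happens inside that crop.

Similarity is scored with the zero-normalised cross-correlation coefficient
(ZNCC): template and image window are each mean-subtracted and scaled by
their standard deviations, so the score lies in [-1, 1] and is invariant to
affine intensity changes (a*I + b, a > 0) — exactly the robustness needed
under non-uniform, drifting illumination. The placement with the maximum
coefficient wins; ties break to the smallest row, then smallest column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .errors import DimensionError, LocationError
from .frame_io import MIN_FRAME_SIDE, Frame, PipelineConfig


@dataclass(frozen=True)
class NozzleTemplate:
    """A reference image of the nozzle and the tip position inside it."""

    pixels: np.ndarray
    tip_offset_rc: tuple[int, int]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise DimensionError("template must be a non-empty 2-D array")
        r, c = self.tip_offset_rc
        if not (0 <= r < px.shape[0] and 0 <= c < px.shape[1]):
            raise ValueError("tip_offset_rc must lie inside the template")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class MatchResult:
    top_left_rc: tuple[int, int]
    score: float
    tip_rc: tuple[int, int]


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open box [top, top+height) x [left, left+width)."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise LocationError("ROI must be non-empty")


def _window_sums(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Sum of arr over every valid shape-sized window, via an integral image."""
    h, w = shape
    c = np.pad(arr, ((1, 0), (1, 0))).cumsum(axis=0).cumsum(axis=1)
    return c[h:, w:] - c[:-h, w:] - c[h:, :-w] + c[:-h, :-w]


def zncc_map(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """ZNCC coefficient for every valid template placement.

    Output shape is ``(H-h+1, W-w+1)``. Windows with (numerically) zero
    variance are assigned score 0: a flat window carries no evidence for or
    against the template.
    """
    img = np.asarray(image, dtype=np.float64)
    tpl = np.asarray(template, dtype=np.float64)
    if tpl.shape[0] > img.shape[0] or tpl.shape[1] > img.shape[1]:
        raise DimensionError(
            f"template {tpl.shape} does not fit inside image {img.shape}"
        )
    n = tpl.size
    t0 = tpl - tpl.mean()
    t_norm = np.sqrt((t0**2).sum())

    num = fftconvolve(img, t0[::-1, ::-1], mode="valid")
    s1 = _window_sums(img, tpl.shape)
    s2 = _window_sums(img**2, tpl.shape)
    win_ssd = np.clip(s2 - s1**2 / n, 0.0, None)  # n * window variance

    # Flat-window guard: integral images accumulate roundoff of order
    # eps * (total image sum), so threshold relative to that scale.
    scale = float(np.abs(img).max()) or 1.0
    flat = win_ssd <= np.finfo(np.float64).eps * img.size * scale**2
    if t_norm == 0.0:
        return np.zeros(num.shape)

    denom = np.sqrt(win_ssd) * t_norm
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(flat | (denom == 0.0), 0.0, num / np.where(denom == 0, 1, denom))
    return np.clip(score, -1.0, 1.0)


def match_template(frame: Frame, template: NozzleTemplate) -> MatchResult:
    """Best nozzle placement in a frame under the ZNCC criterion.

    Ties break to the first maximum in row-major order, so the result is
    deterministic for a given frame/template pair.
    """
    score = zncc_map(frame.pixels, template.pixels)
    flat_idx = int(np.argmax(score))  # row-major first maximum
    top, left = np.unravel_index(flat_idx, score.shape)
    tr, tc = template.tip_offset_rc
    return MatchResult(
        top_left_rc=(int(top), int(left)),
        score=float(score[top, left]),
        tip_rc=(int(top) + tr, int(left) + tc),
    )


def derive_roi(
    match: MatchResult, cfg: PipelineConfig, frame_shape: tuple[int, int]
) -> RegionOfInterest:
    """ROI anchored at the matched nozzle tip.

    The box starts at the tip row, extends ``roi_length_px`` downstream and
    ``roi_halfwidth_px`` to each side of the tip column, clipped to the
    frame. A clipped box smaller than the minimum analysable size (the
    threshold window, and the 32-px frame minimum) in either dimension
    raises :class:`LocationError`.
    """
    rows, cols = frame_shape
    tip_r, tip_c = match.tip_rc
    top = max(tip_r, 0)
    bottom = min(tip_r + cfg.roi_length_px, rows)
    left = max(tip_c - cfg.roi_halfwidth_px, 0)
    right = min(tip_c + cfg.roi_halfwidth_px, cols)
    w = max(cfg.threshold_window, MIN_FRAME_SIDE)
    if bottom - top < w or right - left < w:
        raise LocationError(
            f"ROI from tip {match.tip_rc} clips to {bottom - top}x{right - left}; "
            f"need at least {w}x{w} to analyse"
        )
    return RegionOfInterest(top=top, left=left, height=bottom - top, width=right - left)


def crop(frame: Frame, roi: RegionOfInterest) -> Frame:
    """Extract the ROI sub-image; metadata is preserved."""
    rows, cols = frame.shape
    if roi.top < 0 or roi.left < 0 or roi.top + roi.height > rows or roi.left + roi.width > cols:
        raise LocationError(f"ROI {roi} exceeds frame shape {frame.shape}")
    sub = frame.pixels[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width]
    return Frame(pixels=sub, index=frame.index, pixel_size_um=frame.pixel_size_um)


# ---------------------------------------------------------------------------
# Default template geometry
# ---------------------------------------------------------------------------

def nozzle_silhouette(height: int = 40, width: int = 64, tip_halfwidth: int = 3) -> tuple[np.ndarray, tuple[int, int]]:
    """Boolean raster of a gas-focusing nozzle outline and its tip position.

    A simple symmetric taper: the body spans most of the top row and narrows
    linearly to a blunt tip at the bottom-centre, the shape a backlit
    gas-dynamic virtual nozzle presents to a side microscope. Shared between
    the default matching template and the synthetic scene renderer, so a
    rendered scene contains an exact copy of the template.
    """
    mask = np.zeros((height, width), dtype=bool)
    top_halfwidth = width // 2 - 2
    center = width // 2
    for r in range(height):
        frac = r / max(height - 1, 1)
        hw = int(round(top_halfwidth + frac * (tip_halfwidth - top_halfwidth)))
        mask[r, max(center - hw, 0) : min(center + hw + 1, width)] = True
    return mask, (height - 1, center)


def default_nozzle_template(
    height: int = 40,
    width: int = 64,
    background_level: int = 50000,
    nozzle_level: int = 8000,
) -> NozzleTemplate:
    """The default dark-silhouette nozzle template on a bright background."""
    mask, tip = nozzle_silhouette(height, width)
    pixels = np.full(mask.shape, background_level, dtype=np.uint16)
    pixels[mask] = nozzle_level
    return NozzleTemplate(pixels=pixels, tip_offset_rc=tip)
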