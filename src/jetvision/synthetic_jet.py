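"""Labelled synthetic shadowgraph scenes of a nozzle and liquid jet.

No imagery ships with the method this package implements, so every
downstream stage is exercised against rendered scenes that emulate the
phenomenology of a backlit side-microscope view: a dark nozzle silhouette at
the top of the frame, a dark quasi-vertical jet column a few pixels wide on
a bright background, spontaneous droplet breakup far from the nozzle, and —
for a "hit", when the X-ray pulse intersects the jet — a full-width gap in
the column near the interaction point, optionally surrounded by splatter
speckle. Illumination ramps and additive Gaussian noise are available as
nuisance effects.

The renderer is purely phenomenological: no Rayleigh-breakup or explosion
hydrodynamics, just geometry that carries an exact ground-truth label.
Identical parameters (including the seed) render bit-identical frames.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from math import radians, tan

import numpy as np

from .errors import ParameterError
from .frame_io import Frame, U16_MAX
from .nozzle_locator import nozzle_silhouette


@dataclass(frozen=True)
class SceneParams:
    """Geometry, photometry and nuisance parameters of one rendered scene.

    Micrometre-valued parameters are converted to pixels with
    ``pixel_size_um``; the defaults use a 1 um/px scale so the 200 um
    break-distance rule corresponds to 200 rows.
    """

    height_px: int = 448
    width_px: int = 320
    background_level: float = 50000.0
    jet_level: float = 8000.0
    nozzle_tip_rc: tuple[int, int] = (40, 160)
    jet_width_px: int = 4
    jet_angle_deg: float = 0.0
    breakup_length_um: float = 350.0
    pixel_size_um: float = 1.0
    is_hit: bool = False
    break_center_um: float = 100.0
    break_gap_px: int = 10
    splatter: bool = True
    splatter_dots: int = 30
    splatter_radius_px: float = 25.0
    illum_gradient: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 32 or self.width_px < 32:
            raise ParameterError("scene must be at least 32x32")
        if self.jet_width_px < 1 or self.break_gap_px < 1:
            raise ParameterError("jet width and break gap must be positive")
        if not (self.breakup_length_um > 0 and self.pixel_size_um > 0):
            raise ParameterError("breakup length and pixel size must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.is_hit:
            if self.break_center_um >= self.breakup_length_um:
                raise ParameterError(
                    "a hit's break must lie upstream of the spontaneous breakup: "
                    f"break_center_um={self.break_center_um} >= "
                    f"breakup_length_um={self.breakup_length_um}"
                )
            if self.break_center_um - self.break_gap_px * self.pixel_size_um / 2 <= 0:
                raise ParameterError("break gap must lie strictly below the nozzle tip")

    def replace(self, **kwargs) -> "SceneParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class JitterSpec:
    """Frame-to-frame perturbation of jet angle and lateral nozzle position."""

    angle_sd_deg: float = 0.0
    lateral_sd_px: float = 0.0


def _gap_band(p: SceneParams) -> tuple[int, int]:
    """Half-open row-offset band (from the tip) removed by a hit."""
    center_px = p.break_center_um / p.pixel_size_um
    start = int(round(center_px - p.break_gap_px / 2))
    return start, start + p.break_gap_px


def _draw_jet_rows(img: np.ndarray, p: SceneParams, d_from: int, d_to: int) -> None:
    """Paint jet-level pixels for tip-offset rows [d_from, d_to)."""
    tip_r, tip_c = p.nozzle_tip_rc
    slope = tan(radians(p.jet_angle_deg))
    for d in range(d_from, d_to):
        r = tip_r + d
        if r < 0 or r >= p.height_px:
            continue
        center = tip_c + slope * d
        c0 = int(round(center - p.jet_width_px / 2))
        img[r, max(c0, 0) : min(c0 + p.jet_width_px, p.width_px)] = p.jet_level


def render_scene(p: SceneParams) -> tuple[Frame, bool]:
    """Render one scene; returns the frame and its ground-truth hit label."""
    rng = np.random.default_rng(p.seed)
    cols = np.arange(p.width_px, dtype=np.float64)
    img = np.full((p.height_px, p.width_px), p.background_level, dtype=np.float64)
    img += p.illum_gradient * cols  # linear illumination ramp across columns

    # Nozzle silhouette, tip anchored at nozzle_tip_rc.
    sil, (sil_tr, sil_tc) = nozzle_silhouette()
    tip_r, tip_c = p.nozzle_tip_rc
    top, left = tip_r - sil_tr, tip_c - sil_tc
    rr, cc = np.nonzero(sil)
    rr, cc = rr + top, cc + left
    keep = (rr >= 0) & (rr < p.height_px) & (cc >= 0) & (cc < p.width_px)
    img[rr[keep], cc[keep]] = p.jet_level

    # Continuous jet column from the tip down to the spontaneous breakup
    # point, skipping the explosion gap on hit frames.
    breakup_d = int(round(p.breakup_length_um / p.pixel_size_um))
    if p.is_hit:
        g0, g1 = _gap_band(p)
        _draw_jet_rows(img, p, 1, max(g0, 1))
        _draw_jet_rows(img, p, g1, breakup_d)
    else:
        _draw_jet_rows(img, p, 1, breakup_d)

    # Disconnected droplets beyond the breakup length.
    d = breakup_d
    max_d = p.height_px - tip_r
    while d < max_d:
        d += int(rng.integers(4, 9))  # inter-droplet gap
        drop_len = int(rng.integers(3, 7))
        _draw_jet_rows(img, p, d, min(d + drop_len, max_d))
        d += drop_len

    # Splatter: dark speckle ejected around the explosion, kept out of the
    # gap band itself (material leaves the void it creates).
    if p.is_hit and p.splatter and p.splatter_dots > 0:
        g0, g1 = _gap_band(p)
        center_d = p.break_center_um / p.pixel_size_um
        slope = tan(radians(p.jet_angle_deg))
        cr = tip_r + center_d
        cc_ = tip_c + slope * center_d
        theta = rng.uniform(0.0, 2 * np.pi, size=p.splatter_dots)
        rad = p.splatter_radius_px * np.sqrt(rng.uniform(0.0, 1.0, size=p.splatter_dots))
        for t, s in zip(theta, rad):
            dr = int(round(cr + s * np.sin(t)))
            dc = int(round(cc_ + s * np.cos(t)))
            if tip_r + g0 - 1 <= dr + 1 and dr - 1 < tip_r + g1 + 1:
                continue  # would touch the gap band
            r0, r1 = max(dr - 1, 0), min(dr + 2, p.height_px)
            c0, c1 = max(dc - 1, 0), min(dc + 2, p.width_px)
            img[r0:r1, c0:c1] = p.jet_level

    if p.noise_sd > 0:
        img += rng.normal(0.0, p.noise_sd, size=img.shape)

    pixels = np.clip(np.rint(img), 0, U16_MAX).astype(np.uint16)
    return Frame(pixels=pixels, index=0, pixel_size_um=p.pixel_size_um), p.is_hit


def _labels(
    n: int,
    hit_pattern: list[bool] | None,
    hit_fraction: float | None,
    rng: np.random.Generator,
) -> list[bool]:
    if hit_pattern is not None:
        if len(hit_pattern) != n:
            raise ParameterError(f"hit_pattern length {len(hit_pattern)} != n={n}")
        return [bool(b) for b in hit_pattern]
    if hit_fraction is not None:
        if not 0.0 <= hit_fraction <= 1.0:
            raise ParameterError("hit_fraction must lie in [0, 1]")
        k = int(round(hit_fraction * n))
        labels = np.array([True] * k + [False] * (n - k))
        rng.shuffle(labels)  # stratified assignment, seeded shuffle: counts exact
        return [bool(b) for b in labels]
    return [False] * n


def generate_sequence(
    n: int,
    base: SceneParams,
    hit_pattern: list[bool] | None = None,
    hit_fraction: float | None = None,
    jitter: JitterSpec | None = None,
    seed: int = 0,
) -> tuple[list[Frame], list[bool]]:
    """Render a labelled frame sequence.

    Labels come from ``hit_pattern`` verbatim, or from ``hit_fraction`` as
    exactly ``round(hit_fraction * n)`` hits placed by a seeded shuffle;
    with neither, every frame is a miss. Jitter perturbs the jet angle and
    the lateral nozzle position independently per frame. All randomness
    (labels, per-frame render seeds, jitter) derives from ``seed``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if hit_pattern is not None and hit_fraction is not None:
        raise ParameterError("give hit_pattern or hit_fraction, not both")
    master = np.random.default_rng(seed)
    labels = _labels(n, hit_pattern, hit_fraction, master)
    scene_seeds = master.integers(0, 2**31 - 1, size=n)
    jitter = jitter or JitterSpec()
    d_angle = master.normal(0.0, jitter.angle_sd_deg, size=n) if jitter.angle_sd_deg > 0 else np.zeros(n)
    d_lat = master.normal(0.0, jitter.lateral_sd_px, size=n) if jitter.lateral_sd_px > 0 else np.zeros(n)

    frames: list[Frame] = []
    tip_r, tip_c = base.nozzle_tip_rc
    for i in range(n):
        params = base.replace(
            is_hit=labels[i],
            seed=int(scene_seeds[i]),
            jet_angle_deg=base.jet_angle_deg + float(d_angle[i]),
            nozzle_tip_rc=(tip_r, tip_c + int(round(d_lat[i]))),
        )
        frame, _ = render_scene(params)
        frames.append(Frame(pixels=frame.pixels, index=i, pixel_size_um=base.pixel_size_um))
    return frames, labels
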