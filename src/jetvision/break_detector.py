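"""Row scan of the binarised ROI for a beam-induced break in the jet.

A hit shows up as a *simultaneous* discontinuity on both sides of the
binarised jet — i.e. a band of rows containing no jet pixels at all, bounded
by jet rows above and below. Two rules separate a beam-induced break from
the spontaneous droplet breakup every jet exhibits far from the nozzle:

* the gap may be at most ``max_gap_px`` rows tall (default 20), and
* its upstream edge must lie within ``max_break_distance_um`` of the nozzle
  tip (default 200 um) — droplets typically form farther out, so distance
  alone excludes them. The trailing droplet region is additionally never a
  bounded gap (nothing below it), so it can never qualify.

Row 0 of the ROI is the nozzle tip row; distances are row offsets times the
pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .binarization import BinaryMask, binarize
from .errors import DimensionError
from .frame_io import Frame, PipelineConfig
from .nozzle_locator import MatchResult, NozzleTemplate, crop, derive_roi, match_template


@dataclass(frozen=True)
class JetPresenceProfile:
    """Per-row jet presence in the ROI (row 0 = nozzle tip row)."""

    present: np.ndarray  # 1-D bool

    def __post_init__(self) -> None:
        p = np.asarray(self.present, dtype=bool)
        if p.ndim != 1 or p.size == 0:
            raise DimensionError("profile must be a non-empty 1-D boolean array")
        object.__setattr__(self, "present", p)

    def __len__(self) -> int:
        return self.present.size


@dataclass(frozen=True)
class BreakEvent:
    """A bounded full-width gap in the jet.

    ``gap_start_row``/``gap_end_row`` delimit the jet-free rows (half-open);
    ``distance_um`` is the axial distance of the upstream gap edge from the
    nozzle tip.
    """

    gap_start_row: int
    gap_end_row: int
    distance_um: float

    @property
    def gap_px(self) -> int:
        return self.gap_end_row - self.gap_start_row


@dataclass(frozen=True)
class FrameVerdict:
    index: int
    is_hit: bool
    events: tuple[BreakEvent, ...] = ()
    no_jet: bool = False  # no jet rows found anywhere: flagged, never a hit
    match_score: float | None = None


def jet_profile(mask: BinaryMask, min_run: int = 2) -> JetPresenceProfile:
    """Row-by-row presence scan.

    A row counts as containing jet when it holds at least ``min_run``
    *contiguous* jet pixels; requiring a short run (default 2) keeps single
    salt-noise pixels from masquerading as jet material.
    """
    values = mask.values.astype(bool)
    if min_run > values.shape[1]:
        present = np.zeros(values.shape[0], dtype=bool)
    elif min_run == 1:
        present = values.any(axis=1)
    else:
        runs = sliding_window_view(values, min_run, axis=1).all(axis=-1)
        present = runs.any(axis=1)
    return JetPresenceProfile(present=present)


def find_breaks(profile: JetPresenceProfile, cfg: PipelineConfig) -> list[BreakEvent]:
    """All qualifying gaps in a presence profile.

    A maximal run of jet-free rows becomes a :class:`BreakEvent` iff it is
    bounded by jet rows on both sides, spans at most ``max_gap_px`` rows and
    starts within ``max_break_distance_um`` of row 0.
    """
    p = profile.present
    events: list[BreakEvent] = []
    # Boundaries of maximal false-runs.
    padded = np.concatenate(([True], p, [True]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == -1)
    ends = np.flatnonzero(diff == 1)
    for s, e in zip(starts, ends):
        if s == 0 or e == p.size:
            continue  # not bounded by jet rows on both sides
        gap = e - s
        distance_um = s * cfg.pixel_size_um
        if gap <= cfg.max_gap_px and distance_um <= cfg.max_break_distance_um:
            events.append(BreakEvent(gap_start_row=int(s), gap_end_row=int(e), distance_um=float(distance_um)))
    return events


class JetPipeline:
    """Frame-level hit/miss pipeline with a cached nozzle match.

    Composes template matching -> ROI derivation -> crop -> binarisation ->
    row scan. Because the nozzle and background stay essentially constant
    over a run while the jet varies, the template match from the first frame
    is reused; set ``cfg.rematch_every`` to k > 0 to re-run the match every
    k frames.
    """

    def __init__(self, template: NozzleTemplate, cfg: PipelineConfig) -> None:
        self.template = template
        self.cfg = cfg
        self._match: MatchResult | None = None
        self._frames_since_match = 0

    def _current_match(self, frame: Frame) -> MatchResult:
        k = self.cfg.rematch_every
        if self._match is None or (k > 0 and self._frames_since_match >= k):
            self._match = match_template(frame, self.template)
            self._frames_since_match = 0
        self._frames_since_match += 1
        return self._match

    def classify(self, frame: Frame) -> FrameVerdict:
        if self.cfg.scan_axis == "columns":
            frame = Frame(frame.pixels.T, frame.index, frame.pixel_size_um)
        match = self._current_match(frame)
        roi = derive_roi(match, self.cfg, frame.shape)
        region = crop(frame, roi)
        mask = binarize(region, self.cfg)
        profile = jet_profile(mask, self.cfg.min_run)
        if not profile.present.any():
            return FrameVerdict(index=frame.index, is_hit=False, no_jet=True, match_score=match.score)
        events = find_breaks(profile, self.cfg)
        return FrameVerdict(
            index=frame.index,
            is_hit=bool(events),
            events=tuple(events),
            match_score=match.score,
        )


def classify_frame(frame: Frame, template: NozzleTemplate, cfg: PipelineConfig) -> FrameVerdict:
    """Classify a single frame (fresh template match; see :class:`JetPipeline`
    for sequence processing with a cached match)."""
    return JetPipeline(template, cfg).classify(frame)
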