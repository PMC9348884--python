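"""Instance-level decisions from a FIFO buffer of recent frame verdicts.

Single frames are noisy evidence: imaging noise and sub-100 ms jet
fluctuations produce occasional spurious frame verdicts, while the drifts
worth correcting evolve over seconds. Frame verdicts are therefore pooled
over a sliding first-in-first-out window (default 10 frames, i.e. 1 s at a
10 Hz camera): if any frame in the window is a hit, the whole instance is a
hit. This is the degenerate-but-exact form of a simple moving average with
threshold 1/window.

The default window slides one frame at a time, emitting one instance verdict
per frame from only past frames (causal). A ``tumbling`` mode instead emits
one verdict per disjoint window, mirroring a strict "one decision per
second" reading.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator

from .break_detector import FrameVerdict
from .errors import SequencingError
from .frame_io import PipelineConfig


@dataclass(frozen=True)
class InstanceVerdict:
    window_end_index: int
    frame_hits: tuple[bool, ...]
    is_hit: bool
    window_full: bool


class FifoClassifier:
    """Sliding-window OR over the most recent frame verdicts.

    Verdicts must be pushed in increasing index order. Before the buffer
    fills, decisions use the partial window, which preserves the "any hit
    implies hit" semantics from the very first frame.
    """

    def __init__(self, sma_window: int) -> None:
        if sma_window < 1:
            raise ValueError("sma_window must be >= 1")
        self.sma_window = sma_window
        self._buffer: deque[bool] = deque(maxlen=sma_window)
        self._last_index: int | None = None

    def push(self, verdict: FrameVerdict) -> InstanceVerdict:
        if self._last_index is not None and verdict.index <= self._last_index:
            raise SequencingError(
                f"frame index {verdict.index} pushed after {self._last_index}"
            )
        self._last_index = verdict.index
        self._buffer.append(bool(verdict.is_hit))
        hits = tuple(self._buffer)
        return InstanceVerdict(
            window_end_index=verdict.index,
            frame_hits=hits,
            is_hit=any(hits),
            window_full=len(hits) == self.sma_window,
        )


def classify_stream(
    verdicts: Iterable[FrameVerdict], cfg: PipelineConfig
) -> Iterator[InstanceVerdict]:
    """Instance verdicts for a stream of frame verdicts.

    Sliding mode yields one instance per frame (the trailing-window OR);
    tumbling mode yields one instance per disjoint window of ``sma_window``
    frames, plus a final partial window if the stream ends mid-block.
    """
    fifo = FifoClassifier(cfg.sma_window)
    if cfg.window_mode == "sliding":
        for v in verdicts:
            yield fifo.push(v)
        return
    pending: InstanceVerdict | None = None
    count = 0
    for v in verdicts:
        pending = fifo.push(v)
        count += 1
        if count == cfg.sma_window:
            yield pending
            fifo = FifoClassifier(cfg.sma_window)
            pending = None
            count = 0
    if pending is not None:
        yield pending


def windowed_or(frame_hits: Iterable[bool], window: int) -> list[bool]:
    """Trailing-window OR of a boolean series (the instance-truth analogue
    of the sliding FIFO applied to ground-truth labels)."""
    out: list[bool] = []
    buf: deque[bool] = deque(maxlen=window)
    for h in frame_hits:
        buf.append(bool(h))
        out.append(any(buf))
    return out
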