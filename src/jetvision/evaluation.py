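"""Scoring of algorithm output against manually classified ground truth.

Each compared instance is a true positive (both algorithm and truth say
hit), true negative (both say miss), false positive (algorithm hit, truth
miss) or false negative (algorithm miss, truth hit). Agreement is summarised
by the Dice coefficient

    Dice = 2*TP / (2*TP + FP + FN),

which is 1 for complete agreement, 0 when no event is correctly classified,
and deliberately ignores true negatives — long miss-only stretches should
not inflate the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError
from .frame_io import PipelineConfig
from .stream_classifier import windowed_or


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class RunSummary:
    """Distribution summary of per-run Dice values (box-plot statistics)."""

    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    n_runs: int


def confusion(pred: Sequence[bool], truth: Sequence[bool]) -> ConfusionCounts:
    """Tally the 2x2 confusion counts of two aligned boolean series."""
    if len(pred) != len(truth):
        raise AlignmentError(f"length mismatch: pred {len(pred)} vs truth {len(truth)}")
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    return ConfusionCounts(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def dice(counts: ConfusionCounts) -> float:
    """Dice coefficient 2TP/(2TP+FP+FN).

    The degenerate all-negative case (no positives in either series) is
    perfect agreement and returns 1.0, with a warning since the score then
    carries no information about hit detection.
    """
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        warnings.warn(
            "Dice undefined with no positives in prediction or truth; "
            "returning 1.0 (complete agreement)",
            stacklevel=2,
        )
        return 1.0
    return 2 * counts.tp / denom


def summarize_runs(run_dices: Sequence[float]) -> RunSummary:
    """Mean, sample sd, median, quartiles and range of per-run Dice values.

    Quartiles use linear interpolation between order statistics; the sample
    standard deviation uses the n-1 denominator (0.0 for a single run).
    """
    if len(run_dices) == 0:
        raise ValueError("need at least one run")
    d = np.asarray(run_dices, dtype=float)
    if d.min() < 0 or d.max() > 1:
        raise ValueError("Dice values must lie in [0, 1]")
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    return RunSummary(
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(d.min()),
        max=float(d.max()),
        n_runs=int(d.size),
    )


def score_sequence(
    pred_frame_hits: Sequence[bool],
    truth_frame_hits: Sequence[bool],
    cfg: PipelineConfig,
) -> dict:
    """Frame- and instance-level agreement for one run.

    Instance-level comparison applies the same trailing-OR window to both
    the algorithm's frame verdicts and the ground-truth labels, so both
    series live on the same (instance) timescale before the confusion counts
    are formed.
    """
    frame_counts = confusion(pred_frame_hits, truth_frame_hits)
    inst_pred = windowed_or(pred_frame_hits, cfg.sma_window)
    inst_truth = windowed_or(truth_frame_hits, cfg.sma_window)
    inst_counts = confusion(inst_pred, inst_truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frame_dice = dice(frame_counts)
        inst_dice = dice(inst_counts)
    return {
        "frame": frame_counts,
        "frame_dice": frame_dice,
        "instance": inst_counts,
        "instance_dice": inst_dice,
    }
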