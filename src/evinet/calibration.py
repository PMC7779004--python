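"""Gold-standard benchmarking and monotone score calibration.

Ranked interaction evidence (any raw score: an experiments-channel
functional score, a pooled text-mining probability, ...) is benchmarked
against a gold standard of curated complexes:

1. evidence supported only by genetic-interference assays is excluded as
   purely functional;
2. each remaining pair is labelled **TP** if the two proteins share a
   complex, **FP** if both are in the gold-standard universe but never
   co-complexed, and **unjudged** otherwise (absence of annotation is not
   evidence of absence of interaction);
3. judged pairs are weighted by the reciprocal geometric mean of their
   co-complex degrees, ``w = 1 / sqrt(deg_a * deg_b)``, so the
   quadratically many pairs of large complexes do not dominate;
4. a sliding window over the score-ranked judged pairs yields local
   weighted precision estimates, which are fitted monotonically
   (pool-adjacent-violators) and linearly interpolated.

The fitted curve maps any raw score to a physical-interaction probability
(the probability of co-occurring in a gold-standard complex) and can be
applied to score lists from other channels or organisms — calibration
transfer is just evaluating the curve on a new score list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .core import AssociationRecord, DataError, GoldStandard, co_complexed, gold_degree


@dataclass
class LabeledPair:
    """A benchmark pair: raw score, TP/FP/unjudged label, degree weight."""

    pair: Tuple[str, str]
    raw_score: float
    label: str  # "TP" | "FP" | "unjudged"
    weight: float = 1.0


def exclude_genetic_interference(edges: Iterable[AssociationRecord]) -> List[AssociationRecord]:
    """Drop records whose evidence comes only from genetic-interference assays.

    Records flagged ``physical_capable`` or ``unknown`` are kept.
    """
    return [rec for rec in edges if rec.assay_class != "genetic_interference_only"]


def label_and_weight(
    pairs: Iterable[Tuple[Tuple[str, str], float]], gold: GoldStandard
) -> List[LabeledPair]:
    """Label each (pair, raw_score) against the gold standard and weight it.

    Judged pairs get ``w = 1 / sqrt(deg_a * deg_b)`` on the co-complex
    graph; unjudged pairs keep weight 1 (they never enter precision sums).
    """
    out: List[LabeledPair] = []
    for (a, b), raw in pairs:
        in_a, in_b = a in gold, b in gold
        if in_a and in_b:
            label = "TP" if co_complexed(gold, a, b) else "FP"
            weight = 1.0 / math.sqrt(gold_degree(gold, a) * gold_degree(gold, b))
        else:
            label, weight = "unjudged", 1.0
        out.append(LabeledPair(pair=(a, b), raw_score=float(raw), label=label, weight=weight))
    return out


def default_window(n_judged: int) -> int:
    """Default sliding-window size: max(100, 1% of judged pairs)."""
    return max(100, n_judged // 100)


def weighted_precision(
    labeled: Sequence[LabeledPair], window: Optional[int] = None
) -> List[Tuple[float, float]]:
    """Local weighted precision along the score ranking.

    Judged pairs are sorted by raw score descending (ties broken by
    canonical pair order, so the ranking is deterministic); a sliding
    window of the given size moves one pair at a time and each position
    yields ``(median raw score in window, sum(w | TP) / sum(w))``.
    """
    judged = [lp for lp in labeled if lp.label in ("TP", "FP")]
    judged.sort(key=lambda lp: (-lp.raw_score, lp.pair))
    n = len(judged)
    if window is None:
        window = default_window(n)
    if window < 1:
        raise DataError(f"window must be >= 1, got {window}")
    if window > n:
        raise DataError(f"window {window} exceeds the {n} judged pairs")

    raw = np.array([lp.raw_score for lp in judged])
    w = np.array([lp.weight for lp in judged])
    w_tp = np.where(np.array([lp.label == "TP" for lp in judged]), w, 0.0)

    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwtp = np.concatenate([[0.0], np.cumsum(w_tp)])
    starts = np.arange(n - window + 1)
    tot = cw[starts + window] - cw[starts]
    tp = cwtp[starts + window] - cwtp[starts]
    # window slice of a descending-sorted array: its median is midpoint of
    # the two central elements
    lo = raw[starts + (window - 1) // 2]
    hi = raw[starts + window // 2]
    med = (lo + hi) / 2.0
    prec = tp / tot
    return list(zip(med.tolist(), prec.tolist()))


@dataclass
class CalibrationCurve:
    """Monotone map raw score -> physical-interaction probability.

    Anchor points are stored sorted by raw score with non-decreasing
    precision; evaluation is piecewise-linear between anchors and clamps to
    the boundary values outside their range.
    """

    anchors: List[Tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise DataError("a calibration curve needs >= 2 anchor points")
        self.anchors = sorted(self.anchors)
        ys = [y for _, y in self.anchors]
        if any(y2 < y1 - 1e-12 for y1, y2 in zip(ys, ys[1:])):
            raise DataError("calibration anchors must be non-decreasing")

    def __call__(self, raw_scores) -> np.ndarray:
        xs = np.array([x for x, _ in self.anchors])
        ys = np.array([y for _, y in self.anchors])
        return np.interp(np.asarray(raw_scores, dtype=float), xs, ys)


def fit_calibration(points: Sequence[Tuple[float, float]]) -> CalibrationCurve:
    """Fit a non-decreasing curve through (raw score, precision) points.

    Pool-adjacent-violators isotonic regression of precision on raw score;
    tied raw scores collapse to a single anchor so equal scores always
    calibrate identically.
    """
    if len(points) < 2:
        raise DataError("need >= 2 points to fit a calibration curve")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(x, y)
    anchors: dict = {}
    for xi, yi in zip(x.tolist(), fitted.tolist()):
        anchors[xi] = yi  # isotonic fit gives equal values for tied x
    items = sorted(anchors.items())
    if len(items) < 2:
        # all raw scores identical: a flat curve over a degenerate domain
        items = [(items[0][0], items[0][1]), (items[0][0] + 1e-9, items[0][1])]
    return CalibrationCurve(anchors=items)


def apply_calibration(curve: CalibrationCurve, raw_scores: Sequence[float]) -> List[float]:
    """Evaluate the curve elementwise; outputs are probabilities in [0, 1]."""
    return [float(v) for v in curve(raw_scores)]


def calibrate(
    pairs: Iterable[Tuple[Tuple[str, str], float]],
    gold: GoldStandard,
    window: Optional[int] = None,
) -> CalibrationCurve:
    """Full benchmark pipeline: label, weight, window precision, isotonic fit."""
    labeled = label_and_weight(pairs, gold)
    points = weighted_precision(labeled, window=window)
    return fit_calibration(points)
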