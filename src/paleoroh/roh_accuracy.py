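"""Overlap scoring of predicted vs truth ROH segments.

Two resolutions are supported: base-pair ("length-based") confusion with all
four cells, and segment-based confusion (TP/FP/FN only) under greedy
one-to-one any-overlap matching in coordinate order.  Derived metrics are
F1, MCC, normalised MCC ((MCC + 1) / 2), sensitivity, specificity and FDR;
ratios with empty denominators are reported as NaN, never silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .segments import Segment, check_disjoint, intersect_length, total_length


class RohAccuracyError(ValueError):
    pass


@dataclass
class LengthConfusion:
    """Base-pair confusion tallies partitioning the evaluated genome."""

    tp_bp: int
    fp_bp: int
    fn_bp: int
    tn_bp: int

    def __post_init__(self):
        if min(self.tp_bp, self.fp_bp, self.fn_bp, self.tn_bp) < 0:
            raise RohAccuracyError("negative base-pair tally")

    @property
    def genome_length(self) -> int:
        return self.tp_bp + self.fp_bp + self.fn_bp + self.tn_bp


@dataclass
class SegmentConfusion:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise RohAccuracyError("negative segment tally")


def length_confusion(pred, truth, genome_length: int) -> LengthConfusion:
    """Base-pair overlap confusion between two disjoint segment sets."""
    pred = check_disjoint(pred, "predicted segments")
    truth = check_disjoint(truth, "truth segments")
    pred_bp = total_length(pred)
    truth_bp = total_length(truth)
    if genome_length < max(pred_bp, truth_bp):
        raise RohAccuracyError("genome_length smaller than segment coverage")
    tp = intersect_length(pred, truth)
    fp = pred_bp - tp
    fn = truth_bp - tp
    tn = genome_length - tp - fp - fn
    return LengthConfusion(tp_bp=tp, fp_bp=fp, fn_bp=fn, tn_bp=tn)


def segment_confusion(pred, truth) -> SegmentConfusion:
    """Greedy one-to-one any-overlap matching in coordinate order."""
    pred = check_disjoint(pred, "predicted segments")
    truth = check_disjoint(truth, "truth segments")
    matched_truth: set[int] = set()
    tp = 0
    for p in pred:
        for k, t in enumerate(truth):
            if k in matched_truth:
                continue
            if p.overlaps(t):
                matched_truth.add(k)
                tp += 1
                break
    return SegmentConfusion(tp=tp, fp=len(pred) - tp, fn=len(truth) - tp)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def overlap_metrics(counts) -> dict:
    """F1, MCC, nMCC, sensitivity, specificity, FDR from confusion tallies.

    Accepts either confusion type; TN-dependent metrics (specificity, MCC,
    nMCC) are NaN for :class:`SegmentConfusion`.
    """
    if isinstance(counts, LengthConfusion):
        tp, fp, fn = counts.tp_bp, counts.fp_bp, counts.fn_bp
        tn: float | None = counts.tn_bp
    elif isinstance(counts, SegmentConfusion):
        tp, fp, fn = counts.tp, counts.fp, counts.fn
        tn = None
    else:
        raise RohAccuracyError(f"unsupported counts type {type(counts).__name__}")

    sensitivity = _safe_div(tp, tp + fn)
    precision = _safe_div(tp, tp + fp)
    fdr = _safe_div(fp, tp + fp)
    if math.isnan(precision) or math.isnan(sensitivity):
        f1 = math.nan
    elif precision + sensitivity == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)

    if tn is None:
        specificity = mcc = nmcc = math.nan
    else:
        specificity = _safe_div(tn, tn + fp)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            mcc = math.nan
        else:
            mcc = (tp * tn - fp * fn) / math.sqrt(denom)
        nmcc = (mcc + 1.0) / 2.0 if not math.isnan(mcc) else math.nan

    return {
        "f1": f1,
        "mcc": mcc,
        "nmcc": nmcc,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "fdr": fdr,
    }


def score_roh(pred, truth, genome_length: int) -> dict:
    """Both resolutions at once: ``{"length": {...}, "segment": {...}}``."""
    length = overlap_metrics(length_confusion(pred, truth, genome_length))
    segment = overlap_metrics(segment_confusion(pred, truth))
    return {"length": length, "segment": segment}
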