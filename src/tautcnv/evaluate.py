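"""Benchmark metrics: segment-overlap confusion counts, breakpoint accuracy,
copy-number value agreement.

A detected CNV segment is a true positive when it overlaps a benchmark CNV
segment of the same direction by at least ``min_frac`` of the *benchmark*
segment's length (80% by default).  Matching is one-to-one and greedy by
overlap size.  Specificity needs a notion of true negatives that segment
counts cannot provide, so TN/FP-for-specificity are counted at window level
(windows neutral in both truth and detection, and CNV-detected windows that
are truly neutral, respectively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .tracks import NEUTRAL, Segment
from .simulate import TruthSet


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float       # TP / (FN + TP); NaN when no truth segments
    fdr: float               # FP / (FP + TP); NaN when no calls
    specificity: float       # TN / (FP_windows + TN), window-level
    breakpoint_accuracy: Optional[float] = None
    matched_pairs: Optional[list[tuple[Segment, Segment]]] = None

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "sensitivity": self.sensitivity, "fdr": self.fdr,
                "specificity": self.specificity}


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def _cnv_segments(segments: Sequence[Segment],
                  length_range: Optional[tuple[int, int]] = None
                  ) -> list[Segment]:
    out = [s for s in segments if s.call != NEUTRAL]
    if length_range is not None:
        lo, hi = length_range
        out = [s for s in out if lo <= s.length <= hi]
    return out


def match_segments(detected: Sequence[Segment], truth_segs: Sequence[Segment],
                   min_frac: float = 0.8, reciprocal: bool = False
                   ) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detected to benchmark CNV segments.

    A pair qualifies when the calls agree and the overlap covers at least
    ``min_frac`` of the benchmark segment (of both segments if
    ``reciprocal``).  Pairs are taken largest-overlap first; ties go to the
    earlier truth then earlier detected segment.  Returns (truth index,
    detected index) pairs.
    """
    candidates = []
    for ti, t in enumerate(truth_segs):
        for di, d in enumerate(detected):
            if d.call != t.call:
                continue
            ov = t.overlap(d)
            need = min_frac * t.length
            if reciprocal:
                need = max(need, min_frac * d.length)
            if ov >= need and ov > 0:
                candidates.append((-ov, ti, di))
    candidates.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    pairs = []
    for _, ti, di in candidates:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        pairs.append((ti, di))
    return pairs


def _window_labels(segments: Sequence[Segment], n: int) -> np.ndarray:
    lab = np.zeros(n, dtype=np.int8)
    for s in segments:
        if s.call != NEUTRAL:
            lab[s.start_idx:s.end_idx + 1] = 1
    return lab


def segment_overlap_eval(detected: Sequence[Segment], truth: TruthSet,
                         min_frac: float = 0.8,
                         reciprocal: bool = False,
                         truth_length_range: Optional[tuple[int, int]] = None,
                         detected_length_range: Optional[tuple[int, int]] = None,
                         calls: Optional[Sequence[str]] = None) -> EvalResult:
    """Segment-based TP/FP/FN at the overlap threshold, plus window-level TN.

    ``truth_length_range`` / ``detected_length_range`` restrict the benchmark
    and detected CNV segments (inclusive window-length bounds) for
    length-stratified reporting; ``calls`` restricts to a subset of call
    directions.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    n = len(truth.f)
    for s in detected:
        if s.end_idx >= n:
            raise ValueError("detected segment outside the truth signal")
    det = _cnv_segments(detected, detected_length_range)
    tru = _cnv_segments(truth.segments, truth_length_range)
    if calls is not None:
        det = [s for s in det if s.call in calls]
        tru = [s for s in tru if s.call in calls]
    pairs = match_segments(det, tru, min_frac=min_frac, reciprocal=reciprocal)
    tp = len(pairs)
    fn = len(tru) - tp
    fp = len(det) - tp
    truth_lab = _window_labels(truth.segments, n)
    det_lab = _window_labels(detected, n)
    tn = int(np.sum((truth_lab == 0) & (det_lab == 0)))
    fp_windows = int(np.sum((truth_lab == 0) & (det_lab == 1)))
    return EvalResult(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_rate(tp, tp + fn),
        fdr=_rate(fp, fp + tp),
        specificity=_rate(tn, tn + fp_windows),
        matched_pairs=[(tru[ti], det[di]) for ti, di in pairs],
    )


def breakpoint_accuracy(detected: Sequence[Segment], truth: TruthSet) -> float:
    """Fraction of benchmark CNV segments with a detected CNV segment whose
    start and end indices both match exactly."""
    tru = _cnv_segments(truth.segments)
    if not tru:
        return math.nan
    det_keys = {(s.start_idx, s.end_idx, s.call)
                for s in _cnv_segments(detected)}
    hits = sum((t.start_idx, t.end_idx, t.call) in det_keys for t in tru)
    return hits / len(tru)


def value_agreement(detected: Sequence[Segment], truth: TruthSet,
                    tol_frac: float = 0.2, min_frac: float = 0.8
                    ) -> tuple[float, float]:
    """Copy-number value agreement over matched (TP) pairs.

    Returns (fraction of pairs with |detected - true| < tol_frac * |true|,
    mean relative difference); (NaN, NaN) when nothing matched.
    """
    res = segment_overlap_eval(detected, truth, min_frac=min_frac)
    if not res.matched_pairs:
        return math.nan, math.nan
    rel = np.array([abs(d.mean_value - t.mean_value) / abs(t.mean_value)
                    for t, d in res.matched_pairs])
    return float(np.mean(rel < tol_frac)), float(np.mean(rel))
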