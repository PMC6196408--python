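"""Circular binary segmentation (CBS) and threshold-based CNV calling.

CBS splits an interval at the arc that maximizes the circular two-sample
mean-shift statistic, accepts the split when its permutation p-value clears
``alpha``, and recurses into the resulting pieces.  The implementation is a
from-scratch reimplementation of the classical recipe (max-t arc search +
permutation reference distribution); see docs/methods.md for the exact
search strategy on long intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .tracks import (AMPLIFICATION, DELETION, NEUTRAL, RatioSignal, Segment)
from .tautstring import _values


@dataclass
class CBSParams:
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")
        if int(self.alpha * (self.n_perm + 1)) < 1:
            raise ValueError(
                "n_perm too small to resolve a p-value below alpha")


@dataclass
class CallParams:
    thr: float = 0.2

    def __post_init__(self) -> None:
        if not self.thr > 0:
            raise ValueError("thr must be > 0")


#: intervals up to this length get the exhaustive O(m^2) arc search
EXACT_LIMIT = 600


@njit(cache=True)
def _max_stat(x, widths, stop_at):  # pragma: no cover - numba kernel
    """Max over arcs (i, i+w], w in ``widths``, of
    |sum(arc) - w * mean| / sqrt(w * (m - w)).

    Returns (stat, i, w); aborts early once ``stop_at`` is reached (used by
    the permutation loop, where only exceedance matters).
    """
    m = x.shape[0]
    S = np.empty(m + 1)
    S[0] = 0.0
    for i in range(m):
        S[i + 1] = S[i] + x[i]
    mu = S[m] / m
    best = 0.0
    bi = -1
    bw = -1
    for wi in range(widths.shape[0]):
        w = widths[wi]
        denom = np.sqrt(w * (m - w))
        wmu = w * mu
        for i in range(m - w + 1):
            d = S[i + w] - S[i] - wmu
            if d < 0.0:
                d = -d
            st = d / denom
            if st > best:
                best = st
                bi = i
                bw = w
        if best >= stop_at:
            return best, bi, bw
    return best, bi, bw


@njit(cache=True)
def _perm_accept(x, widths, obs, n_perm, e_allow, seed):  # pragma: no cover
    """Permutation test: True when the split is accepted (p <= alpha).

    Stops as soon as the exceedance count makes p > alpha certain.
    """
    np.random.seed(seed)
    y = x.copy()
    exceed = 0
    thresh = obs * (1.0 - 1e-10)
    for _ in range(n_perm):
        np.random.shuffle(y)
        st, _, _ = _max_stat(y, widths, thresh)
        if st >= thresh:
            exceed += 1
            if exceed > e_allow:
                return False
    return True


def _grid_widths(m: int, min_width: int) -> np.ndarray:
    """Arc widths scanned on long intervals: every short width, a geometric
    ladder up to m/2, and the mirror m-w of each (the wrapped arcs), so the
    search is genuinely circular."""
    ws = set(range(min_width, min(16, m - min_width + 1)))
    g = 16.0
    while g <= m / 2:
        ws.add(int(g))
        g *= 1.4
    ws.add(m // 2)
    ws |= {m - w for w in list(ws)}
    ws = {w for w in ws if min_width <= w <= m - min_width}
    return np.array(sorted(ws), dtype=np.int64)


def _interval_seed(seed: int, lo: int, hi: int) -> int:
    return (seed * 1000003 + lo * 9176 + hi * 31 + 7) % (2 ** 31 - 1)


def _find_split(x: np.ndarray, params: CBSParams, lo: int, hi: int
                ) -> tuple[int, int] | None:
    """Best accepted split of x (one interval), or None.

    Returns arc bounds (i, j), 0-based half-open within the interval.
    """
    m = len(x)
    mw = params.min_width
    if m < 2 * mw:
        return None
    if m <= EXACT_LIMIT:
        widths = np.arange(mw, m - mw + 1, dtype=np.int64)
        exact = True
    else:
        widths = _grid_widths(m, mw)
        exact = False
    obs, bi, bw = _max_stat(x, widths, np.inf)
    if obs <= 0.0 or bi < 0:
        return None
    e_allow = int(params.alpha * (params.n_perm + 1)) - 1
    ok = _perm_accept(x, widths, obs, params.n_perm, e_allow,
                      _interval_seed(params.seed, lo, hi))
    if not ok:
        return None
    if not exact:
        # the grid quantizes the arc width; refine the changepoint pair
        # exhaustively in the gap around the best grid width (the accept
        # decision itself stays on the grid statistic, identically for
        # observed and permuted data)
        pos = int(np.searchsorted(widths, bw))
        wlo = int(widths[pos - 1]) + 1 if pos > 0 else mw
        whi = int(widths[pos + 1]) - 1 if pos + 1 < len(widths) else m - mw
        wlo = max(wlo, mw)
        whi = min(whi, m - mw)
        if wlo <= whi:
            fine = np.arange(wlo, whi + 1, dtype=np.int64)
            st2, i2, w2 = _max_stat(x, fine, np.inf)
            if st2 > obs:
                bi, bw = i2, w2
    return bi, bi + bw


def cbs_segment(signal, params: CBSParams | None = None) -> list[Segment]:
    """Recursive CBS; returns segments partitioning 0..n-1 with their means.

    Deterministic given ``params.seed`` (each interval's permutation stream
    is derived from the seed and the interval bounds).
    """
    if params is None:
        params = CBSParams()
    x = _values(signal)
    n = len(x)
    if n < 2:
        return [Segment(0, n - 1, float(x.mean()))] if n else []
    changepoints: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        split = _find_split(x[lo:hi], params, lo, hi)
        if split is None:
            continue
        i, j = split
        if i > 0:
            changepoints.append(lo + i)
            stack.append((lo, lo + i))
        if j < hi - lo:
            changepoints.append(lo + j)
            stack.append((lo + j, hi))
        stack.append((lo + i, lo + j))
    bounds = [0] + sorted(changepoints) + [n]
    return [Segment(a, b - 1, float(x[a:b].mean()))
            for a, b in zip(bounds[:-1], bounds[1:])]


def segments_from_piecewise(f_hat) -> list[Segment]:
    """One segment per maximal constant run of a piecewise-constant signal."""
    x = _values(f_hat)
    n = len(x)
    if n == 0:
        return []
    change = np.flatnonzero(x[1:] != x[:-1]) + 1
    bounds = np.concatenate(([0], change, [n]))
    return [Segment(int(a), int(b - 1), float(x[a]))
            for a, b in zip(bounds[:-1], bounds[1:])]


def merge_adjacent_calls(segments: Sequence[Segment],
                         values) -> list[Segment]:
    """Merge consecutive segments carrying the same call into maximal CNV
    regions, recomputing each region's mean over ``values``.

    CNV regions are maximal runs of windows on one side of the calling
    threshold; reporting them merged is what makes the segment-overlap
    evaluation meaningful when segmentation splits one long CNV into
    several pieces of almost equal level.
    """
    x = _values(values)
    out: list[Segment] = []
    for seg in segments:
        if out and out[-1].call == seg.call \
                and out[-1].end_idx + 1 == seg.start_idx:
            prev = out[-1]
            out[-1] = Segment(prev.start_idx, seg.end_idx,
                              float(x[prev.start_idx:seg.end_idx + 1].mean()),
                              seg.call)
        else:
            out.append(seg)
    return out


def call_segments(segments: Sequence[Segment],
                  params: CallParams | None = None) -> list[Segment]:
    """Label each segment by its mean log2 ratio: amplification above +thr,
    deletion below -thr, neutral in between (strict inequalities)."""
    if params is None:
        params = CallParams()
    out = []
    for seg in segments:
        if seg.mean_value > params.thr:
            call = AMPLIFICATION
        elif seg.mean_value < -params.thr:
            call = DELETION
        else:
            call = NEUTRAL
        out.append(Segment(seg.start_idx, seg.end_idx, seg.mean_value, call))
    return out
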