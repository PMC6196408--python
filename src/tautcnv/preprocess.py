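"""Readcount preprocessing: outlier filtering, GC-bias correction, log2 ratio.

The preprocessing chain mirrors standard read-depth practice: windows whose
count (or GC content) falls in the extreme percentile tails are dropped, the
unimodal dependence of coverage on GC content is flattened with a weighted
local regression on per-GC-bin mean counts, and the sample is put in ratio to
a matched normal so that residual position-specific biases (mappability in
particular) cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .tracks import RatioSignal, WindowTrack


@dataclass
class FilterReport:
    """Bookkeeping for percentile outlier filtering.

    A window may trip several criteria; each tally counts it once per
    criterion, while ``kept_mask`` is the conjunction of all criteria.
    """

    kept_mask: np.ndarray
    n_removed_count_low: int = 0
    n_removed_count_high: int = 0
    n_removed_gc_low: int = 0
    n_removed_gc_high: int = 0

    @property
    def n_removed(self) -> int:
        return int((~self.kept_mask).sum())


@dataclass
class GCBiasCurve:
    """Mean readcount per integer GC percent, raw and Loess-smoothed."""

    gc_level: np.ndarray       # populated integer-percent bins, ascending
    m_gc: np.ndarray           # mean count per bin
    m_gc_smooth: np.ndarray    # weighted-Loess smoothed means
    n_windows: np.ndarray      # occupancy per bin (the Loess weights)
    global_center: float       # median count over all usable windows

    def smooth_at(self, gc_pct: np.ndarray) -> np.ndarray:
        """Smoothed mean count at the given integer GC percents.

        Bins between populated levels are linearly interpolated; outside the
        populated range the nearest endpoint value is used.
        """
        return np.interp(np.asarray(gc_pct, dtype=float),
                         self.gc_level.astype(float), self.m_gc_smooth)


def gc_bin(gc: np.ndarray) -> np.ndarray:
    """Integer GC percent of a GC fraction (nearest percent)."""
    return np.rint(np.asarray(gc, dtype=float) * 100.0).astype(np.int64)


def filter_outliers(track: WindowTrack, pct: float = 1.0
                    ) -> tuple[WindowTrack, FilterReport]:
    """Drop windows in the extreme ``pct`` percentile tails.

    Cutoffs are linear-interpolation percentiles of the count (and, when
    present, GC) distribution; a window is removed when its value is strictly
    below the lower or strictly above the upper cutoff, so fully tied data
    removes nothing.
    """
    if len(track) == 0:
        raise ValueError("cannot filter an empty track")
    if not 0 <= pct < 50:
        raise ValueError("pct must be in [0, 50)")
    kept = np.ones(len(track), dtype=bool)
    report = FilterReport(kept_mask=kept)
    if pct > 0:
        lo, hi = np.percentile(track.count, [pct, 100.0 - pct])
        low = track.count < lo
        high = track.count > hi
        report.n_removed_count_low = int(low.sum())
        report.n_removed_count_high = int(high.sum())
        kept &= ~(low | high)
        if track.gc is not None:
            glo, ghi = np.percentile(track.gc, [pct, 100.0 - pct])
            low = track.gc < glo
            high = track.gc > ghi
            report.n_removed_gc_low = int(low.sum())
            report.n_removed_gc_high = int(high.sum())
            kept &= ~(low | high)
    report.kept_mask = kept
    if not kept.any():
        raise ValueError("filtering removed every window")
    return track.subset(kept), report


def _weighted_loess(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                    span: float = 0.3, degree: int = 2) -> np.ndarray:
    """Weighted local polynomial regression with tricube kernel.

    Fits, at each x[i], a degree-``degree`` polynomial to the nearest
    ``ceil(span * len(x))`` points with weights tricube(distance) * w.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    m = len(x)
    k = max(degree + 1, int(np.ceil(span * m)))
    k = min(k, m)
    out = np.empty(m)
    for i in range(m):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = np.average(y[idx], weights=w[idx])
            continue
        tri = (1.0 - (d[idx] / dmax) ** 3) ** 3
        tri = np.clip(tri, 0.0, None)
        ww = tri * w[idx]
        if ww.sum() <= 0:
            ww = w[idx]
        deg = min(degree, len(idx) - 1)
        # weighted least squares on centred x for conditioning
        X = np.vander(x[idx] - x[i], deg + 1, increasing=True)
        sw = np.sqrt(ww)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = coef[0]
    return out


def fit_gc_bias(track: WindowTrack, span: float = 0.3) -> GCBiasCurve:
    """Estimate the GC-bias curve: per-GC-bin mean counts, Loess-smoothed.

    Windows are binned at integer GC percent; the weighted Loess (weights
    proportional to bin occupancy) tames bins populated by few windows, whose
    raw means are unstable.
    """
    if track.gc is None:
        raise ValueError("track has no GC column; cannot fit GC bias")
    bins = gc_bin(track.gc)
    levels, inverse, counts_per = np.unique(bins, return_inverse=True,
                                            return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 populated GC bins")
    sums = np.bincount(inverse, weights=track.count)
    m_gc = sums / counts_per
    m_smooth = _weighted_loess(levels.astype(float), m_gc,
                               counts_per.astype(float), span=span)
    m_smooth = np.clip(m_smooth, 0.0, None)
    return GCBiasCurve(
        gc_level=levels,
        m_gc=m_gc,
        m_gc_smooth=m_smooth,
        n_windows=counts_per,
        global_center=float(np.median(track.count)),
    )


def correct_gc_bias(track: WindowTrack, curve: GCBiasCurve) -> WindowTrack:
    """Rescale counts so the expected count no longer depends on GC.

    corrected_i = count_i * global_center / m_gc_smooth(gc_i).
    """
    if track.gc is None:
        raise ValueError("track has no GC column; cannot correct GC bias")
    smooth = curve.smooth_at(gc_bin(track.gc))
    if np.any(smooth <= 0):
        bad = gc_bin(track.gc)[smooth <= 0]
        raise ValueError(
            f"smoothed GC curve non-positive at bin(s) {sorted(set(bad))}")
    return track.with_count(track.count * curve.global_center / smooth)


def intersect_tracks(sample: WindowTrack, normal: WindowTrack
                     ) -> tuple[WindowTrack, WindowTrack, np.ndarray, np.ndarray]:
    """Restrict both tracks to their common (chrom, start) windows.

    Returns the restricted tracks plus the index of each kept window in the
    original sample and normal tracks.
    """
    skey = [(sample.chrom[i], int(sample.start[i])) for i in range(len(sample))]
    nkey = {(normal.chrom[i], int(normal.start[i])): i
            for i in range(len(normal))}
    sidx, nidx = [], []
    for i, k in enumerate(skey):
        j = nkey.get(k)
        if j is not None:
            sidx.append(i)
            nidx.append(j)
    sidx = np.asarray(sidx, dtype=np.int64)
    nidx = np.asarray(nidx, dtype=np.int64)
    if len(sidx) == 0:
        raise ValueError("sample and normal tracks share no windows")
    return sample.subset(sidx), normal.subset(nidx), sidx, nidx


def log2_ratio(sample: WindowTrack, normal: WindowTrack,
               pseudocount: float = 0.5,
               median_center: bool = True) -> RatioSignal:
    """log2 sample/normal readcount ratio on the common window set.

    Both tracks are first scaled to the mean of the two library sizes so the
    ratio reflects relative copy number rather than sequencing depth; the
    pseudocount keeps zero-count windows finite.  With ``median_center`` the
    signal median is subtracted so copy-neutral regions sit at 0, which the
    symmetric ±thr calling rule assumes.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    s_track, n_track, sidx, _ = intersect_tracks(sample, normal)
    S = s_track.count.sum()
    N = n_track.count.sum()
    if S <= 0 or N <= 0:
        raise ValueError("track has zero total count on the intersection")
    M = 0.5 * (S + N)
    s = s_track.count * (M / S) + pseudocount
    nrm = n_track.count * (M / N) + pseudocount
    if np.any(s <= 0) or np.any(nrm <= 0):
        raise ValueError("zero counts require a positive pseudocount")
    r = np.log2(s / nrm)
    if median_center:
        r = r - np.median(r)
    return RatioSignal(values=r, window_index=sidx, track=sample)
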