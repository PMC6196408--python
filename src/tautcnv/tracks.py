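"""Windowed readcount tracks, log2-ratio signals and segment calls.

Coordinates follow the BED convention: 0-based, half-open.  A track holds
fixed-width, non-overlapping windows sorted by (chrom, start); the log2-ratio
signal is a plain 1-D vector with an index mapping back into the track it was
derived from, so that calls made on the signal can be written out in genomic
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

AMPLIFICATION = "amplification"
DELETION = "deletion"
NEUTRAL = "neutral"
CALLS = (AMPLIFICATION, DELETION, NEUTRAL)


class TrackValidationError(ValueError):
    """Raised when a window track violates its structural invariants."""


class TrackParseError(ValueError):
    """Raised when a track file cannot be parsed; names the offending line."""


@dataclass
class WindowTrack:
    """Per-window readcounts, optionally with per-window GC fraction.

    ``count`` is float-valued because GC correction rescales counts; raw
    input counts are integers.
    """

    chrom: np.ndarray          # object array of chromosome labels
    start: np.ndarray          # int64, 0-based inclusive
    end: np.ndarray            # int64, exclusive
    count: np.ndarray          # float64, >= 0
    gc: Optional[np.ndarray] = None   # float64 in [0, 1], or None
    window_width: Optional[int] = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.float64)
        if self.gc is not None:
            self.gc = np.asarray(self.gc, dtype=np.float64)
        if self.window_width is None and len(self.start) > 0:
            self.window_width = int(self.end[0] - self.start[0])
        self.validate()

    def __len__(self) -> int:
        return len(self.start)

    @property
    def has_gc(self) -> bool:
        return self.gc is not None

    def validate(self) -> None:
        n = len(self.start)
        for name, arr in (("chrom", self.chrom), ("end", self.end),
                          ("count", self.count)):
            if len(arr) != n:
                raise TrackValidationError(f"column {name!r} length mismatch")
        if self.gc is not None and len(self.gc) != n:
            raise TrackValidationError("gc column length mismatch")
        if n == 0:
            return
        widths = self.end - self.start
        if self.window_width is not None and np.any(widths != self.window_width):
            bad = int(np.argmax(widths != self.window_width))
            raise TrackValidationError(
                f"window {bad} has width {widths[bad]}, expected "
                f"{self.window_width}")
        if np.any(self.count < 0):
            raise TrackValidationError("negative readcount")
        if self.gc is not None and (np.any(self.gc < 0) or np.any(self.gc > 1)):
            raise TrackValidationError("gc fraction outside [0, 1]")
        # sortedness and non-overlap within chromosome; chromosomes must be
        # contiguous blocks
        seen = set()
        prev_chrom = None
        for i in range(n):
            c = self.chrom[i]
            if c != prev_chrom:
                if c in seen:
                    raise TrackValidationError(
                        f"chromosome {c!r} appears in non-contiguous blocks")
                seen.add(c)
                prev_chrom = c
            elif self.start[i] < self.end[i - 1]:
                raise TrackValidationError(
                    f"windows {i - 1} and {i} on {c!r} overlap or are "
                    "unsorted")

    def subset(self, mask_or_index: np.ndarray) -> "WindowTrack":
        idx = np.asarray(mask_or_index)
        return WindowTrack(
            chrom=self.chrom[idx],
            start=self.start[idx],
            end=self.end[idx],
            count=self.count[idx],
            gc=None if self.gc is None else self.gc[idx],
            window_width=self.window_width,
        )

    def with_count(self, count: np.ndarray) -> "WindowTrack":
        return replace(self, count=np.asarray(count, dtype=np.float64))

    def by_chromosome(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (chrom, index array) per chromosome, in track order."""
        if len(self) == 0:
            return
        chroms = self.chrom
        boundaries = [0]
        for i in range(1, len(self)):
            if chroms[i] != chroms[i - 1]:
                boundaries.append(i)
        boundaries.append(len(self))
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            yield chroms[a], np.arange(a, b)

    def to_frame(self) -> pd.DataFrame:
        data = {"chrom": self.chrom, "start": self.start, "end": self.end,
                "count": self.count}
        if self.gc is not None:
            data["gc"] = self.gc
        return pd.DataFrame(data)


@dataclass
class RatioSignal:
    """A 1-D log2-ratio signal r modeled as r = f + noise.

    ``window_index`` maps each position back to a window of the track the
    signal was computed from; synthetic signals use the identity mapping.
    """

    values: np.ndarray
    window_index: Optional[np.ndarray] = None
    track: Optional[WindowTrack] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratio signal contains non-finite values")
        if self.window_index is None:
            self.window_index = np.arange(len(self.values), dtype=np.int64)
        else:
            self.window_index = np.asarray(self.window_index, dtype=np.int64)
            if len(self.window_index) != len(self.values):
                raise ValueError("window_index length mismatch")
            if np.any(np.diff(self.window_index) <= 0):
                raise ValueError("window_index must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Segment:
    """A constant-copy-number interval on signal indices (inclusive bounds)."""

    start_idx: int
    end_idx: int
    mean_value: float
    call: str = NEUTRAL

    def __post_init__(self) -> None:
        if self.start_idx > self.end_idx:
            raise ValueError("start_idx > end_idx")
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")

    @property
    def length(self) -> int:
        return self.end_idx - self.start_idx + 1

    def overlap(self, other: "Segment") -> int:
        return max(0, min(self.end_idx, other.end_idx)
                   - max(self.start_idx, other.start_idx) + 1)


def validate_partition(segments: Sequence[Segment], n: int) -> None:
    """Check that segments partition 0..n-1 without gaps or overlap."""
    if len(segments) == 0:
        if n != 0:
            raise ValueError("empty segmentation of non-empty signal")
        return
    pos = 0
    for seg in segments:
        if seg.start_idx != pos:
            raise ValueError(f"segmentation gap/overlap at index {pos}")
        pos = seg.end_idx + 1
    if pos != n:
        raise ValueError("segmentation does not cover the signal")


def read_window_track(path, dialect: str = "bedgraph",
                      window_width: Optional[int] = None) -> WindowTrack:
    """Read a windowed readcount track.

    ``dialect`` is ``"bedgraph"`` (chrom, start, end, count) or ``"bed4+gc"``
    (chrom, start, end, count, gc fraction).  Tab-separated, ``#`` comments
    and a ``track`` line are skipped.
    """
    if dialect not in ("bedgraph", "bed4+gc"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = 4 if dialect == "bedgraph" else 5
    chroms, starts, ends, counts, gcs = [], [], [], [], []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise TrackParseError(
                    f"{path}: line {lineno}: expected {ncols} columns, "
                    f"got {len(fields)}")
            try:
                starts.append(int(fields[1]))
                ends.append(int(fields[2]))
                counts.append(float(fields[3]))
                if ncols == 5:
                    gcs.append(float(fields[4]))
            except ValueError as exc:
                raise TrackParseError(
                    f"{path}: line {lineno}: {exc}") from None
            chroms.append(fields[0])
    try:
        return WindowTrack(
            chrom=np.array(chroms, dtype=object),
            start=np.array(starts, dtype=np.int64),
            end=np.array(ends, dtype=np.int64),
            count=np.array(counts, dtype=np.float64),
            gc=np.array(gcs, dtype=np.float64) if gcs else None,
            window_width=window_width,
        )
    except TrackValidationError as exc:
        raise TrackValidationError(f"{path}: {exc}") from None


def write_window_track(track: WindowTrack, path) -> None:
    """Write a track in the dialect implied by its columns (inverse of
    :func:`read_window_track`)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for i in range(len(track)):
            fields = [str(track.chrom[i]), str(int(track.start[i])),
                      str(int(track.end[i])), repr(float(track.count[i]))]
            if track.gc is not None:
                fields.append(repr(float(track.gc[i])))
            fh.write("\t".join(fields) + "\n")


def write_segments(segments: Sequence[Segment], track: WindowTrack, path,
                   window_index: Optional[np.ndarray] = None) -> None:
    """Write segment calls as BED5: chrom, start, end, mean log2 ratio, call.

    ``window_index`` maps signal indices to track windows when the signal was
    built from a filtered track; identity when omitted.  Each segment must lie
    within a single chromosome.
    """
    if window_index is None:
        window_index = np.arange(len(track), dtype=np.int64)
    with open(path, "wt", encoding="utf-8") as fh:
        for seg in segments:
            if seg.start_idx < 0 or seg.end_idx >= len(window_index):
                raise IndexError(
                    f"segment [{seg.start_idx}, {seg.end_idx}] outside track")
            wa = int(window_index[seg.start_idx])
            wb = int(window_index[seg.end_idx])
            ca, cb = track.chrom[wa], track.chrom[wb]
            if ca != cb:
                raise ValueError(
                    f"segment [{seg.start_idx}, {seg.end_idx}] spans "
                    f"chromosomes {ca!r} and {cb!r}")
            fh.write(f"{ca}\t{int(track.start[wa])}\t{int(track.end[wb])}\t"
                     f"{repr(float(seg.mean_value))}\t{seg.call}\n")


def read_segments(path, track: WindowTrack) -> list[Segment]:
    """Read BED5 segment calls back to signal indices on ``track``.

    Inverse of :func:`write_segments` for unfiltered tracks (identity
    window_index).
    """
    key = {(track.chrom[i], int(track.start[i])): i for i in range(len(track))}
    end_key = {(track.chrom[i], int(track.end[i])): i for i in range(len(track))}
    segments = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise TrackParseError(
                    f"{path}: line {lineno}: expected 5 columns")
            chrom, start, end, mean, call = fields[:5]
            try:
                a = key[(chrom, int(start))]
                b = end_key[(chrom, int(end))]
            except KeyError:
                raise TrackParseError(
                    f"{path}: line {lineno}: coordinates not aligned to "
                    "track windows") from None
            segments.append(Segment(a, b, float(mean), call))
    return segments
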