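"""Synthetic CNV data: log2-ratio signals and paired readcount tracks.

The ratio-signal generator produces the benchmark design used throughout the
test battery: piecewise-constant truth over a zero (copy-neutral) baseline
with CNV segments of log-uniform length, unit log2 amplitude of either sign,
plus i.i.d. Gaussian noise whose standard deviation sweeps the grid
sigma_N = 0.47 .. 0.05 (SNR spans roughly 4.5-400 at unit amplitude, with
SNR defined as the mean-square CNV amplitude over sigma_N^2).

The paired-track generator adds the earlier pipeline stages: Poisson counts
at a controlled mean depth, a unimodal GC-bias curve distorting both sample
and normal, and the CNV truth scaling only the sample — enough structure to
exercise filtering, GC correction and the ratio end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

from .tracks import AMPLIFICATION, DELETION, RatioSignal, Segment, WindowTrack

#: the benchmark noise grid, highest noise first
SIGMA_GRID = tuple(np.round(np.linspace(0.47, 0.05, 10), 4))

#: benchmark geometry (see docs/methods.md)
BENCH_N = 35_000
BENCH_N_CNV = 10
BENCH_MAX_LEN = 10_000
BENCH_MAX_COVERAGE = 0.30
BENCH_REPLICATES = 50


@dataclass
class SimConfig:
    """Configuration of one simulated ratio signal.

    Exactly one of ``sigma_N`` / ``snr`` must be given; with ``snr`` the
    noise scale is sigma_N = sqrt(P_signal / snr) with P_signal the mean
    square of the truth over CNV windows.
    """

    n: int
    cnv_segments: Sequence[tuple[int, int, float]] = field(default_factory=list)
    sigma_N: Optional[float] = None
    snr: Optional[float] = None
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if (self.sigma_N is None) == (self.snr is None):
            raise ValueError("give exactly one of sigma_N or snr")
        if self.sigma_N is not None and self.sigma_N < 0:
            raise ValueError("sigma_N must be >= 0")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be > 0")
        occupied = np.zeros(self.n, dtype=bool)
        for start, length, amp in self.cnv_segments:
            if length < 1 or start < 0 or start + length > self.n:
                raise ValueError(
                    f"CNV ({start}, {length}) outside signal bounds")
            if amp == 0:
                raise ValueError("CNV amplitude must be nonzero")
            if occupied[start:start + length].any():
                raise ValueError(f"CNV at {start} overlaps another segment")
            occupied[start:start + length] = True


@dataclass
class TruthSet:
    """Ground-truth CNV segments and the per-window noiseless signal f."""

    segments: list[Segment]
    f: np.ndarray

    @classmethod
    def from_cnvs(cls, n: int,
                  cnvs: Sequence[tuple[int, int, float]]) -> "TruthSet":
        f = np.zeros(n)
        segments = []
        for start, length, amp in sorted(cnvs):
            f[start:start + length] = amp
            call = AMPLIFICATION if amp > 0 else DELETION
            segments.append(Segment(start, start + length - 1, float(amp),
                                    call))
        return cls(segments=segments, f=f)

    @property
    def coverage(self) -> float:
        return float(np.mean(self.f != 0.0))


def signal_power(f: np.ndarray) -> float:
    """Mean square of the truth over CNV (non-zero) windows; 0 if none."""
    nz = f[f != 0.0]
    return float(np.mean(nz ** 2)) if len(nz) else 0.0


def simulate_ratio_signal(config: SimConfig) -> tuple[TruthSet, RatioSignal]:
    """Truth plus noisy observation r = f + N(0, sigma_N^2)."""
    truth = TruthSet.from_cnvs(config.n, config.cnv_segments)
    if config.sigma_N is not None:
        sigma = config.sigma_N
    else:
        p = signal_power(truth.f)
        if p == 0:
            raise ValueError("snr specification requires at least one CNV")
        sigma = float(np.sqrt(p / config.snr))
    rng = np.random.default_rng(config.seed)
    r = truth.f + rng.normal(0.0, sigma, config.n)
    return truth, RatioSignal(values=r)


def random_truth(n: int, n_cnv: int, rng: np.random.Generator,
                 max_len: int = BENCH_MAX_LEN,
                 max_coverage: float = BENCH_MAX_COVERAGE) -> TruthSet:
    """Random CNV layout: log-uniform lengths in [1, max_len], amplitudes
    ±1, placed uniformly with at least one neutral window between CNVs and
    total coverage capped at ``max_coverage``."""
    occupied = np.zeros(n, dtype=bool)
    cnvs: list[tuple[int, int, float]] = []
    covered = 0
    for _ in range(n_cnv):
        length = int(np.rint(np.exp(rng.uniform(0.0, np.log(max_len)))))
        length = max(1, min(length, max_len))
        if covered + length > max_coverage * n:
            continue
        placed = False
        for _attempt in range(200):
            start = int(rng.integers(0, n - length + 1))
            a = max(0, start - 1)
            b = min(n, start + length + 1)
            if not occupied[a:b].any():
                placed = True
                break
        if not placed:
            continue
        amp = 1.0 if rng.random() < 0.5 else -1.0
        occupied[start:start + length] = True
        covered += length
        cnvs.append((start, length, amp))
    return TruthSet.from_cnvs(n, cnvs)


def default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Unimodal coverage-vs-GC response peaking at 45% GC (max 1)."""
    return 0.05 + 0.95 * np.exp(-((gc * 100.0 - 45.0) ** 2) / (2.0 * 15.0 ** 2))


def simulate_paired_tracks(config: SimConfig,
                           gc_bias: Callable[[np.ndarray], np.ndarray] | None = None,
                           mean_depth: float = 100.0,
                           window_width: int = 100,
                           chrom: str = "chr1"
                           ) -> tuple[WindowTrack, WindowTrack, TruthSet]:
    """Paired sample/normal Poisson count tracks with injected GC bias.

    Per-window GC ~ Beta(9, 11) (mean 0.45); normal counts are
    Poisson(depth * b(gc)); sample counts Poisson(depth * b(gc) * 2^f) so
    the CNV truth scales the sample only.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if gc_bias is None:
        gc_bias = default_gc_bias
    truth = TruthSet.from_cnvs(config.n, config.cnv_segments)
    rng = np.random.default_rng(config.seed)
    gc = rng.beta(9.0, 11.0, config.n)
    b = np.asarray(gc_bias(gc), dtype=float)
    if np.any(b <= 0):
        raise ValueError("gc_bias curve must be positive")
    base = mean_depth * b
    normal_counts = rng.poisson(base).astype(float)
    sample_counts = rng.poisson(base * np.exp2(truth.f)).astype(float)
    start = np.arange(config.n, dtype=np.int64) * window_width
    end = start + window_width
    chroms = np.full(config.n, chrom, dtype=object)
    sample = WindowTrack(chrom=chroms, start=start, end=end,
                         count=sample_counts, gc=gc,
                         window_width=window_width)
    normal = WindowTrack(chrom=chroms.copy(), start=start.copy(),
                         end=end.copy(), count=normal_counts, gc=gc.copy(),
                         window_width=window_width)
    return sample, normal, truth


@dataclass
class BenchmarkCase:
    """One (noise level, replicate) cell of the benchmark suite."""

    sigma: float
    replicate: int
    truth: TruthSet
    signal: RatioSignal


def paper_benchmark_suite(seed: int,
                          n_replicates: int = BENCH_REPLICATES,
                          sigma_grid: Sequence[float] = SIGMA_GRID,
                          n: int = BENCH_N,
                          n_cnv: int = BENCH_N_CNV
                          ) -> Iterator[BenchmarkCase]:
    """The benchmark battery: ``n_replicates`` truth layouts, each observed
    at every noise level of ``sigma_grid``.

    Truth layouts follow :func:`random_truth` (lengths 1..10^4 windows,
    ±1 amplitudes, coverage <= 30%).  Fully deterministic given ``seed``;
    yielded lazily, noise level varying fastest.
    """
    for rep in range(n_replicates):
        truth_rng = np.random.default_rng([seed % (2 ** 31), 1, rep])
        truth = random_truth(n, n_cnv, truth_rng)
        for li, sigma in enumerate(sigma_grid):
            noise_rng = np.random.default_rng([seed % (2 ** 31), 2, rep, li])
            r = truth.f + noise_rng.normal(0.0, sigma, n)
            yield BenchmarkCase(sigma=float(sigma), replicate=rep,
                                truth=truth, signal=RatioSignal(values=r))
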