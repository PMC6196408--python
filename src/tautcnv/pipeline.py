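"""End-to-end CNV detection: filter -> GC-correct -> ratio -> denoise ->
segment -> call, with every stage parameterized by one config object.

Stage order is fixed; the denoising stage is skipped with ``method="none"``.
Each stage logs its parameters and record counts so a run can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import preprocess, tracks
from .baselines import BaselineParams, dwt_denoise, moving_average
from .segmentation import (CBSParams, CallParams, call_segments,
                           cbs_segment, merge_adjacent_calls)
from .tautstring import TautStringParams, denoise
from .tracks import RatioSignal, Segment, WindowTrack

log = logging.getLogger("tautcnv")

METHODS = ("tautstring", "dwt", "ma", "none")


@dataclass
class PipelineConfig:
    """All knobs of the detection chain (see module docs for stage order)."""

    window_width: int = 100
    filter_pct: float = 1.0
    loess_span: float = 0.3
    pseudocount: float = 0.5
    median_center: bool = True
    method: str = "tautstring"
    gamma: float = 0.5
    c: float = 0.25
    use_multiresolution: bool = True
    ma_window: int = 9
    wavelet_name: str = "haar"
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 2
    thr: float = 0.2
    min_overlap: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        # fail fast on method-specific parameters before any stage runs
        self.tautstring_params()
        self.baseline_params()
        self.cbs_params()
        self.call_params()

    def tautstring_params(self) -> TautStringParams:
        return TautStringParams(c=self.c, gamma=self.gamma,
                                use_multiresolution=self.use_multiresolution)

    def baseline_params(self) -> BaselineParams:
        return BaselineParams(ma_window=self.ma_window,
                              wavelet_name=self.wavelet_name)

    def cbs_params(self, seed: int | None = None) -> CBSParams:
        return CBSParams(alpha=self.alpha, n_perm=self.n_perm,
                         min_width=self.min_width,
                         seed=self.seed if seed is None else seed)

    def call_params(self) -> CallParams:
        return CallParams(thr=self.thr)


def denoise_values(values: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Apply the configured denoiser to a raw 1-D log2-ratio vector."""
    if config.method == "tautstring":
        return denoise(values, config.tautstring_params()).f_hat
    if config.method == "dwt":
        return dwt_denoise(values, config.baseline_params())
    if config.method == "ma":
        return moving_average(values, config.ma_window)
    return np.asarray(values, dtype=float)


def call_cnvs(signal, config: PipelineConfig,
              cbs_seed: int | None = None) -> list[Segment]:
    """Denoise, CBS-segment and threshold-call one ratio signal.

    Copy-number values are means of the *denoised* signal over the CBS
    segments; adjacent segments receiving the same call are merged into
    maximal CNV regions (the reported unit of detection).
    """
    values = signal.values if isinstance(signal, RatioSignal) else np.asarray(
        signal, dtype=float)
    smooth = denoise_values(values, config)
    log.info("denoise method=%s n=%d", config.method, len(values))
    segments = cbs_segment(smooth, config.cbs_params(cbs_seed))
    called = call_segments(segments, config.call_params())
    called = merge_adjacent_calls(called, smooth)
    log.info("segment n_segments=%d alpha=%g n_perm=%d thr=%g",
             len(called), config.alpha, config.n_perm, config.thr)
    return called


def preprocess_tracks(sample: WindowTrack, normal: WindowTrack,
                      config: PipelineConfig) -> RatioSignal:
    """Filter, GC-correct (when GC is available) and ratio a track pair."""
    sample_f, rep_s = preprocess.filter_outliers(sample, config.filter_pct)
    normal_f, rep_n = preprocess.filter_outliers(normal, config.filter_pct)
    log.info("filter pct=%g removed sample=%d normal=%d", config.filter_pct,
             rep_s.n_removed, rep_n.n_removed)
    if sample_f.has_gc and normal_f.has_gc:
        curve_s = preprocess.fit_gc_bias(sample_f, span=config.loess_span)
        curve_n = preprocess.fit_gc_bias(normal_f, span=config.loess_span)
        sample_f = preprocess.correct_gc_bias(sample_f, curve_s)
        normal_f = preprocess.correct_gc_bias(normal_f, curve_n)
        log.info("gc-correct span=%g centers sample=%g normal=%g",
                 config.loess_span, curve_s.global_center,
                 curve_n.global_center)
    signal = preprocess.log2_ratio(sample_f, normal_f,
                                   pseudocount=config.pseudocount,
                                   median_center=config.median_center)
    log.info("ratio n_windows=%d", signal.n)
    return signal


def run_pipeline(sample: WindowTrack, normal: WindowTrack,
                 config: PipelineConfig) -> tuple[list[Segment], RatioSignal]:
    """Full chain on an in-memory track pair.

    The signal is processed per chromosome (CNVs cannot cross chromosome
    boundaries) and the segment lists are concatenated on the global signal
    index.  Returns (called segments, the preprocessed ratio signal);
    segment indices refer to signal positions, ``signal.window_index`` maps
    them into ``signal.track`` (the filtered sample track), whose
    start/end columns carry the genomic coordinates.
    """
    signal = preprocess_tracks(sample, normal, config)
    assert signal.track is not None
    chrom_of = signal.track.chrom[signal.window_index]
    segments: list[Segment] = []
    offset = 0
    n = signal.n
    while offset < n:
        end = offset
        while end < n and chrom_of[end] == chrom_of[offset]:
            end += 1
        sub = signal.values[offset:end]
        called = call_cnvs(sub, config, cbs_seed=config.seed + offset)
        segments.extend(Segment(s.start_idx + offset, s.end_idx + offset,
                                s.mean_value, s.call) for s in called)
        offset = end
    return segments, signal


def run_pipeline_files(sample_path, normal_path, out_calls,
                       config: PipelineConfig,
                       dialect: str = "bed4+gc") -> list[Segment]:
    """File-to-file variant of :func:`run_pipeline` (BED in, BED5 out)."""
    sample = tracks.read_window_track(sample_path, dialect=dialect,
                                      window_width=config.window_width)
    normal = tracks.read_window_track(normal_path, dialect=dialect,
                                      window_width=config.window_width)
    segments, signal = run_pipeline(sample, normal, config)
    tracks.write_segments(segments, signal.track, out_calls,
                          window_index=signal.window_index)
    log.info("wrote %d segments to %s", len(segments), out_calls)
    return segments
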