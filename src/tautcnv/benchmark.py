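"""The simulated-readcount benchmark: denoise -> CBS -> call -> score.

Drives the noise-grid simulation suite through the detection chain for one
or more denoising methods and pools segment-overlap confusion counts, both
overall and stratified by CNV length, plus per-noise-level breakpoint
accuracy.  This is the engine behind ``scripts/acceptance.py`` and the
benchmark tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluate import breakpoint_accuracy, segment_overlap_eval
from .pipeline import PipelineConfig, call_cnvs
from .simulate import SIGMA_GRID, BENCH_N, BENCH_N_CNV, paper_benchmark_suite
from .tracks import AMPLIFICATION, DELETION

#: the narrow-CNV stratum (window lengths, inclusive)
SHORT_RANGE = (1, 20)


@dataclass
class Counts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def add(self, res) -> None:
        self.tp += res.tp
        self.fp += res.fp
        self.fn += res.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def fdr(self) -> float:
        d = self.tp + self.fp
        return self.fp / d if d else float("nan")


@dataclass
class MethodResult:
    """Pooled benchmark metrics for one denoising method."""

    overall: Counts = field(default_factory=Counts)
    sens_short: dict = field(default_factory=lambda: {
        AMPLIFICATION: Counts(), DELETION: Counts()})
    fdr_short: dict = field(default_factory=lambda: {
        AMPLIFICATION: Counts(), DELETION: Counts()})
    # sigma -> list of per-signal breakpoint accuracies
    bp_by_sigma: dict = field(default_factory=dict)

    def bp_median(self) -> dict:
        return {s: float(np.median(v)) for s, v in sorted(
            self.bp_by_sigma.items(), reverse=True)}


def run_benchmark(seed: int,
                  methods: Sequence[str] = ("tautstring",),
                  n_layouts: int = 50,
                  sigma_grid: Sequence[float] = SIGMA_GRID,
                  n: int = BENCH_N,
                  n_cnv: int = BENCH_N_CNV,
                  n_perm: int = 100,
                  alpha: float = 0.01,
                  thr: float = 0.2,
                  min_overlap: float = 0.8,
                  short_range: tuple[int, int] = SHORT_RANGE,
                  ) -> dict[str, MethodResult]:
    """Run the suite through each method and pool the metrics.

    The full suite is ``n_layouts`` truth layouts x every noise level; to
    fit a single-CPU budget this driver samples it diagonally — layout i is
    scored at noise level i mod len(sigma_grid) — so all layouts are
    independent and the grid is covered evenly with n_layouts signals.

    Sensitivity strata select benchmark segments by true length; FDR strata
    select detected calls by detected length (false positives have no true
    counterpart to take a length from).  ``n_perm`` here sizes the CBS
    permutation test for the benchmark runs; p = 1/(n_perm+1) must clear
    ``alpha``.
    """
    results = {m: MethodResult() for m in methods}
    configs = {m: PipelineConfig(method=m, n_perm=n_perm, alpha=alpha,
                                 thr=thr, seed=seed % (2 ** 20))
               for m in methods}
    suite = paper_benchmark_suite(seed, n_replicates=n_layouts,
                                  sigma_grid=sigma_grid, n=n, n_cnv=n_cnv)
    n_levels = len(sigma_grid)
    for case_idx, case in enumerate(suite):
        if case_idx % n_levels != case.replicate % n_levels:
            continue
        for mi, m in enumerate(methods):
            res = results[m]
            calls = call_cnvs(case.signal, configs[m],
                              cbs_seed=(seed + 7919 * case_idx + mi)
                              % (2 ** 31 - 1))
            res.overall.add(segment_overlap_eval(
                calls, case.truth, min_frac=min_overlap))
            for direction in (AMPLIFICATION, DELETION):
                res.sens_short[direction].add(segment_overlap_eval(
                    calls, case.truth, min_frac=min_overlap,
                    truth_length_range=short_range, calls=[direction]))
                res.fdr_short[direction].add(segment_overlap_eval(
                    calls, case.truth, min_frac=min_overlap,
                    detected_length_range=short_range, calls=[direction]))
            bp = breakpoint_accuracy(calls, case.truth)
            res.bp_by_sigma.setdefault(case.sigma, []).append(bp)
    return results
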