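# tautcnv

Read-depth CNV detection built around taut-string total-variation
denoising of windowed readcount log2-ratio signals.

Copy-number variants leave a piecewise-constant footprint in the per-window
log2 ratio of sample to matched-normal readcounts, r = f + ε with
ε ~ N(0, σ_N²) — but the noise and the GC/mappability biases of sequencing
data routinely bury focal events and blur breakpoints, which is where
segmentation algorithms fail. `tautcnv` is for people analyzing WES/WGS
coverage tracks (or benchmarking CNV callers) who want an edge-preserving
denoiser in front of segmentation, plus the simulation and evaluation
machinery to measure what it buys.

The core is the exact 1-D total-variation minimizer

    min_f  ½ Σᵢ (rᵢ − fᵢ)² + λ Σᵢ |fᵢ₊₁ − fᵢ|

computed by the taut-string construction: thread the shortest string
through the tube Rᵢ ± ϑ around the running sums Rᵢ = Σ_{u≤i} r_u, pinned at
both ends; its increments are the denoised signal. The default radius is
ϑ = 0.5λ with λ = c·√n·σ and σ the robust successive-difference noise
estimate (1.48/√2)·median|rᵢ₊₁ − rᵢ|. Local squeezing then shrinks the
tube by γ = 0.5 wherever residuals violate a multiresolution bound, so
narrow CNVs survive a tube sized for the whole chromosome. Downstream:
circular binary segmentation (permutation-tested arc splits), ±thr calling
on segment means, and segment-overlap evaluation (sensitivity, FDR,
specificity at ≥80% benchmark overlap; exact-breakpoint accuracy).
Moving-average and wavelet-shrinkage baselines ship alongside.
See `docs/methods.md` for the model, parameters and design choices.

## Worked example

Simulate a 10,000-window signal containing three CNVs — a 400-window and a
60-window amplification and a 12-window deletion — at noise σ_N = 0.25,
run the full chain, and score it:

```python
import numpy as np
from tautcnv import (SimConfig, simulate_ratio_signal, PipelineConfig,
                     call_cnvs, segment_overlap_eval, breakpoint_accuracy)

cfg = SimConfig(n=10_000, cnv_segments=[(2_000, 400, 1.0), (5_000, 12, -1.0),
                                        (8_000, 60, 1.0)],
                sigma_N=0.25, seed=7)
truth, signal = simulate_ratio_signal(cfg)
calls = call_cnvs(signal, PipelineConfig(method="tautstring", n_perm=200,
                                         seed=11))
for s in calls:
    if s.call != "neutral":
        print(f"{s.start_idx:>5} {s.end_idx:>5} {s.mean_value:+.3f} {s.call}")
res = segment_overlap_eval(calls, truth)
print(f"sensitivity={res.sensitivity:.2f} fdr={res.fdr:.2f} "
      f"breakpoint_accuracy={breakpoint_accuracy(calls, truth):.2f}")
```

prints

```
 2000  2399 +0.981 amplification
 5000  5012 -0.547 deletion
 8000  8059 +0.899 amplification
sensitivity=1.00 fdr=0.00 breakpoint_accuracy=0.67
```

All three CNVs are recovered (sensitivity 1.0, no false calls); the two
amplifications have exact breakpoints, while the 12-window deletion —
whose observed mean is shrunk toward 0 by the penalty but kept above the
0.2 calling threshold by local squeezing — overshoots its right edge by
one window, hence breakpoint accuracy 2/3.

The same chain is available from the shell:

```
tautcnv simulate --n 100000 --sigma 0.2 --seed 1 \
    --out-truth truth.bed --out-signal signal.txt
tautcnv denoise --method tautstring --signal signal.txt --out denoised.txt
tautcnv segment --signal denoised.txt --thr 0.2 --seed 7 --out calls.bed
tautcnv evaluate --truth truth.bed --calls calls.bed
```

plus `preprocess` (filter → GC-correct → log2 ratio for BED track pairs)
and `pipeline` (everything end to end).

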