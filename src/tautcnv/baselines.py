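"""Comparison denoisers: moving average and wavelet shrinkage.

Both are linear/threshold smoothers without the edge-preserving,
piecewise-constant bias of the taut string; they serve as the reference
points in the benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .tracks import RatioSignal
from .tautstring import _values, estimate_sigma


@dataclass
class BaselineParams:
    ma_window: int = 9
    wavelet_name: str = "haar"
    dwt_level: int | None = None   # None = maximal dyadic depth
    threshold_rule: str = "universal"
    threshold_mode: str = "soft"

    def __post_init__(self) -> None:
        if self.ma_window < 1 or self.ma_window % 2 == 0:
            raise ValueError("ma_window must be odd and >= 1")
        if self.dwt_level is not None and self.dwt_level < 1:
            raise ValueError("dwt_level must be >= 1 or None")
        if self.threshold_rule != "universal":
            raise ValueError("only the universal threshold rule is supported")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError("threshold_mode must be 'soft' or 'hard'")


def moving_average(r, w: int) -> np.ndarray:
    """Centred moving average; near the edges the window shrinks
    symmetrically so the output stays unbiased at a constant signal."""
    x = _values(r)
    n = len(x)
    if w % 2 == 0:
        raise ValueError("window length must be odd")
    if not 1 <= w <= n:
        raise ValueError("window length must be in [1, n]")
    if w == 1:
        return x.copy()
    h = w // 2
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    rho = np.minimum(h, np.minimum(idx, n - 1 - idx))
    lo = idx - rho
    hi = idx + rho + 1
    return (cs[hi] - cs[lo]) / (hi - lo)


def dwt_denoise(r, params: BaselineParams | None = None) -> np.ndarray:
    """Wavelet shrinkage with the universal threshold sigma * sqrt(2 log n).

    The signal is symmetrically padded to the next power of two, decomposed,
    detail coefficients are thresholded, and the reconstruction is truncated
    back to length n.  sigma comes from the successive-difference estimator.
    """
    if params is None:
        params = BaselineParams()
    x = _values(r)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if params.wavelet_name not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unsupported wavelet {params.wavelet_name!r}")
    n2 = 1 << int(np.ceil(np.log2(n)))
    padded = np.pad(x, (0, n2 - n), mode="symmetric") if n2 > n else x
    wavelet = pywt.Wavelet(params.wavelet_name)
    max_level = pywt.dwt_max_level(n2, wavelet.dec_len)
    level = max_level if params.dwt_level is None else min(params.dwt_level,
                                                           max_level)
    coeffs = pywt.wavedec(padded, wavelet, level=level)
    sigma = estimate_sigma(x)
    thr = sigma * np.sqrt(2.0 * np.log(n))
    if params.threshold_mode == "soft":
        shrink = lambda c: np.sign(c) * np.maximum(np.abs(c) - thr, 0.0)
    else:
        shrink = lambda c: np.where(np.abs(c) > thr, c, 0.0)
    coeffs = [coeffs[0]] + [shrink(c) for c in coeffs[1:]]
    rec = pywt.waverec(coeffs, wavelet)
    return rec[:n]


def denoise_baseline(r, method: str,
                     params: BaselineParams | None = None) -> np.ndarray:
    """Dispatch to a baseline by name ('ma' or 'dwt')."""
    if params is None:
        params = BaselineParams()
    if method == "ma":
        return moving_average(r, params.ma_window)
    if method == "dwt":
        return dwt_denoise(r, params)
    raise ValueError(f"unknown baseline {method!r}")
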