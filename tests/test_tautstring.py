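"""Taut-string denoiser: exactness, structure, squeezing behaviour."""

import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import tv_denoise_oracle, tv_objective
from conftest import make_piecewise
from tautcnv.tautstring import (DenoiseResult, TautStringParams,
                                count_local_extrema, default_lambda, denoise,
                                estimate_sigma, taut_string)

SIGMA_SCALE = 1.48 / np.sqrt(2.0)


class TestEstimateSigma:
    def test_constant_signal_gives_zero(self):
        assert estimate_sigma(np.full(10, 3.0)) == 0.0

    def test_alternating_signal(self):
        r = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        assert estimate_sigma(r) == pytest.approx(SIGMA_SCALE, rel=1e-12)

    def test_recovers_noise_scale_with_sparse_jumps(self, rng):
        for _ in range(5):
            f = np.repeat(rng.normal(scale=2, size=6), 3400)[:20000]
            r = f + rng.normal(scale=0.2, size=20000)
            assert estimate_sigma(r) == pytest.approx(0.2, rel=0.05)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.array([1.0]))


class TestDefaultLambda:
    def test_constant_signal_gives_zero(self):
        assert default_lambda(np.zeros(50), c=1.0) == 0.0

    def test_arithmetic_and_linearity(self, rng):
        r = rng.normal(size=100)
        sigma = estimate_sigma(r)
        assert default_lambda(r, c=0.3) == pytest.approx(3.0 * sigma)
        assert default_lambda(r, c=0.6) == pytest.approx(
            2 * default_lambda(r, c=0.3))


class TestTautString:
    def test_zero_radius_interpolates(self, rng):
        r = rng.normal(size=50)
        assert np.allclose(taut_string(r, 0.0).f_hat, r, atol=1e-10)

    def test_two_point_closed_form(self):
        res = taut_string(np.array([0.0, 2.0]), 0.5)
        assert np.allclose(res.f_hat, [0.5, 1.5])
        # radius beyond the half-gap collapses to the mean
        res = taut_string(np.array([0.0, 2.0]), 1.5)
        assert np.allclose(res.f_hat, [1.0, 1.0])

    def test_wide_tube_gives_global_mean(self, rng):
        r = rng.normal(size=200)
        R = np.concatenate(([0.0], np.cumsum(r)))
        chord = np.arange(201) / 200 * R[-1]
        res = taut_string(r, np.max(np.abs(R - chord)) + 1e-9)
        assert np.allclose(res.f_hat, r.mean())
        assert len(res.breakpoints) == 0

    def test_negative_radius_errors(self):
        with pytest.raises(ValueError):
            taut_string(np.zeros(5), -1.0)

    def test_matches_exact_tv_minimizer(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 200))
            r = make_piecewise(rng, n)
            lam = float(rng.uniform(0.01, 4.0))
            f = taut_string(r, lam).f_hat
            assert np.max(np.abs(f - tv_denoise_oracle(r, lam))) < 1e-7


@settings(max_examples=60, deadline=None, derandomize=True)
@given(values=st.lists(st.floats(-10, 10, allow_nan=False), min_size=2,
                       max_size=30),
       lam=st.floats(1e-3, 5.0))
def test_taut_string_equals_tv_minimizer_property(values, lam):
    """Property form of the exactness check on arbitrary small inputs."""
    r = np.asarray(values)
    f = taut_string(r, lam).f_hat
    oracle = tv_denoise_oracle(r, lam)
    assert tv_objective(r, f, lam) <= tv_objective(r, oracle, lam) + 1e-8
    assert np.max(np.abs(f - oracle)) < 1e-6


def cumsum_with_zero(x):
    return np.concatenate(([0.0], np.cumsum(x)))


class TestStringStructure:
    """Tube feasibility, pinned endpoints, run-mean structure."""

    def make_case(self, rng):
        n = int(rng.integers(10, 400))
        r = make_piecewise(rng, n)
        lam = float(rng.uniform(0.05, 3.0))
        return r, lam, taut_string(r, 0.5 * lam)

    def test_tube_feasibility_and_endpoints(self, rng):
        for _ in range(40):
            r, lam, res = self.make_case(rng)
            R = cumsum_with_zero(r)
            S = cumsum_with_zero(res.f_hat)
            assert S[0] == 0.0
            assert abs(S[-1] - R[-1]) < 1e-9
            assert np.all(np.abs(S - R) <= res.theta + 1e-9)

    def test_piecewise_constant_run_count(self, rng):
        for _ in range(40):
            _, _, res = self.make_case(rng)
            n_runs = 1 + int(np.sum(res.f_hat[1:] != res.f_hat[:-1]))
            assert n_runs == len(res.breakpoints) + 1

    def test_run_means_follow_kkt_structure(self, rng):
        """Interior non-extremum runs equal the data mean over the run;
        boundary runs deviate by theta/len and extremum runs by 2*theta/len
        (the dual variable is pinned at ±theta at the enclosing knots)."""
        for _ in range(40):
            r, lam, res = self.make_case(rng)
            theta = 0.5 * lam
            f = res.f_hat
            starts = np.concatenate(([0], res.breakpoints, [len(f)]))
            vals = f[starts[:-1]]
            for k in range(len(vals)):
                a, b = starts[k], starts[k + 1]
                dev = (f[a] - r[a:b].mean()) * (b - a)
                boundary = k == 0 or k == len(vals) - 1
                if boundary:
                    allowed = (0.0, theta)
                else:
                    left, mid, right = vals[k - 1], vals[k], vals[k + 1]
                    extremum = (mid > left and mid > right) or \
                               (mid < left and mid < right)
                    allowed = (0.0, 2.0 * theta) if extremum else (0.0,)
                assert any(abs(abs(dev) - a_) < 1e-8 for a_ in allowed), \
                    (k, dev, allowed)

    def test_breakpoint_count_non_increasing_in_lambda(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 300))
            r = make_piecewise(rng, n)
            lams = np.linspace(0.01, 3.0, 12)
            counts = [len(taut_string(r, 0.5 * lam).breakpoints)
                      for lam in lams]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDenoise:
    def test_noiseless_step_recovered_exactly(self):
        f = np.concatenate([np.zeros(50), np.ones(50)])
        res = denoise(f, TautStringParams())
        assert list(res.breakpoints) == [50]
        assert np.allclose(res.f_hat[:50], 0.0, atol=1e-6)
        assert np.allclose(res.f_hat[50:], 1.0, atol=1e-6)

    def test_single_pass_when_residuals_pass(self, rng):
        r = rng.normal(scale=0.1, size=500)
        res = denoise(r, TautStringParams())
        if res.squeeze_rounds == 1:
            plain = taut_string(r, 0.5 * res.lam)
            assert np.array_equal(res.f_hat, plain.f_hat)

    def test_multiresolution_off_equals_plain_pass(self, rng):
        r = make_piecewise(rng, 300)
        res = denoise(r, TautStringParams(use_multiresolution=False))
        plain = taut_string(r, 0.5 * res.lam)
        assert np.array_equal(res.f_hat, plain.f_hat)
        assert res.squeeze_rounds == 1

    def test_squeezing_recovers_narrow_spike(self, rng):
        # a 3-window CNV that the global radius flattens
        f = np.zeros(2000)
        f[1000:1003] = 1.0
        r = f + rng.normal(scale=0.2, size=2000)
        plain = denoise(r, TautStringParams(use_multiresolution=False))
        squeezed = denoise(r, TautStringParams())
        assert np.max(plain.f_hat[1000:1003]) < 0.5
        assert np.max(squeezed.f_hat[1000:1003]) > 0.5

    def test_gentle_squeeze_yields_fewer_extrema(self, rng):
        gentler, harsher = [], []
        for _ in range(20):
            f = np.zeros(1500)
            f[400:410] = 1.0
            f[900:901] = -1.0
            r = f + rng.normal(scale=0.25, size=1500)
            gentler.append(denoise(r, TautStringParams(gamma=0.8)).k)
            harsher.append(denoise(r, TautStringParams(gamma=0.1)).k)
        assert np.median(gentler) <= np.median(harsher)

    def test_repeat_denoising_does_not_raise_total_variation(self, rng):
        for _ in range(10):
            r = make_piecewise(rng, 400)
            f1 = denoise(r, TautStringParams()).f_hat
            f2 = denoise(f1, TautStringParams()).f_hat
            tv = lambda x: np.sum(np.abs(np.diff(x)))
            assert tv(f2) <= tv(f1) + 1e-9

    def test_nonconvergence_is_flagged_not_raised(self, rng):
        r = make_piecewise(rng, 600, n_jumps=40, noise=0.4)
        res = denoise(r, TautStringParams(max_squeeze_iters=1,
                                          mr_threshold_const=0.01))
        assert isinstance(res, DenoiseResult)
        assert not res.converged
        assert res.squeeze_rounds == 1

    def test_deterministic(self, rng):
        r = make_piecewise(rng, 500)
        a = denoise(r, TautStringParams()).f_hat
        b = denoise(r, TautStringParams()).f_hat
        assert np.array_equal(a, b)


def test_count_local_extrema():
    assert count_local_extrema(np.array([0, 0, 1, 1, 0, 0.0])) == 1
    assert count_local_extrema(np.array([0, 1, 2, 3.0])) == 0
    assert count_local_extrema(np.array([0, 2, 1, 3, 0.0])) == 3
    assert count_local_extrema(np.array([0, 2, 0, 0.0])) == 1


def test_runtime_scales_roughly_linearly(rng):
    """Amortized linear-time construction: the log-log slope of runtime
    versus n stays near 1 (generous band; timing noise is real)."""
    sizes = [30_000, 100_000, 300_000, 1_000_000]
    times = []
    f = np.repeat(rng.normal(size=100), sizes[-1] // 100 + 1)
    noise = rng.normal(scale=0.3, size=sizes[-1])
    taut_string(noise[:1000], 1.0)   # warm the JIT
    for n in sizes:
        r = f[:n] + noise[:n]
        best = np.inf
        for _ in range(3):
            t0 = time.perf_counter()
            taut_string(r, 0.5 * default_lambda(r))
            best = min(best, time.perf_counter() - t0)
        times.append(best)
    slope = np.polyfit(np.log(sizes), np.log(times), 1)[0]
    assert 0.6 < slope < 1.4, (sizes, times)
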