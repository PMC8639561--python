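"""Engine correctness: literal definition, spectral route, Wiener-Khinchin
route, lag handling, and memory planning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from structurator import (
    CapacityError,
    ImageSeries,
    InputError,
    WorkCounters,
    bytes_per_wavevector,
    lagged_autocorrelation,
    log_spaced_lags,
    plan_memory,
    plan_with_groups,
    spatial_fft,
    structure_direct,
    structure_naive,
    structure_wk,
)

ENGINES = {
    "naive": lambda s, **kw: structure_naive(s, **kw),
    "direct": lambda s, **kw: structure_direct(s, **kw),
    "wk": lambda s, **kw: structure_wk(s, **kw),
}


def _rel_dev(a, b):
    return np.abs(a - b).max() / max(np.abs(b).max(), 1e-300)


class TestNaive:
    def test_two_by_two_hand_dft_oracle(self):
        # I0 - I1 = [[1, 0], [0, -1]]; DFT F(ky,kx) = 1 - (-1)^(ky+kx)
        # |F|^2 full plane = [[0, 4], [4, 0]]; half plane keeps both columns
        series = ImageSeries(
            frames=np.array([[[1.0, 0.0], [0.0, 0.0]], [[0.0, 0.0], [0.0, 1.0]]]),
            dt=1.0, pixel_size=1.0,
        )
        sf = structure_naive(series, lags=[1])
        np.testing.assert_allclose(sf.d[0], [[0.0, 4.0], [4.0, 0.0]], atol=1e-14)

    def test_identical_frames_give_zero(self):
        series = ImageSeries(
            frames=np.tile(np.arange(16.0).reshape(4, 4), (5, 1, 1)),
            dt=1.0, pixel_size=1.0,
        )
        sf = structure_naive(series)
        assert np.abs(sf.d).max() == 0.0

    def test_pair_counts(self, make_series):
        sf = structure_naive(make_series(N=10))
        np.testing.assert_array_equal(sf.pair_counts, 10 - np.arange(10))


class TestDirect:
    def test_matches_naive_on_random_frames(self, make_series):
        series = make_series(seed=11, N=16, H=8, W=8)
        ref = structure_naive(series)
        got = structure_direct(spatial_fft(series))
        assert _rel_dev(got.d, ref.d) < 1e-12

    def test_accepts_series_directly(self, make_series):
        series = make_series(seed=11, N=8)
        np.testing.assert_array_equal(
            structure_direct(series).d, structure_direct(spatial_fft(series)).d
        )


class TestLaggedAutocorrelation:
    def test_constant_series_closed_form(self):
        c = 2.0 - 1.5j
        N = 11
        C = lagged_autocorrelation(np.full(N, c))
        np.testing.assert_allclose(C, (N - np.arange(N)) * abs(c) ** 2, rtol=1e-12)

    def test_lag_zero_is_total_power(self):
        rng = np.random.default_rng(5)
        ts = rng.normal(size=9) + 1j * rng.normal(size=9)
        C = lagged_autocorrelation(ts)
        assert C[0].real == pytest.approx(np.sum(np.abs(ts) ** 2), rel=1e-12)
        assert abs(C[0].imag) <= 1e-10 * C[0].real  # temporal-route residual

    def test_matches_direct_double_sum(self):
        rng = np.random.default_rng(12)
        ts = rng.normal(size=16) + 1j * rng.normal(size=16)
        C = lagged_autocorrelation(ts)
        direct = np.array(
            [np.sum(np.conj(ts[: 16 - m]) * ts[m:]) for m in range(16)]
        )
        assert _rel_dev(C, direct) < 1e-12

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=hst.integers(0, 10_000), n=hst.integers(1, 40))
    def test_wiener_khinchin_identity_property(self, seed, n):
        rng = np.random.default_rng(seed)
        ts = rng.normal(size=n) + 1j * rng.normal(size=n)
        C = lagged_autocorrelation(ts)
        direct = np.array([np.sum(np.conj(ts[: n - m]) * ts[m:]) for m in range(n)])
        np.testing.assert_allclose(C, direct, atol=1e-10 * max(1.0, np.abs(direct).max()))

    def test_empty_series_rejected(self):
        with pytest.raises(InputError):
            lagged_autocorrelation(np.array([]))


class TestWienerKhinchinEngine:
    def test_matches_naive_on_random_frames(self, make_series):
        series = make_series(seed=21, N=64, H=16, W=16)
        ref = structure_naive(series)
        got = structure_wk(spatial_fft(series))
        assert _rel_dev(got.d, ref.d) < 1e-9

    def test_two_frame_identity(self, make_series):
        series = make_series(seed=8, N=2)
        spec = spatial_fft(series)
        sf = structure_wk(spec, lags=[1])
        expected = np.abs(spec.spectra[0] - spec.spectra[1]) ** 2
        np.testing.assert_allclose(sf.d[0], expected, rtol=1e-12)

    def test_identical_frames_give_zero(self):
        series = ImageSeries(
            frames=np.tile(np.arange(36.0).reshape(6, 6), (8, 1, 1)),
            dt=1.0, pixel_size=1.0,
        )
        sf = structure_wk(series)
        assert np.abs(sf.d).max() < 1e-6  # absolute rounding on ~1e3 magnitudes

    def test_requested_lag_subset(self, make_series):
        series = make_series(seed=13, N=12)
        all_lags = structure_wk(series)
        some = structure_wk(series, lags=[1, 3, 7])
        np.testing.assert_array_equal(some.lags, [1, 3, 7])
        np.testing.assert_array_equal(some.d, all_lags.d[[1, 3, 7]])

    def test_chunk_invariance(self, make_series):
        series = make_series(seed=17, N=24, H=8, W=8)
        ref = structure_wk(series)
        for G in (1, 2, 4, 7):
            plan = plan_with_groups(24, 8, 8, G)
            got = structure_wk(series, plan=plan)
            assert _rel_dev(got.d, ref.d) <= 1e-12

    def test_single_precision_storage_double_accumulation(self, make_series):
        series = make_series(seed=2, N=16)
        d64 = structure_wk(spatial_fft(series)).d
        d32 = structure_wk(spatial_fft(series, precision="single")).d
        assert d32.dtype == np.float32
        assert _rel_dev(d32.astype(np.float64), d64) < 1e-4

    def test_lag_out_of_range(self, make_series):
        series = make_series(N=8)
        for engine in ENGINES.values():
            with pytest.raises(InputError):
                engine(series, lags=[8])


@pytest.mark.parametrize("name", ["naive", "direct", "wk"])
class TestSharedInvariants:
    def test_zero_lag_is_exactly_zero(self, name, make_series):
        sf = ENGINES[name](make_series(seed=31, N=10))
        assert np.all(sf.d[sf.lags == 0] == 0.0)

    def test_nonnegative_up_to_rounding(self, name, make_series):
        sf = ENGINES[name](make_series(seed=32, N=12))
        assert sf.d.min() >= -1e-9 * sf.d.max()


class TestMemoryPlanning:
    def test_single_group_when_budget_suffices(self):
        plan = plan_memory(16, 8, 8, budget_bytes=10**9)
        assert plan.n_groups == 1
        assert plan.group_ranges == [(0, 8 * 5)]

    def test_ceiling_arithmetic_example(self):
        # 10 wave vectors, budget worth 3 of them -> 4 groups
        per = bytes_per_wavevector(16)
        plan = plan_memory(16, 2, 8, budget_bytes=3 * per)
        assert plan.n_groups == 4
        assert plan.group_ranges[0][0] == 0
        assert plan.group_ranges[-1][1] == 10
        for (lo, hi), (lo2, _) in zip(plan.group_ranges, plan.group_ranges[1:]):
            assert hi == lo2
        assert all(
            (hi - lo) * per <= plan.budget_bytes for lo, hi in plan.group_ranges
        )

    @pytest.mark.parametrize("budget_wavevectors", [1, 3, 7, 100, 2080, 5000])
    def test_minimal_partition_oracle(self, budget_wavevectors):
        # brute force: fewest contiguous <=-budget chunks of uniform-cost items
        N, H, W = 256, 64, 64
        per = bytes_per_wavevector(N, "double")
        n_q = H * (W // 2 + 1)
        budget = budget_wavevectors * per
        greedy_groups = -(-n_q // budget_wavevectors)
        plan = plan_memory(N, H, W, "double", budget)
        assert plan.n_groups == greedy_groups
        assert all((hi - lo) * per <= budget for lo, hi in plan.group_ranges)

    def test_budget_below_one_wavevector(self):
        per = bytes_per_wavevector(64)
        with pytest.raises(CapacityError):
            plan_memory(64, 8, 8, budget_bytes=per - 1)

    def test_bytes_per_wavevector_accounting(self):
        # N complex doubles plus a padded workspace of the next power of
        # two >= 2N, 16 bytes each
        assert bytes_per_wavevector(100, "double") == (100 + 256) * 16
        assert bytes_per_wavevector(100, "single") == (100 + 256) * 8


class TestLagLists:
    def test_log_spaced_contract(self):
        lags = log_spaced_lags(100, 10)
        assert lags.size == 10
        assert lags[0] == 1 and lags[-1] == 99
        assert np.unique(lags).size == lags.size

    def test_log_spaced_validation(self):
        with pytest.raises(InputError):
            log_spaced_lags(2, 10)


class TestWorkAccounting:
    def test_wk_counts_independent_of_requested_lags(self, make_series):
        series = make_series(seed=41, N=32, H=8, W=8)
        n_q = 8 * 5
        for lags in (None, [1], [1, 5, 9]):
            counters = WorkCounters()
            structure_wk(series, lags=lags, counters=counters)
            assert counters.temporal_ffts == 2 * n_q
            assert counters.spatial_ffts == 32

    def test_wk_counts_scale_with_groups(self, make_series):
        series = make_series(seed=41, N=32, H=8, W=8)
        for G in (1, 2, 5):
            counters = WorkCounters()
            structure_wk(series, plan=plan_with_groups(32, 8, 8, G), counters=counters)
            # temporal work is per wave vector, not per group; spatial
            # FFTs are recomputed once per group
            assert counters.temporal_ffts == 2 * 8 * 5
            assert counters.spatial_ffts == 32 * G

    def test_direct_pass_count_grows_with_lags(self, make_series):
        series = make_series(seed=42, N=32, H=8, W=8)
        counters = WorkCounters()
        structure_direct(series, counters=counters)
        assert counters.elementwise_passes == sum(32 - m for m in range(1, 32))
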