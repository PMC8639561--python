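"""Structure-function engines.

The image structure function at integer lag ``m`` is

    d(m) = 1/(N-m) * sum_{n=m}^{N-1} |F_xy(I_{n-m} - I_n)|^2 ,

the average power spectrum of frame differences at fixed delay. Three
engines compute it:

``structure_naive``
    The literal definition — difference first, spatial transform second.
    O(N^2) spatial FFTs; it is the reference oracle.
``structure_direct``
    Differences of cached spectra ``(I~_{n-m} - I~_n)``, exploiting FFT
    linearity. O(N) spatial FFTs but still O(N^2) elementwise work.
``structure_wk``
    Expansion of the squared modulus,

        d(m) = 1/(N-m) * [ sum_{k<=N-1-m} |I~_k|^2
                           + sum_{n>=m} |I~_n|^2  - 2 Re C(m) ],

    where ``C(m) = sum_n I~*_{n-m} I~_n`` is the lagged autocorrelation
    of each wave vector's time series, evaluated through the
    Wiener-Khinchin theorem: zero-pad to length P (smallest power of two
    >= 2N so the circular correlation equals the linear one exactly),
    temporal FFT, squared modulus, inverse FFT. O(N log N) per wave
    vector, independent of how many lags are requested.

When cached spectra for all wave vectors exceed the memory budget, a
:class:`MemoryPlan` splits the half-plane into contiguous groups and the
executor recomputes the spatial FFTs once per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .exceptions import CapacityError, InputError
from .series import ImageSeries
from .spectra import SpectrumStack, WaveVectorGrid, spatial_fft, wavevector_grid

_COMPLEX_ITEMSIZE = {"double": 16, "single": 8}


@dataclass
class WorkCounters:
    """Instrumented operation counts, for complexity accounting.

    ``spatial_ffts`` counts 2D frame transforms, ``temporal_ffts``
    counts 1D transforms along time (forward and inverse separately),
    ``elementwise_passes`` counts per-lag spectrum-difference traversals
    of the direct engine (one per image pair).
    """

    spatial_ffts: int = 0
    temporal_ffts: int = 0
    elementwise_passes: int = 0


@dataclass
class StructureFunction:
    """d(m) over the half-plane wave-vector grid for each requested lag."""

    lags: np.ndarray  # (L,) int
    d: np.ndarray  # (L, H, W//2+1) real
    pair_counts: np.ndarray  # (L,) int, N - m
    dt: float
    grid: WaveVectorGrid
    algorithm: str

    @property
    def lag_times(self) -> np.ndarray:
        """Physical delays ``m * dt`` in seconds."""
        return self.lags * self.dt


@dataclass
class MemoryPlan:
    """Contiguous partition of the half plane into memory-bounded groups."""

    budget_bytes: int
    n_groups: int
    group_ranges: list[tuple[int, int]]
    bytes_per_wavevector: int

    @property
    def total_bytes(self) -> int:
        n_q = self.group_ranges[-1][1] if self.group_ranges else 0
        return n_q * self.bytes_per_wavevector


def _padded_length(N: int) -> int:
    """Smallest power of two >= 2N (linear correlation via circular FFT)."""
    P = 1
    while P < 2 * N:
        P *= 2
    return P


def _validate_lags(lags, N: int) -> np.ndarray:
    if lags is None:
        return np.arange(N)
    lags = np.atleast_1d(np.asarray(lags, dtype=np.int64))
    if lags.size == 0:
        raise InputError("empty lag list")
    if lags.min() < 0 or lags.max() > N - 1:
        raise InputError(
            f"lags must lie in [0, {N - 1}], got range "
            f"[{lags.min()}, {lags.max()}]"
        )
    return lags


def log_spaced_lags(N: int, K: int) -> np.ndarray:
    """About K unique integer lags, log-spaced over [1, N-1] inclusive."""
    if N < 3 or K < 2:
        raise InputError("need N >= 3 and K >= 2 for a log-spaced lag list")
    raw = np.logspace(0.0, math.log10(N - 1), K)
    return np.unique(np.rint(raw).astype(np.int64))


# ---------------------------------------------------------------------------
# engines


def structure_naive(
    series: ImageSeries, lags=None, counters: WorkCounters | None = None
) -> StructureFunction:
    """Literal pair-difference engine (the reference oracle).

    For each lag, every frame pair is differenced in real space and
    transformed; O(sum_m (N-m)) spatial FFTs.
    """
    N = series.n_frames
    lags = _validate_lags(lags, N)
    H, W = series.shape
    grid = wavevector_grid(H, W, series.pixel_size)
    frames = series.frames.astype(np.float64, copy=False)
    d = np.empty((lags.size, H, W // 2 + 1))
    for i, m in enumerate(lags):
        acc = np.zeros((H, W // 2 + 1))
        for n in range(m, N):
            f = scipy.fft.rfft2(frames[n - m] - frames[n])
            acc += f.real**2 + f.imag**2
            if counters is not None:
                counters.spatial_ffts += 1
        d[i] = acc / (N - m)
    return StructureFunction(
        lags=lags, d=d, pair_counts=N - lags, dt=series.dt, grid=grid,
        algorithm="naive",
    )


def _as_spectra(source, precision: str, counters) -> SpectrumStack:
    if isinstance(source, SpectrumStack):
        return source
    if isinstance(source, ImageSeries):
        return spatial_fft(source, precision=precision, counters=counters)
    raise InputError(f"expected ImageSeries or SpectrumStack, got {type(source)!r}")


def structure_direct(
    source: ImageSeries | SpectrumStack,
    lags=None,
    counters: WorkCounters | None = None,
    precision: str = "double",
) -> StructureFunction:
    """Cached-spectra engine: average |I~_{n-m} - I~_n|^2 per lag.

    Mathematically identical to :func:`structure_naive` by linearity of
    the Fourier transform; spatial FFTs drop to O(N) but the elementwise
    differencing still costs O(sum_m (N-m)). Its cost scales with the
    number of requested lags, so a log-spaced sublist
    (:func:`log_spaced_lags`) is worthwhile here.
    """
    spectra = _as_spectra(source, precision, counters)
    N = spectra.n_frames
    lags = _validate_lags(lags, N)
    s = spectra.spectra
    H, Wh = s.shape[1], s.shape[2]
    d = np.empty((lags.size, H, Wh))
    for i, m in enumerate(lags):
        if m == 0:
            d[i] = 0.0
            continue
        acc = np.zeros((H, Wh))
        # accumulate in double regardless of stored precision
        for n in range(m, N):
            diff = s[n - m].astype(np.complex128) - s[n].astype(np.complex128)
            acc += diff.real**2 + diff.imag**2
            if counters is not None:
                counters.elementwise_passes += 1
        d[i] = acc / (N - m)
    out_dtype = np.float32 if s.dtype == np.complex64 else np.float64
    return StructureFunction(
        lags=lags, d=d.astype(out_dtype, copy=False), pair_counts=N - lags,
        dt=spectra.dt, grid=spectra.grid, algorithm="direct",
    )


def lagged_autocorrelation(ts: np.ndarray, counters: WorkCounters | None = None) -> np.ndarray:
    """Linear lagged autocorrelation C(m) = sum_{n=m}^{N-1} ts*(n-m) ts(n).

    Computed by the Wiener-Khinchin route: zero-pad to the smallest
    power of two >= 2N, forward FFT, squared modulus, inverse FFT, read
    lags 0..N-1. The padding makes the circular correlation equal the
    finite linear sum exactly (up to rounding).
    """
    ts = np.asarray(ts)
    if ts.size == 0:
        raise InputError("empty time series")
    return _batched_autocorrelation(ts.reshape(1, -1), counters)[0]


def _batched_autocorrelation(ts: np.ndarray, counters) -> np.ndarray:
    """Rows are independent complex series; returns C with the same shape."""
    N = ts.shape[-1]
    P = _padded_length(N)
    F = scipy.fft.fft(ts, n=P, axis=-1)
    C = scipy.fft.ifft(F.real**2 + F.imag**2, axis=-1)[..., :N]
    if counters is not None:
        counters.temporal_ffts += 2 * ts.shape[0]
    return C


def structure_wk(
    source: ImageSeries | SpectrumStack,
    lags=None,
    plan: MemoryPlan | None = None,
    counters: WorkCounters | None = None,
    precision: str = "double",
) -> StructureFunction:
    """Wiener-Khinchin engine: temporal-FFT autocorrelation per wave vector.

    All N lags are always computed (the temporal-FFT cost does not
    depend on how many are requested); ``lags`` merely selects which are
    returned. With a :class:`MemoryPlan` of G > 1 groups the spatial
    FFTs are recomputed once per group instead of holding every wave
    vector's time series at once.

    Accepts either an :class:`ImageSeries` (spectra computed per group,
    mirroring the recompute-on-split strategy) or a pre-computed
    :class:`SpectrumStack` (sliced per group).
    """
    if isinstance(source, ImageSeries):
        series: ImageSeries | None = source
        cached: SpectrumStack | None = None
        N = source.n_frames
        H, W = source.shape
        grid = wavevector_grid(H, W, source.pixel_size)
        dt = source.dt
        store_single = precision == "single"
    elif isinstance(source, SpectrumStack):
        series = None
        cached = source
        N = source.n_frames
        grid = source.grid
        H, W = grid.H, grid.W
        dt = source.dt
        store_single = source.spectra.dtype == np.complex64
    else:
        raise InputError(f"expected ImageSeries or SpectrumStack, got {type(source)!r}")

    requested = _validate_lags(lags, N)
    n_q = grid.n_wavevectors
    ranges = plan.group_ranges if plan is not None else [(0, n_q)]
    if plan is not None:
        covered = sorted(ranges)
        if covered[0][0] != 0 or covered[-1][1] != n_q or any(
            covered[i][1] != covered[i + 1][0] for i in range(len(covered) - 1)
        ):
            raise InputError("memory plan does not partition the wave-vector grid")

    m = np.arange(N)
    norm = (N - m).astype(np.float64)
    d_flat = np.empty((N, n_q))
    for lo, hi in ranges:
        if series is not None:
            group_spec = spatial_fft(series, precision=precision, counters=counters)
        else:
            group_spec = cached
        s = group_spec.spectra.reshape(N, n_q)[:, lo:hi]
        s = s.astype(np.complex128, copy=False)  # accumulate in double always
        p = s.real**2 + s.imag**2
        csum = np.cumsum(p, axis=0)
        total = csum[-1]
        # first (N-m) power spectra and last (N-m) power spectra
        term_head = csum[::-1]  # term_head[m] = sum_{k=0}^{N-1-m} p_k
        term_tail = total[None, :] - np.concatenate(
            [np.zeros((1, hi - lo)), csum[:-1]], axis=0
        )  # term_tail[m] = sum_{n=m}^{N-1} p_n
        C = _batched_autocorrelation(s.T, counters).T  # (N, n_group)
        d = (term_head + term_tail - 2.0 * C.real) / norm[:, None]
        d[0] = 0.0  # the expansion collapses identically at zero lag
        d_flat[:, lo:hi] = d

    d_full = d_flat.reshape(N, H, W // 2 + 1)[requested]
    out_dtype = np.float32 if store_single else np.float64
    return StructureFunction(
        lags=requested, d=d_full.astype(out_dtype, copy=False),
        pair_counts=N - requested, dt=dt, grid=grid, algorithm="wk",
    )


# ---------------------------------------------------------------------------
# memory planning


def bytes_per_wavevector(N: int, precision: str = "double") -> int:
    """Cost of one wave vector's time series plus temporal-FFT workspace.

    N complex samples at working precision plus a padded buffer of
    length P (smallest power of two >= 2N).
    """
    try:
        itemsize = _COMPLEX_ITEMSIZE[precision]
    except KeyError:
        raise InputError(f"precision must be 'single' or 'double', got {precision!r}")
    return (N + _padded_length(N)) * itemsize


def plan_memory(
    N: int, H: int, W: int, precision: str = "double", budget_bytes: int | None = None
) -> MemoryPlan:
    """Partition the half plane into the fewest contiguous <=-budget groups.

    Groups are balanced by wave-vector count; a single group is returned
    whenever the whole job fits the budget.
    """
    per = bytes_per_wavevector(N, precision)
    n_q = H * (W // 2 + 1)
    if budget_bytes is None:
        return MemoryPlan(
            budget_bytes=n_q * per, n_groups=1, group_ranges=[(0, n_q)],
            bytes_per_wavevector=per,
        )
    max_per_group = budget_bytes // per
    if max_per_group < 1:
        raise CapacityError(
            f"budget of {budget_bytes} B cannot hold one wave vector "
            f"({per} B for N={N}, {precision} precision)"
        )
    G = math.ceil(n_q / max_per_group)
    bounds = np.linspace(0, n_q, G + 1).astype(int)
    ranges = [(int(bounds[i]), int(bounds[i + 1])) for i in range(G)]
    return MemoryPlan(
        budget_bytes=budget_bytes, n_groups=G, group_ranges=ranges,
        bytes_per_wavevector=per,
    )


def plan_with_groups(N: int, H: int, W: int, G: int, precision: str = "double") -> MemoryPlan:
    """A plan with an explicitly requested number of groups (for testing
    chunk invariance and for reproducing a particular split)."""
    per = bytes_per_wavevector(N, precision)
    n_q = H * (W // 2 + 1)
    if not 1 <= G <= n_q:
        raise InputError(f"G must lie in [1, {n_q}], got {G}")
    bounds = np.linspace(0, n_q, G + 1).astype(int)
    ranges = [(int(bounds[i]), int(bounds[i + 1])) for i in range(G)]
    budget = max(hi - lo for lo, hi in ranges) * per
    return MemoryPlan(
        budget_bytes=budget, n_groups=G, group_ranges=ranges,
        bytes_per_wavevector=per,
    )
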