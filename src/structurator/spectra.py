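"""Spatial Fourier transforms of frames and the wave-vector geometry.

Both structure-function algorithms share a first step: the bidimensional
FFT of every frame. Frames are real, so only the Hermitian-reduced half
plane of ``H x (W//2 + 1)`` wave vectors is stored; a multiplicity array
(2 for the columns duplicated by Hermitian symmetry, 1 for the
self-conjugate ``k_x = 0`` and Nyquist columns) makes half-plane
averages equal to full-plane averages.

Conventions
-----------
The forward transform is unnormalized (no ``1/(H*W)`` factor), so the
DC component equals the pixel sum of the frame and Parseval reads
``sum_fullplane |I~(q)|^2 = H*W * sum_xy I(x,y)^2``. Wave-vector
components are ``q_i = 2*pi*k_i / (n_i * pixel_size)`` in rad/m with
integer frequency index ``k_i`` in ``[-n_i/2, n_i/2)``. No window is
applied before the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .exceptions import DimensionError, InputError
from .series import ImageSeries


@dataclass
class WaveVectorGrid:
    """Half-plane wave-vector magnitudes and Hermitian multiplicities."""

    H: int
    W: int
    pixel_size: float
    q_magnitudes: np.ndarray  # (H, W//2+1), rad/m
    multiplicity: np.ndarray  # (H, W//2+1), int

    @property
    def n_wavevectors(self) -> int:
        return self.H * (self.W // 2 + 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WaveVectorGrid):
            return NotImplemented
        return (
            self.H == other.H
            and self.W == other.W
            and self.pixel_size == other.pixel_size
        )


@dataclass
class SpectrumStack:
    """Per-frame half-plane spatial transforms, ``(N, H, W//2+1)`` complex."""

    spectra: np.ndarray
    grid: WaveVectorGrid
    dt: float

    @property
    def n_frames(self) -> int:
        return self.spectra.shape[0]


def wavevector_grid(H: int, W: int, pixel_size: float) -> WaveVectorGrid:
    """Build the half-plane grid of ``|q|`` and Hermitian multiplicities.

    Only even frame dimensions are accepted; odd sizes complicate the
    Nyquist bookkeeping for no practical gain with camera sensors.
    """
    if H <= 0 or W <= 0 or H % 2 or W % 2:
        raise InputError(f"frame dimensions must be even and positive, got {H}x{W}")
    if not pixel_size > 0:
        raise InputError(f"pixel_size must be positive, got {pixel_size}")
    qy = 2.0 * np.pi * np.fft.fftfreq(H, d=pixel_size)
    qx = 2.0 * np.pi * np.fft.rfftfreq(W, d=pixel_size)
    q_mag = np.hypot(qy[:, None], qx[None, :])
    mult = np.ones((H, W // 2 + 1), dtype=np.int64)
    mult[:, 1 : W // 2] = 2  # interior columns appear at +k_x and -k_x
    return WaveVectorGrid(H=H, W=W, pixel_size=pixel_size, q_magnitudes=q_mag, multiplicity=mult)


def spatial_fft(
    series: ImageSeries,
    precision: str = "double",
    counters=None,
) -> SpectrumStack:
    """Unnormalized forward rfft2 of every frame.

    ``precision`` selects the working dtype of the stored spectra
    (``"double"`` -> complex128, ``"single"`` -> complex64); double is
    the default because validation against the literal pair-difference
    definition demands it.
    """
    if precision not in ("double", "single"):
        raise InputError(f"precision must be 'single' or 'double', got {precision!r}")
    frames = series.frames
    if not np.all(np.isfinite(frames)):
        raise InputError("frames contain non-finite pixels")
    H, W = series.shape
    grid = wavevector_grid(H, W, series.pixel_size)
    work = frames.astype(np.float32) if precision == "single" else frames
    spec = scipy.fft.rfft2(work, axes=(-2, -1))
    if counters is not None:
        counters.spatial_ffts += series.n_frames
    return SpectrumStack(spectra=spec, grid=grid, dt=series.dt)


def hermitian_full_plane(half: np.ndarray, W: int) -> np.ndarray:
    """Reconstruct the full ``H x W`` plane from a half-plane transform.

    Mainly used by tests and the azimuthal-average cross-checks; columns
    ``k_x = 1 .. W/2-1`` are mirrored to negative ``k_x`` with complex
    conjugation and row index negated.
    """
    H = half.shape[-2]
    if half.shape[-1] != W // 2 + 1:
        raise DimensionError("half-plane width does not match W")
    full = np.zeros(half.shape[:-1] + (W,), dtype=complex)
    full[..., : W // 2 + 1] = half
    rows = (-np.arange(H)) % H
    for kx in range(1, W // 2):
        full[..., rows, W - kx] = np.conj(half[..., :, kx])
    return full
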