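import numpy as np
import pytest

from structurator import ImageSeries


@pytest.fixture
def make_series():
    """Factory for seeded random-intensity series (16-bit value range)."""

    def _make(seed=0, N=16, H=8, W=8, dt=0.04, pixel_size=1e-6):
        rng = np.random.default_rng(seed)
        frames = rng.integers(0, 65536, size=(N, H, W)).astype(np.float64)
        return ImageSeries(frames=frames, dt=dt, pixel_size=pixel_size, bit_depth=16)

    return _make


def full_plane_dft(frame):
    """Brute-force full-plane 2D DFT, the independent spectral oracle."""
    H, W = frame.shape
    y, x = np.arange(H), np.arange(W)
    out = np.empty((H, W), dtype=complex)
    for ky in range(H):
        for kx in range(W):
            phase = np.exp(
                -2j * np.pi * (ky * y[:, None] / H + kx * x[None, :] / W)
            )
            out[ky, kx] = np.sum(frame * phase)
    return out
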