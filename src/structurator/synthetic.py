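"""Synthetic image series with analytically known dynamics.

Two generators make every stage of the pipeline testable without any
experimental data:

* :func:`generate_brownian_series` renders point particles undergoing
  2D Brownian motion as Gaussian blobs on a uniform background with
  additive camera noise. Because the wave vectors of the periodic
  domain are commensurate with the box, periodic wrapping is invisible
  to exp(i q . x) and the intermediate scattering function is exactly
  exp(-D q^2 t) wherever the blobs carry signal (the blob envelope
  attenuates power as exp(-sigma^2 q_pix^2), so the usable band ends
  near q ~ 1/blob_sigma in pixel units).
* :func:`generate_noise_series` draws i.i.d. zero-mean Gaussian frames,
  whose structure function has the flat analytic expectation
  2 H W sigma^2 at every nonzero wave vector and lag m >= 1 under the
  unnormalized-FFT convention.

All randomness comes from ``numpy.random.default_rng`` (PCG64) seeded
with the mandatory config seed, so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .series import ImageSeries

_TRUNC_SIGMAS = 4.0  # blob stamps truncated at 4 sigma


@dataclass
class BrownianConfig:
    """Parameters of the Brownian-particle image fixture.

    Defaults are sized for desk-scale validation runs: a 128 x 128
    sensor at 25 Hz (dt = 0.04 s) with micron pixels, 200 particles of
    diffusion coefficient 0.5 um^2/s imaged as 2-pixel Gaussian blobs.
    """

    seed: int
    n_particles: int = 200
    D_true: float = 0.5e-12  # m^2/s
    N: int = 1024
    H: int = 128
    W: int = 128
    dt: float = 0.04  # s
    pixel_size: float = 1e-6  # m
    blob_sigma: float = 2.0  # pixels
    intensity: float = 1000.0  # integrated counts per particle
    background: float = 100.0  # counts
    noise_sigma: float = 2.0  # counts, additive Gaussian camera noise

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("a seed is mandatory for reproducible fixtures")
        for name in ("n_particles", "N", "H", "W", "dt", "pixel_size",
                     "blob_sigma", "intensity"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be positive")
        if self.D_true < 0 or self.noise_sigma < 0 or self.background < 0:
            raise InputError("D_true, noise_sigma and background must be >= 0")
        if self.blob_sigma < 1.0:
            raise InputError("blob_sigma must be >= 1 pixel (band-limited signal)")
        if _TRUNC_SIGMAS * self.blob_sigma * 2 >= min(self.H, self.W):
            raise InputError("blob footprint covers the whole frame")


def _render_frames(positions: np.ndarray, cfg: BrownianConfig) -> np.ndarray:
    """Sample Gaussian blobs of unit integrated flux * intensity onto the
    pixel grid, with periodic wrap, one frame per time step."""
    N, n_p, _ = positions.shape
    r = int(np.ceil(_TRUNC_SIGMAS * cfg.blob_sigma))
    offs = np.arange(-r, r + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    oy, ox = oy.ravel(), ox.ravel()  # (K,)
    amp = cfg.intensity / (2.0 * np.pi * cfg.blob_sigma**2)
    inv2s2 = 1.0 / (2.0 * cfg.blob_sigma**2)
    frames = np.full((N, cfg.H, cfg.W), cfg.background, dtype=np.float64)
    for n in range(N):
        py, px = positions[n, :, 0], positions[n, :, 1]
        cy, cx = np.floor(py).astype(np.int64), np.floor(px).astype(np.int64)
        gy = (cy[:, None] + oy[None, :]) % cfg.H  # (n_p, K)
        gx = (cx[:, None] + ox[None, :]) % cfg.W
        dy = cy[:, None] + oy[None, :] - py[:, None]
        dx = cx[:, None] + ox[None, :] - px[:, None]
        w = amp * np.exp(-(dy**2 + dx**2) * inv2s2)
        np.add.at(frames[n], (gy.ravel(), gx.ravel()), w.ravel())
    return frames


def generate_brownian_series(cfg: BrownianConfig) -> tuple[ImageSeries, np.ndarray]:
    """Brownian-particle image series plus its latent trajectories.

    Particles start uniformly at random; every frame each advances by an
    independent Gaussian step of per-axis variance 2 * D_true * dt
    (converted to pixels), wrapping periodically. Returns the rendered
    :class:`ImageSeries` and the trajectories as an ``(N, n_particles,
    2)`` array of (row, col) pixel positions, so displacement-level
    checks need not re-infer positions from images.
    """
    rng = np.random.default_rng(cfg.seed)
    step_px = np.sqrt(2.0 * cfg.D_true * cfg.dt) / cfg.pixel_size
    start = rng.uniform(0.0, [cfg.H, cfg.W], size=(cfg.n_particles, 2))
    steps = rng.normal(0.0, step_px, size=(cfg.N - 1, cfg.n_particles, 2))
    positions = np.empty((cfg.N, cfg.n_particles, 2))
    positions[0] = start
    np.cumsum(steps, axis=0, out=positions[1:])
    positions[1:] += start[None]
    wrapped = np.mod(positions, [cfg.H, cfg.W])
    frames = _render_frames(wrapped, cfg)
    if cfg.noise_sigma > 0:
        frames += rng.normal(0.0, cfg.noise_sigma, size=frames.shape)
    series = ImageSeries(
        frames=frames, dt=cfg.dt, pixel_size=cfg.pixel_size, bit_depth=16
    )
    return series, positions


def generate_noise_series(
    N: int, H: int, W: int, sigma: float, seed: int,
    dt: float = 0.04, pixel_size: float = 1e-6,
) -> ImageSeries:
    """i.i.d. zero-mean Gaussian frames of standard deviation sigma."""
    if N < 2:
        raise InputError("need at least 2 frames")
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    frames = rng.normal(0.0, sigma, size=(N, H, W))
    return ImageSeries(frames=frames, dt=dt, pixel_size=pixel_size)
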