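"""Azimuthal averaging of structure functions onto wave-number rings.

For isotropic samples d(m, q) depends on the wave vector only through
its magnitude, so the half-plane matrix is collapsed onto rings of
constant |q|. Ring r collects the wave vectors with
``round(|q| / dq) == r`` where ``dq = 2*pi / (max(H, W) * pixel_size)``
is the finest grid spacing; each half-plane entry contributes with its
Hermitian multiplicity so the weighted half-plane mean equals the plain
full-plane mean. The q = 0 (DC) pixel is always excluded and empty
rings are dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .engines import StructureFunction
from .exceptions import InputError


@dataclass
class RadialStructure:
    """Ring-averaged structure function d(q, m*dt)."""

    q_centers: np.ndarray  # (R,) rad/m
    d_radial: np.ndarray  # (R, M)
    ring_counts: np.ndarray  # (R,) full-plane pixel counts
    lags: np.ndarray  # (M,) int
    dt: float

    @property
    def lag_times(self) -> np.ndarray:
        return self.lags * self.dt

    @property
    def n_rings(self) -> int:
        return self.q_centers.size

    def subset_lags(self, lags: np.ndarray) -> "RadialStructure":
        """Restrict to the given integer lags (all must be present)."""
        lags = np.asarray(lags)
        idx = np.isin(self.lags, lags)
        if idx.sum() != np.unique(lags).size:
            missing = np.setdiff1d(lags, self.lags)
            raise InputError(f"lags {missing.tolist()} not present")
        return RadialStructure(
            q_centers=self.q_centers, d_radial=self.d_radial[:, idx],
            ring_counts=self.ring_counts, lags=self.lags[idx], dt=self.dt,
        )


def ring_indices(grid) -> tuple[np.ndarray, float]:
    """Ring index of every half-plane wave vector and the ring spacing dq.

    Round-half-even rounding (numpy's default) breaks ties on exact
    half-integer |q|/dq deterministically.
    """
    dq = 2.0 * np.pi / (max(grid.H, grid.W) * grid.pixel_size)
    return np.rint(grid.q_magnitudes / dq).astype(np.int64), dq


def azimuthal_average(sf: StructureFunction) -> RadialStructure:
    """Multiplicity-weighted ring averages of a structure function."""
    grid = sf.grid
    if sf.d.shape[1:] != grid.q_magnitudes.shape:
        raise InputError(
            f"structure function {sf.d.shape[1:]} does not match its "
            f"grid {grid.q_magnitudes.shape}"
        )
    rings, dq = ring_indices(grid)
    flat_rings = rings.ravel()
    weights = grid.multiplicity.ravel().astype(np.float64)
    include = np.ones(flat_rings.size, dtype=bool)
    include[0] = False  # DC sits at flat index 0 of the half plane
    n_rings = int(flat_rings.max()) + 1

    w_sum = np.bincount(flat_rings[include], weights=weights[include], minlength=n_rings)
    occupied = w_sum > 0
    M = sf.lags.size
    d_radial = np.empty((int(occupied.sum()), M))
    for j in range(M):
        vals = sf.d[j].ravel().astype(np.float64)
        num = np.bincount(
            flat_rings[include], weights=(weights * vals)[include], minlength=n_rings
        )
        d_radial[:, j] = num[occupied] / w_sum[occupied]
    r_idx = np.nonzero(occupied)[0]
    return RadialStructure(
        q_centers=r_idx * dq,
        d_radial=d_radial,
        ring_counts=np.rint(w_sum[occupied]).astype(np.int64),
        lags=sf.lags.copy(),
        dt=sf.dt,
    )


def write_radial_csv(rad: RadialStructure, path: str | Path) -> Path:
    """Wide-format table: one row per ring, columns q then one per lag time."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["q_rad_per_m"] + [f"t={t:.9g}s" for t in rad.lag_times])
        for r in range(rad.n_rings):
            writer.writerow(
                [f"{rad.q_centers[r]:.9e}"]
                + [f"{v:.9e}" for v in rad.d_radial[r]]
            )
    return path
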