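"""Persistence of result containers.

Results are written to a small documented HDF5 layout; ring-averaged
and fit tables can additionally be exported as plain CSV with a
one-line header.

HDF5 layout (one object per file)::

    /               attrs: kind, version, dt
    kind "structure_function":
        d (L, H, W/2+1), lags (L,), pair_counts (L,)
        q_magnitudes, multiplicity (H, W/2+1)
        attrs: algorithm, H, W, pixel_size
    kind "radial_structure":
        q_centers (R,), d_radial (R, M), ring_counts (R,), lags (M,)
    kind "isf_fit":
        q, amplitude, baseline, tau, residual, converged (R,)
        attrs (optional): D, q_min, q_max
"""

from __future__ import annotations

import csv
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import h5py
import numpy as np

from .engines import StructureFunction
from .exceptions import InputError
from .fitting import IsfFit, write_fit_csv
from .radial import RadialStructure, write_radial_csv
from .spectra import WaveVectorGrid

try:
    __version__ = version("structurator")
except PackageNotFoundError:  # pragma: no cover - source tree without install
    __version__ = "0+unknown"


def _write_structure(f: h5py.File, sf: StructureFunction) -> None:
    f.attrs["kind"] = "structure_function"
    f.attrs["algorithm"] = sf.algorithm
    f.attrs["dt"] = sf.dt
    f.attrs["H"] = sf.grid.H
    f.attrs["W"] = sf.grid.W
    f.attrs["pixel_size"] = sf.grid.pixel_size
    f.create_dataset("d", data=sf.d)
    f.create_dataset("lags", data=sf.lags)
    f.create_dataset("pair_counts", data=sf.pair_counts)
    f.create_dataset("q_magnitudes", data=sf.grid.q_magnitudes)
    f.create_dataset("multiplicity", data=sf.grid.multiplicity)


def _write_radial(f: h5py.File, rad: RadialStructure) -> None:
    f.attrs["kind"] = "radial_structure"
    f.attrs["dt"] = rad.dt
    f.create_dataset("q_centers", data=rad.q_centers)
    f.create_dataset("d_radial", data=rad.d_radial)
    f.create_dataset("ring_counts", data=rad.ring_counts)
    f.create_dataset("lags", data=rad.lags)


def _write_fit(f: h5py.File, fit: IsfFit) -> None:
    f.attrs["kind"] = "isf_fit"
    f.attrs["dt"] = 0.0
    f.create_dataset("q", data=fit.q)
    f.create_dataset("amplitude", data=fit.amplitude)
    f.create_dataset("baseline", data=fit.baseline)
    f.create_dataset("tau", data=fit.tau)
    f.create_dataset("residual", data=fit.residual)
    f.create_dataset("converged", data=fit.converged)
    if fit.D is not None:
        f.attrs["D"] = fit.D
        f.attrs["q_min"], f.attrs["q_max"] = fit.q_range


def save_results(obj, path: str | Path) -> Path:
    """Write a result container; format chosen by suffix (.h5/.hdf5/.csv).

    CSV is available for :class:`RadialStructure` (long format,
    one (q, lag time, value) row per ring-lag pair) and
    :class:`IsfFit`; structure functions are HDF5-only.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if isinstance(obj, RadialStructure):
            times = obj.lag_times
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["q_rad_per_m", "lag_time_s", "d"])
                for r in range(obj.n_rings):
                    for j, t in enumerate(times):
                        writer.writerow(
                            [f"{obj.q_centers[r]:.9e}", f"{t:.9g}",
                             f"{obj.d_radial[r, j]:.9e}"]
                        )
            return path
        if isinstance(obj, IsfFit):
            return write_fit_csv(obj, path)
        raise InputError(f"CSV export not available for {type(obj).__name__}")
    try:
        f = h5py.File(path, "w")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    with f:
        f.attrs["version"] = __version__
        if isinstance(obj, StructureFunction):
            _write_structure(f, obj)
        elif isinstance(obj, RadialStructure):
            _write_radial(f, obj)
        elif isinstance(obj, IsfFit):
            _write_fit(f, obj)
        else:
            raise InputError(f"cannot save object of type {type(obj).__name__}")
    return path


def load_results(path: str | Path):
    """Read back any container written by :func:`save_results` (HDF5)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        if kind == "structure_function":
            H, W = int(f.attrs["H"]), int(f.attrs["W"])
            grid = WaveVectorGrid(
                H=H, W=W, pixel_size=float(f.attrs["pixel_size"]),
                q_magnitudes=f["q_magnitudes"][()],
                multiplicity=f["multiplicity"][()],
            )
            return StructureFunction(
                lags=f["lags"][()], d=f["d"][()],
                pair_counts=f["pair_counts"][()],
                dt=float(f.attrs["dt"]), grid=grid,
                algorithm=str(f.attrs["algorithm"]),
            )
        if kind == "radial_structure":
            return RadialStructure(
                q_centers=f["q_centers"][()], d_radial=f["d_radial"][()],
                ring_counts=f["ring_counts"][()], lags=f["lags"][()],
                dt=float(f.attrs["dt"]),
            )
        if kind == "isf_fit":
            fit = IsfFit(
                q=f["q"][()], amplitude=f["amplitude"][()],
                baseline=f["baseline"][()], tau=f["tau"][()],
                residual=f["residual"][()],
                converged=f["converged"][()].astype(bool),
            )
            if "D" in f.attrs:
                fit.D = float(f.attrs["D"])
                fit.q_range = (float(f.attrs["q_min"]), float(f.attrs["q_max"]))
            return fit
        raise InputError(f"unknown result kind {kind!r} in {path}")
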