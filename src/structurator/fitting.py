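"""Exponential ISF fits per ring and the diffusive-scaling fit.

For simple Brownian diffusion the intermediate scattering function is a
single exponential, f(q, t) = exp(-t / tau(q)), so the ring-averaged
structure function follows

    d(q, t) = A(q) * (1 - exp(-t / tau(q))) + B(q) ,

with amplitude A(q) set by the sample signal at that wave number and
baseline B(q) set by uncorrelated (camera) noise. Fitting this model on
each ring yields the decay time tau(q); in the diffusive regime
tau(q) = 1 / (D q^2), and a linear fit of 1/tau against q^2 through the
origin pools the rings into one diffusion coefficient D.

The zero lag carries no information (d(0) = 0 identically) and is never
part of the fit. Rings where the model cannot converge, or where the
curve is flat so tau is unidentifiable, are flagged rather than dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitError, InputError
from .radial import RadialStructure


@dataclass
class IsfFit:
    """Per-ring exponential-model parameters and the pooled diffusion fit."""

    q: np.ndarray  # (R,) rad/m
    amplitude: np.ndarray  # (R,) A(q), structure-function units
    baseline: np.ndarray  # (R,) B(q)
    tau: np.ndarray  # (R,) seconds; NaN when unidentifiable
    residual: np.ndarray  # (R,) L2 norm of fit residuals
    converged: np.ndarray  # (R,) bool
    D: float | None = None  # m^2/s, set by fit_diffusion
    q_range: tuple[float, float] | None = None

    @property
    def n_rings(self) -> int:
        return self.q.size


def _isf_model(t: np.ndarray, A: float, B: float, tau: float) -> np.ndarray:
    return A * (1.0 - np.exp(-t / tau)) + B


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    B0 = float(y.min())
    A0 = float(y.max() - y.min())
    tau0 = None
    if A0 > 0:
        level = B0 + (1.0 - np.exp(-1.0)) * A0
        above = np.nonzero(y >= level)[0]
        if above.size:
            tau0 = float(t[above[0]])
    if tau0 is None or tau0 <= 0:
        tau0 = float(t[t.size // 2])
    return A0, B0, tau0


def fit_isf(rad: RadialStructure, min_lags: int = 4) -> IsfFit:
    """Least-squares single-exponential fit of every ring.

    Uses lags m >= 1 only; requires at least ``min_lags`` of them (the
    model has three parameters). Bounds keep A >= 0 and tau > 0.
    Non-convergent or degenerate rings come back flagged with
    ``converged=False`` and ``tau=NaN``; no exception is raised for
    them.
    """
    pos = rad.lags >= 1
    if int(pos.sum()) < max(min_lags, 3):
        raise FitError(
            f"need at least {max(min_lags, 3)} lags with m >= 1, "
            f"got {int(pos.sum())}"
        )
    t = (rad.lags[pos] * rad.dt).astype(np.float64)
    R = rad.n_rings
    A = np.zeros(R)
    B = np.zeros(R)
    tau = np.full(R, np.nan)
    resid = np.full(R, np.nan)
    ok = np.zeros(R, dtype=bool)
    for r in range(R):
        y = rad.d_radial[r, pos].astype(np.float64)
        A0, B0, tau0 = _initial_guess(t, y)
        scale = max(abs(y).max(), 1.0)
        if A0 <= 1e-12 * scale:
            # flat curve: no decay to time, tau unidentifiable
            A[r], B[r] = 0.0, float(y.mean())
            resid[r] = float(np.linalg.norm(y - y.mean()))
            continue
        try:
            popt, _ = curve_fit(
                _isf_model, t, y,
                p0=[A0, B0, tau0],
                bounds=([0.0, -np.inf, np.finfo(float).tiny], np.inf),
                maxfev=10000,
            )
        except RuntimeError:
            A[r], B[r] = A0, B0
            continue
        A[r], B[r], tau[r] = popt
        resid[r] = float(np.linalg.norm(y - _isf_model(t, *popt)))
        ok[r] = np.isfinite(tau[r]) and tau[r] > 0
    return IsfFit(
        q=rad.q_centers.copy(), amplitude=A, baseline=B, tau=tau,
        residual=resid, converged=ok,
    )


def fit_diffusion(fit: IsfFit, q_min: float, q_max: float) -> float:
    """Diffusion coefficient from 1/tau = D q^2 on converged rings in range.

    Unweighted least squares through the origin,
    D = sum(q^2 / tau) / sum(q^4), which is linear in D and needs no
    iterative solver. The result is stored on ``fit`` (``D`` and
    ``q_range``) and returned.
    """
    if not q_min < q_max:
        raise InputError(f"empty q-range [{q_min}, {q_max}]")
    sel = fit.converged & (fit.q >= q_min) & (fit.q <= q_max)
    if int(sel.sum()) < 2:
        raise FitError(
            f"need >= 2 converged rings in [{q_min:.4g}, {q_max:.4g}] rad/m, "
            f"got {int(sel.sum())}"
        )
    q2 = fit.q[sel] ** 2
    rate = 1.0 / fit.tau[sel]
    D = float(np.dot(q2, rate) / np.dot(q2, q2))
    fit.D = D
    fit.q_range = (float(q_min), float(q_max))
    return D


def tau_scaling_exponent(fit: IsfFit, q_min: float, q_max: float) -> float:
    """Slope of log tau versus log q on converged rings in range.

    Diffusive dynamics give -2; deviations diagnose gravity-affected
    low-q rings or noise-dominated high-q rings.
    """
    sel = fit.converged & (fit.q >= q_min) & (fit.q <= q_max)
    if int(sel.sum()) < 2:
        raise FitError("need >= 2 converged rings for a scaling exponent")
    slope, _ = np.polyfit(np.log(fit.q[sel]), np.log(fit.tau[sel]), 1)
    return float(slope)


def measure_diffusion(
    series,
    q_min: float,
    q_max: float,
    n_fit_lags: int | None = 40,
    plan=None,
    precision: str = "double",
) -> tuple[float, IsfFit, RadialStructure]:
    """Full pipeline: frames -> d(q, t) -> ring fits -> diffusion coefficient.

    Runs the Wiener-Khinchin engine over all lags, ring-averages, fits
    the exponential ISF model per ring and pools converged rings in
    [q_min, q_max] into D. When ``n_fit_lags`` is set, the per-ring fits
    use a log-spaced sublist of that many lags: a full linear lag set
    piles most points onto the long-time plateau, whose correlated
    finite-sample wiggles then dominate the fit, while log spacing
    balances the leverage of the decay and the plateau.

    Returns ``(D, fit, radial)``.
    """
    from .engines import log_spaced_lags, structure_wk
    from .radial import azimuthal_average

    sf = structure_wk(series, plan=plan, precision=precision)
    rad = azimuthal_average(sf)
    rad_fit = rad
    if n_fit_lags is not None:
        N = int(sf.lags.max()) + 1
        rad_fit = rad.subset_lags(log_spaced_lags(N, n_fit_lags))
    fit = fit_isf(rad_fit)
    D = fit_diffusion(fit, q_min, q_max)
    return D, fit, rad


def write_fit_csv(fit: IsfFit, path: str | Path) -> Path:
    """Per-ring table (q, A, B, tau, residual, converged) with the pooled
    D and its q-range repeated on every row when present."""
    path = Path(path)
    has_d = fit.D is not None
    header = ["q_rad_per_m", "A", "B", "tau_s", "residual", "converged"]
    if has_d:
        header += ["D_m2_per_s", "q_min", "q_max"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in range(fit.n_rings):
            row = [
                f"{fit.q[r]:.9e}", f"{fit.amplitude[r]:.9e}",
                f"{fit.baseline[r]:.9e}", f"{fit.tau[r]:.9e}",
                f"{fit.residual[r]:.9e}", int(fit.converged[r]),
            ]
            if has_d:
                row += [
                    f"{fit.D:.9e}", f"{fit.q_range[0]:.9e}", f"{fit.q_range[1]:.9e}",
                ]
            writer.writerow(row)
    return path
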