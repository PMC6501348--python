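"""Equilibrium summary statistics of dimer trajectories.

Estimators for the three benchmark quantities: the mean dimer length L_d
(time average with a batch-means confidence interval), the centre-of-mass
velocity autocorrelation function C_d(tau) (time-averaged over all
overlapping origins), and the diffusion constant D_d — via the Green-Kubo
integral of the VACF, via the mean-squared-displacement slope, or via a
nonlinear fit of the Langevin form (D*gamma/2) exp(-gamma*tau) which
recovers D and gamma simultaneously.

Estimators are pure functions of trajectories: re-running them on a saved
trajectory reproduces the statistics bit for bit.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats

from .model_core import Trajectory

__all__ = [
    "VacfEstimate",
    "MeanLengthResult",
    "estimate_vacf",
    "diffusion_from_vacf",
    "diffusion_from_trajectory",
    "diffusion_from_msd",
    "estimate_mean_length",
    "fit_exponential_vacf",
]


class DataError(ValueError):
    """The trajectory is too short for the requested estimate."""


@dataclasses.dataclass
class VacfEstimate:
    """Velocity autocorrelation estimate on a uniform lag grid."""

    lags: np.ndarray
    values: np.ndarray
    n_samples: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_samples = np.asarray(self.n_samples)
        if self.lags[0] != 0.0:
            raise ValueError("lag grid must start at 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VACF values must be finite")


@dataclasses.dataclass
class MeanLengthResult:
    value: float
    ci_low: float
    ci_high: float
    se: float
    confidence: float


def _select(traj: Trajectory, burn_in: float) -> np.ndarray:
    mask = traj.times >= traj.times[0] + burn_in
    if mask.sum() < 4:
        raise DataError("trajectory too short after burn-in")
    return mask


def _autocorr_sums(x: np.ndarray, max_k: int) -> np.ndarray:
    """sum_t x_t x_{t+k} for k = 0..max_k via FFT (columns summed)."""
    n = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    F = np.fft.rfft(x, n=nfft, axis=0)
    S = np.fft.irfft((F * F.conj()).real.sum(axis=1), n=nfft)
    return S[: max_k + 1]


def estimate_vacf(traj: Trajectory, max_lag: Optional[float] = None,
                  burn_in: float = 0.0) -> VacfEstimate:
    """Time-averaged VACF (1/3) <Vbar(t+tau) . Vbar(t)> over all overlapping
    origins after burn-in; the lag grid is the trajectory sampling interval."""
    mask = _select(traj, burn_in)
    V = traj.Vbar[mask]
    h = traj.sample_interval
    n = len(V)
    if max_lag is None:
        max_lag = 0.25 * (n - 1) * h
    K = int(round(max_lag / h))
    if K >= n:
        raise DataError(
            f"max_lag {max_lag} exceeds the post-burn-in span {(n - 1) * h}")
    sums = _autocorr_sums(V, K)
    counts = n - np.arange(K + 1)
    return VacfEstimate(lags=np.arange(K + 1) * h,
                        values=sums / counts / 3.0,
                        n_samples=counts)


def diffusion_from_vacf(vacf: VacfEstimate, upper: float) -> float:
    """Green-Kubo estimate: trapezoidal integral of the VACF over
    [0, upper]."""
    h = vacf.lags[1] - vacf.lags[0] if len(vacf.lags) > 1 else 0.0
    if upper > vacf.lags[-1] + 0.5 * h:
        raise DataError("integration limit exceeds the available lags")
    m = vacf.lags <= upper + 0.5 * h
    return float(np.trapezoid(vacf.values[m], vacf.lags[m]))


def diffusion_from_trajectory(traj: Trajectory, upper: float = 1.0,
                              burn_in: float = 0.0,
                              n_batches: int = 5) -> Tuple[float, float]:
    """VACF-integral diffusion estimate with a batch standard error.

    The post-burn-in trajectory is cut into n_batches contiguous segments;
    each yields an independent Green-Kubo estimate. Returns (mean, se).
    """
    mask = _select(traj, burn_in)
    idx = np.flatnonzero(mask)
    h = traj.sample_interval
    seg = len(idx) // n_batches
    if seg * h <= upper * 1.5:
        raise DataError("batches too short for the requested upper limit")
    vals = []
    for b in range(n_batches):
        sl = idx[b * seg:(b + 1) * seg]
        sub = Trajectory(times=traj.times[sl], Xbar=traj.Xbar[sl],
                         Vbar=traj.Vbar[sl], R=traj.R[sl])
        vals.append(diffusion_from_vacf(estimate_vacf(sub, max_lag=upper),
                                        upper))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_batches))


def _msd(X: np.ndarray, max_k: int) -> np.ndarray:
    """Mean-squared displacement over lags 0..max_k (FFT algorithm)."""
    n = X.shape[0]
    D = (X ** 2).sum(axis=1)
    S2 = _autocorr_sums(X, max_k)
    counts = n - np.arange(max_k + 1)
    # S1[k] = sum_{t} (D[t] + D[t+k]) over valid origins
    c = np.concatenate(([0.0], np.cumsum(D)))
    tail = c[n] - c[np.arange(max_k + 1)]        # sum D[k:]
    head = c[n - np.arange(max_k + 1)]           # sum D[:n-k]
    return (tail + head - 2.0 * S2) / counts


def diffusion_from_msd(traj: Trajectory, burn_in: float = 0.0,
                       fit_range: Optional[Tuple[float, float]] = None
                       ) -> float:
    """Diffusion constant from the least-squares slope of the MSD against
    6*tau over the diffusive regime (default lag window: 0.5% to 5% of the
    post-burn-in span, where many independent origins contribute). Warns
    when the window looks ballistic (slope still growing)."""
    mask = _select(traj, burn_in)
    X = traj.Xbar[mask]
    h = traj.sample_interval
    span = (len(X) - 1) * h
    if fit_range is None:
        fit_range = (0.005 * span, 0.05 * span)
    k_lo = max(1, int(round(fit_range[0] / h)))
    k_hi = int(round(fit_range[1] / h))
    if k_hi <= k_lo + 1:
        raise DataError("MSD fit window too narrow")
    msd = _msd(X, k_hi)
    lags = np.arange(k_hi + 1) * h
    sl = slice(k_lo, k_hi + 1)
    slope, _ = np.polyfit(lags[sl], msd[sl], 1)
    # non-diffusive diagnostic: compare local slopes in the two window halves
    mid = (k_lo + k_hi) // 2
    s1, _ = np.polyfit(lags[k_lo:mid + 1], msd[k_lo:mid + 1], 1)
    s2, _ = np.polyfit(lags[mid:k_hi + 1], msd[mid:k_hi + 1], 1)
    if s1 > 0 and s2 / s1 > 1.5:
        warnings.warn(
            "MSD slope grows across the fit window: the trajectory does not "
            "look diffusive on these lags", stacklevel=2)
    return float(slope / 6.0)


def estimate_mean_length(traj: Trajectory, burn_in: float = 0.0,
                         confidence: float = 0.99,
                         n_batches: int = 20) -> MeanLengthResult:
    """Post-burn-in time average of the dimer length with a two-sided
    batch-means confidence interval (autocorrelation-aware)."""
    mask = _select(traj, burn_in)
    R = traj.R[mask]
    nb = min(n_batches, len(R))
    seg = len(R) // nb
    means = R[: nb * seg].reshape(nb, seg).mean(axis=1)
    value = float(R.mean())
    se = float(means.std(ddof=1) / np.sqrt(nb))
    if se == 0.0:
        return MeanLengthResult(value, value, value, 0.0, confidence)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, nb - 1)
    return MeanLengthResult(value, value - tcrit * se, value + tcrit * se,
                            se, confidence)


def fit_exponential_vacf(vacf: VacfEstimate,
                         max_lag: Optional[float] = None
                         ) -> Tuple[float, float]:
    """Nonlinear least-squares fit of (D*gamma/2) exp(-gamma*tau) to the
    VACF; returns (D_hat, gamma_hat).

    The fit window runs to max_lag, or to the first non-positive VACF value
    if that comes sooner (the model is positive).
    """
    lags = vacf.lags
    vals = vacf.values
    if vals[0] <= 0:
        raise RuntimeError("VACF is non-positive at lag 0; nothing to fit")
    nonpos = np.flatnonzero(vals <= 0)
    hi = nonpos[0] if len(nonpos) else len(vals)
    if max_lag is not None:
        hi = min(hi, int(np.searchsorted(lags, max_lag, side="right")))
    lags = lags[:hi]
    vals = vals[:hi]
    if len(lags) < 3:
        raise RuntimeError("fewer than 3 usable VACF points")
    c0 = vals[0]
    below = np.flatnonzero(vals < c0 / math.e)
    g0 = 1.0 / lags[below[0]] if len(below) and lags[below[0]] > 0 else \
        1.0 / lags[-1]
    d0 = 2.0 * c0 / g0

    def model(tau, D, g):
        return 0.5 * D * g * np.exp(-g * tau)

    try:
        popt, _ = optimize.curve_fit(model, lags, vals, p0=(d0, g0),
                                     maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"exponential VACF fit did not converge (p0=({d0:.3g}, "
            f"{g0:.3g}), {len(lags)} points): {exc}") from exc
    return float(popt[0]), float(popt[1])
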