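"""Mean-square-displacement estimators and anomalous-scaling fits.

Three averaging modes are provided:

* time-averaged MSD of a single track over a measurement window ``T``,
* ensemble MSD over many tracks at fixed clock times,
* MSD reconstructed from empirical step-count probabilities
  ``χ̂_n(t)`` — the fraction of tracks that completed exactly ``n`` steps by
  time ``t`` — combined with the per-step spatial law ``r̄²_n``.

For ergodic (Brownian) motion the time and ensemble averages agree; for a
heavy-tailed CTRW they do not — per-track time averages stay random even as
the measurement time grows, which is the operational fingerprint of broken
ergodicity.

Scaling exponents are estimated by ordinary least squares of ``log MSD``
on ``log t``; the fit window by default discards the first and last
half-decade of available abscissa, where transients and poor statistics
bias the slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .walks import Trajectory

__all__ = [
    "MSDCurve",
    "ScalingFit",
    "log_grid",
    "time_averaged_msd",
    "ensemble_msd",
    "fit_scaling",
    "step_count_fractions",
    "msd_from_step_counts",
]


def log_grid(a: float, b: float, per_decade: int = 25) -> np.ndarray:
    """Logarithmically spaced abscissa, ``per_decade`` points per decade."""
    if not 0 < a < b:
        raise ValueError("need 0 < a < b")
    n_dec = np.log10(b / a)
    n = max(int(round(n_dec * per_decade)), 1) + 1
    return np.logspace(np.log10(a), np.log10(b), n)


@dataclass
class MSDCurve:
    """MSD values on a time/lag abscissa (units ℓ₀² vs simulation time)."""

    abscissa: np.ndarray
    values: np.ndarray
    averaging: str = "ensemble"  # time | ensemble | sub_ensemble
    n_tracks: int = 1
    T: Optional[float] = None

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.abscissa.shape != self.values.shape:
            raise ValueError("abscissa/values shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("MSD values must be non-negative")


@dataclass
class ScalingFit:
    """Power-law fit ``MSD(t) = prefactor · t^exponent`` (log-log OLS)."""

    exponent: float
    prefactor: float
    window: tuple[float, float]
    r_squared: float
    stderr: float = float("nan")


def time_averaged_msd(
    traj: Trajectory,
    lags: Sequence[float],
    T: Optional[float] = None,
    n_origins: int = 512,
) -> MSDCurve:
    """Time-averaged MSD of one track.

    For each lag Δ the squared displacement ``|r(t+Δ) − r(t)|²`` is averaged
    over ``n_origins`` evenly spaced origins ``t ∈ [0, T−Δ]``, with the
    trajectory piecewise constant between events (CTRW convention).
    """
    lags = np.asarray(lags, dtype=float)
    if T is None:
        T = traj.duration
    if T > traj.duration:
        raise ValueError("measurement time T exceeds the trajectory duration")
    if np.any(lags >= T):
        raise ValueError("lags must be smaller than the measurement time T")
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative")
    vals = np.empty_like(lags)
    for j, lag in enumerate(lags):
        t0 = np.linspace(0.0, T - lag, n_origins)
        d = traj.positions_at(t0 + lag) - traj.positions_at(t0)
        vals[j] = np.mean((d * d).sum(axis=-1))
    return MSDCurve(lags, vals, averaging="time", n_tracks=1, T=float(T))


def ensemble_msd(trajs: Sequence[Trajectory], times: Sequence[float]) -> MSDCurve:
    """Ensemble MSD: mean over tracks of ``|r(t) − r(0)|²``."""
    if len(trajs) == 0:
        raise ValueError("empty track set")
    times = np.asarray(times, dtype=float)
    acc = np.zeros_like(times)
    for tr in trajs:
        d = tr.positions_at(times) - tr.positions[0]
        acc += (d * d).sum(axis=-1)
    return MSDCurve(times, acc / len(trajs), averaging="ensemble", n_tracks=len(trajs))


def _default_window(abscissa: np.ndarray) -> tuple[float, float]:
    """Drop the first and last half-decade of the available abscissa."""
    lo, hi = abscissa[abscissa > 0].min(), abscissa.max()
    return lo * np.sqrt(10.0), hi / np.sqrt(10.0)


def fit_scaling(
    curve: MSDCurve, window: Optional[tuple[float, float]] = None
) -> ScalingFit:
    """OLS of ``log MSD`` on ``log t`` over a window: slope = exponent,
    ``exp(intercept)`` = prefactor."""
    if window is None:
        window = _default_window(curve.abscissa)
    lo, hi = window
    sel = (curve.abscissa >= lo) & (curve.abscissa <= hi)
    t = curve.abscissa[sel]
    v = curve.values[sel]
    if len(t) < 5:
        raise ValueError(f"need ≥ 5 points in the fit window, got {len(t)}")
    if np.any(v <= 0):
        raise ValueError("MSD values in the fit window must be positive")
    x = np.log(t)
    y = np.log(v)
    xc = x - x.mean()
    sxx = xc @ xc
    slope = (xc @ y) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = max(len(t) - 2, 1)
    stderr = float(np.sqrt(ss_res / dof / sxx))
    return ScalingFit(
        exponent=float(slope),
        prefactor=float(np.exp(intercept)),
        window=(float(lo), float(hi)),
        r_squared=float(r2),
        stderr=stderr,
    )


def step_count_fractions(
    trajs: Sequence[Trajectory], times: Sequence[float]
) -> np.ndarray:
    """Empirical ``χ̂_n(t)``: fraction of tracks with exactly ``n`` completed
    steps by each time.  Returns an array of shape ``(n_max+1, len(times))``
    whose columns sum to one."""
    times = np.asarray(times, dtype=float)
    counts = np.empty((len(trajs), len(times)), dtype=np.int64)
    for i, tr in enumerate(trajs):
        if times.max() > tr.duration:
            raise ValueError("requested times beyond the simulated horizon")
        counts[i] = np.searchsorted(tr.times, times, side="right") - 1
    n_max = int(counts.max())
    chi = np.zeros((n_max + 1, len(times)))
    for j in range(len(times)):
        chi[:, j] = np.bincount(counts[:, j], minlength=n_max + 1) / len(trajs)
    return chi


def msd_from_step_counts(
    trajs: Sequence[Trajectory],
    support_msd_per_step: Sequence[float],
    times: Sequence[float],
) -> MSDCurve:
    """MSD via the step-count decomposition ``⟨r²(t)⟩ = Σ_n r̄²_n χ̂_n(t)``.

    ``support_msd_per_step`` is the spatial law ``r̄²_n`` (index = step
    count), e.g. the ensemble MSD of a constant-time walk on the same
    support; ``χ̂_n(t)`` is estimated from the tracks' event times.
    """
    times = np.asarray(times, dtype=float)
    chi = step_count_fractions(trajs, times)
    r2n = np.asarray(support_msd_per_step, dtype=float)
    if len(r2n) < chi.shape[0]:
        raise ValueError(
            f"spatial law covers {len(r2n)} step counts but tracks completed "
            f"up to {chi.shape[0] - 1} steps"
        )
    vals = r2n[: chi.shape[0]] @ chi
    return MSDCurve(times, vals, averaging="ensemble", n_tracks=len(trajs))
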