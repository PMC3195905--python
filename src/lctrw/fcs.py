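"""Anomalous-diffusion FCS: the auto/cross-correlation model and the
time-dependent diffusion quantities.

The normalized correlation for anomalous diffusion with exponent γ̃ in a
Gaussian observation volume of structural factor ``s = z₀/ω_xy`` reads

    G(τ) = (1/N)·[1 + (τ/τ_D)^γ̃]^{-1}·[1 + (1/s²)(τ/τ_D)^γ̃]^{-(dim-2)/2} + 1

so that G(0) − 1 = 1/N (N: mean molecule number in ΔV, which may be < 1 at
the single-molecule level).  For γ̃ = 1 and dim = 3 this is the classical
one-component FCS form; for dim = 2 the axial factor drops out.

The MSD prefactor Γ_γ̃ℓ (units: length²/time^γ̃) defines the apparent
diffusion coefficient D_app(t) = Γ_γ̃ℓ/(2·dim)·t^{γ̃−1}, the instantaneous
coefficient D_inst = γ̃·D_app, and the diffusion time
τ_D = [ω_xy²·(2·dim)/(4·m·Γ_γ̃ℓ)]^{1/γ̃} — the fixed point of
τ = ω_xy²/(4·m·D_app(τ)); ``m`` is the photon order (1 or 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FCSParams",
    "CorrelationCurve",
    "FCSFitResult",
    "correlation_model",
    "d_app",
    "d_inst",
    "diffusion_time",
    "fit_correlation",
]


@dataclass
class FCSParams:
    """Parameter bundle for the anomalous-diffusion correlation model."""

    N: float
    tau_D: float
    gamma: float = 1.0
    s: float = 5.0
    dim: int = 3
    m: int = 1
    omega_xy: Optional[float] = None
    z0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("mean molecule number N must be positive")
        if self.tau_D <= 0:
            raise ValueError("diffusion time τ_D must be positive")
        if self.s <= 0:
            raise ValueError("structural factor s must be positive")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.m not in (1, 2):
            raise ValueError("photon order m must be 1 or 2")
        if self.gamma <= 0:
            raise ValueError("anomaly exponent γ̃ must be positive")
        if self.omega_xy is not None and self.z0 is not None:
            s_geom = self.z0 / self.omega_xy
            if not np.isclose(s_geom, self.s, rtol=1e-9):
                raise ValueError(
                    f"s = {self.s} inconsistent with z₀/ω_xy = {s_geom}"
                )


@dataclass
class CorrelationCurve:
    """Correlation values G(τ) on a positive, increasing lag axis."""

    lags: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.shape != self.G.shape:
            raise ValueError("lag/G shape mismatch")
        if np.any(self.lags < 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be non-negative and increasing")


def correlation_model(tau, p: FCSParams) -> np.ndarray:
    """Evaluate G(τ) for the anomalous-diffusion model."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("correlation lags must be ≥ 0")
    x = (tau / p.tau_D) ** p.gamma
    G = (1.0 / p.N) / (1.0 + x)
    if p.dim == 3:
        G = G / np.sqrt(1.0 + x / p.s**2)
    return G + 1.0


def d_app(t, gamma: float, prefactor: float, dim: int = 3) -> np.ndarray:
    """Apparent diffusion coefficient D_app(t) = Γ_γ̃ℓ/(2·dim)·t^{γ̃−1},
    defined so that MSD(t) = 2·dim·D_app(t)·t = Γ_γ̃ℓ·t^γ̃."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be positive")
    return prefactor / (2.0 * dim) * t ** (gamma - 1.0)


def d_inst(t, gamma: float, prefactor: float, dim: int = 3) -> np.ndarray:
    """Instantaneous coefficient (1/(2·dim))·d⟨r²⟩/dt = γ̃·D_app(t)."""
    return gamma * d_app(t, gamma, prefactor, dim)


def diffusion_time(
    omega_xy: float, m: int, prefactor: float, gamma: float, dim: int = 3
) -> float:
    """Diffusion time τ_D = [ω_xy²·(2·dim)/(4·m·Γ_γ̃ℓ)]^{1/γ̃}.

    This is the fixed point of τ = ω_xy²/(4·m·D_app(τ)); the identity is
    asserted internally.
    """
    if omega_xy <= 0 or prefactor <= 0 or m not in (1, 2):
        raise ValueError("geometry, prefactor and photon order must be valid")
    if gamma <= 0:
        raise ValueError("anomaly exponent γ̃ must be positive")
    tau = (omega_xy**2 * 2.0 * dim / (4.0 * m * prefactor)) ** (1.0 / gamma)
    fixed_point = omega_xy**2 / (4.0 * m * float(d_app(tau, gamma, prefactor, dim)))
    assert abs(tau - fixed_point) <= 1e-10 * tau
    return float(tau)


@dataclass
class FCSFitResult:
    """Nonlinear least-squares fit of (N, τ_D, γ̃) to a correlation curve."""

    params: FCSParams
    success: bool
    message: str
    residuals: np.ndarray
    covariance: Optional[np.ndarray]

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)


def fit_correlation(
    curve: CorrelationCurve,
    dim: int = 3,
    s: float = 5.0,
    fix_gamma: Optional[float] = None,
    x0: Optional[tuple[float, float, float]] = None,
    gamma_bounds: tuple[float, float] = (0.05, 1.5),
) -> FCSFitResult:
    """Fit (N, τ_D, γ̃) with ``s`` and ``dim`` held fixed.

    N and τ_D are fitted in log-space (positivity); γ̃ is box-bounded.
    Non-convergence is reported through ``success``/``message`` with the
    best iterate retained.
    """
    sel = curve.lags > 0
    lags = curve.lags[sel]
    G = curve.G[sel]
    if len(lags) < 10:
        raise ValueError("need ≥ 10 positive-lag points for a stable fit")
    amp0 = max(float(G[0] - 1.0), 1e-6)
    N0, tau0, g0 = x0 if x0 is not None else (
        1.0 / amp0,
        float(np.sqrt(lags[0] * lags[-1])),
        0.8,
    )

    def unpack(x):
        N = np.exp(x[0])
        tau_D = np.exp(x[1])
        gamma = fix_gamma if fix_gamma is not None else x[2]
        return N, tau_D, gamma

    def resid(x):
        N, tau_D, gamma = unpack(x)
        p = FCSParams(N=N, tau_D=tau_D, gamma=gamma, s=s, dim=dim)
        return correlation_model(lags, p) - G

    if fix_gamma is None:
        x_init = np.array([np.log(N0), np.log(tau0), g0])
        lb = np.array([-np.inf, -np.inf, gamma_bounds[0]])
        ub = np.array([np.inf, np.inf, gamma_bounds[1]])
    else:
        x_init = np.array([np.log(N0), np.log(tau0)])
        lb = np.array([-np.inf, -np.inf])
        ub = np.array([np.inf, np.inf])
    sol = least_squares(resid, x_init, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
    N, tau_D, gamma = unpack(sol.x)
    params = FCSParams(N=N, tau_D=tau_D, gamma=gamma, s=s, dim=dim)
    cov = None
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(len(lags) - len(sol.x), 1)
        cov = np.linalg.inv(jtj) * (sol.fun @ sol.fun) / dof
    except np.linalg.LinAlgError:
        pass
    return FCSFitResult(
        params=params,
        success=bool(sol.success),
        message=str(sol.message),
        residuals=sol.fun,
        covariance=cov,
    )
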