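"""Weibull model of cumulative exposure to interaction sites.

The fraction of interaction exposure accumulated below scale ``r`` is
modeled as a Weibull law ``m(<r)/m_total = 1 − exp[−(r/r_max)^q]`` with
``r_max`` the geometric size of the cell or nucleus and integer shape
``q > 0``.  For small ``r`` the Maclaurin truncation reduces it to the
power law ``(r/r_max)^q``, whose density on [0, r_max] has closed-form
moments:

    r̄    = q/(q+1)·r_max          (mean interaction size)
    σ_r² = q/[(q+2)(q+1)²]·r_max²  (variance)

``r̄²`` is the geometric upper limit of the MSD used by the limited CTRW
(the default cap radius handed to the walker is r̄, so the simulated MSD
plateaus at ``msd_cap = r̄²``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExposureModel",
    "weibull_cumulative",
    "weibull_survival",
    "densities",
    "moments",
    "size_from_volume",
]


@dataclass(frozen=True)
class ExposureModel:
    """Exposure model parameters: maximum size ``r_max`` (length units, e.g.
    metres) and positive integer shape ``q``."""

    r_max: float
    q: int = 2

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.q <= 0 or self.q != int(self.q):
            raise ValueError("shape q must be a positive integer")

    @property
    def mean_size(self) -> float:
        return self.q / (self.q + 1) * self.r_max

    @property
    def variance(self) -> float:
        return self.q / ((self.q + 2) * (self.q + 1) ** 2) * self.r_max**2

    @property
    def msd_cap(self) -> float:
        """Upper limiting value of the MSD: ``r̄²``."""
        return self.mean_size**2


def weibull_cumulative(r, model: ExposureModel) -> np.ndarray:
    """Cumulative exposure fraction ``m(<r)/m_total = 1 − exp[−(r/r_max)^q]``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("size r must be ≥ 0")
    return 1.0 - np.exp(-((r / model.r_max) ** model.q))


def weibull_survival(r, model: ExposureModel) -> np.ndarray:
    """Complement ``m(>r)/m_total = exp[−(r/r_max)^q]``."""
    return 1.0 - weibull_cumulative(r, model)


def densities(r, model: ExposureModel) -> tuple[np.ndarray, np.ndarray]:
    """Probability densities ``(f_Weibull, f_power_law)`` at ``r``.

    ``f_Weibull(r) = q·r^{q−1}/r_max^q · exp[−(r/r_max)^q]`` on [0, ∞);
    ``f_power_law(r) = q·r^{q−1}/r_max^q`` on [0, r_max] (0 beyond).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("size r must be ≥ 0")
    base = model.q * r ** (model.q - 1) / model.r_max**model.q
    f_weibull = base * np.exp(-((r / model.r_max) ** model.q))
    f_power = np.where(r <= model.r_max, base, 0.0)
    return f_weibull, f_power


def moments(model: ExposureModel) -> tuple[float, float, float]:
    """Closed-form moments of the power-law size density on [0, r_max]:
    ``(r̄, σ_r², msd_cap = r̄²)``."""
    return model.mean_size, model.variance, model.msd_cap


def size_from_volume(volume: float) -> float:
    """Linear dimension as the cube root of a volume (unit proportionality
    constant; units follow from the input)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return float(volume) ** (1.0 / 3.0)
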