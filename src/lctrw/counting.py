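"""Single-molecule Poisson counting statistics for a confocal volume.

With bulk molar concentration ``c_m`` and observation volume ``ΔV`` the
mean occupancy is ``C = c_m·N_A·ΔV``; molecule counts in ΔV are Poisson
with mean C.  The single-molecule regime requires the probability
``N = P(X=1) = C·e^{−C}`` to stay below one molecule on average (C < 1);
above the cutoff concentration ``c* = 1/(N_A·ΔV)`` aliasing terms (two,
three, … molecules at once) contaminate the fluctuation signal.

The *meaningful time* ``T_m = (τ_D/C)·e^{−C}`` is the expected duration
over which one and the same molecule can be observed before it is replaced
by an exchange with the bulk; over a measurement of length T the budget of
distinct single molecules of the same kind is ``N_ℓmax = T/T_m``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import poisson

__all__ = [
    "AVOGADRO",
    "CountingConfig",
    "expected_count",
    "poisson_count_prob",
    "single_molecule_prob",
    "single_molecule_cutoff",
    "meaningful_time",
    "track_budget",
]

# 2019 SI exact value, mol^-1.
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class CountingConfig:
    """Concentration / volume / timing bundle for the counting calculators.

    Units: ``c_m`` mol/L, ``dV`` L, ``tau_D`` s, ``T`` s.
    """

    c_m: float
    dV: float
    tau_D: float
    T: float

    def __post_init__(self) -> None:
        for name in ("c_m", "dV", "tau_D", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def expected_count(self) -> float:
        return expected_count(self.c_m, self.dV)

    @property
    def single_molecule_prob(self) -> float:
        return single_molecule_prob(self.expected_count)

    @property
    def cutoff(self) -> float:
        return single_molecule_cutoff(self.dV)

    @property
    def meaningful_time(self) -> float:
        return meaningful_time(self.tau_D, self.c_m, self.dV)

    @property
    def track_budget(self) -> float:
        return track_budget(self.T, self.meaningful_time)


def expected_count(c_m: float, dV: float) -> float:
    """Mean occupancy ``C = c_m·N_A·ΔV`` (dimensionless)."""
    if c_m <= 0 or dV <= 0:
        raise ValueError("concentration and volume must be positive")
    return c_m * AVOGADRO * dV


def poisson_count_prob(x: int, C: float) -> float:
    """Poisson probability ``C^x·e^{−C}/x!`` of observing x molecules."""
    if x < 0 or x != int(x):
        raise ValueError("molecule count x must be a non-negative integer")
    if C < 0:
        raise ValueError("mean occupancy C must be ≥ 0")
    return float(poisson.pmf(int(x), C))


def single_molecule_prob(C: float) -> float:
    """``N = P(X=1) = C·e^{−C}``; for C ≪ e^{−C}, N ≈ C."""
    return poisson_count_prob(1, C)


def single_molecule_cutoff(dV: float) -> float:
    """Concentration ``c* = 1/(N_A·ΔV)`` at which C = 1 (mol/L).

    Above c* the mean occupancy exceeds one molecule and the N < 1
    single-molecule condition is violated (aliasing regime).
    """
    if dV <= 0:
        raise ValueError("observation volume must be positive")
    return 1.0 / (AVOGADRO * dV)


def meaningful_time(tau_D: float, c_m: float, dV: float) -> float:
    """Meaningful observation time ``T_m = (τ_D/C)·e^{−C}`` (seconds)."""
    if tau_D <= 0:
        raise ValueError("diffusion time must be positive")
    C = expected_count(c_m, dV)
    if C >= 1.0:
        warnings.warn(
            f"mean occupancy C = {C:.3g} ≥ 1: outside the single-molecule "
            "regime; T_m loses its one-molecule interpretation",
            stacklevel=2,
        )
    return tau_D / C * math.exp(-C)


def track_budget(T: float, T_m: float) -> float:
    """Number of distinct single molecules recorded over T: ``N_ℓmax = T/T_m``.

    Returned as a real number; ``int(...)`` gives the floor count.
    """
    if T <= 0 or T_m <= 0:
        raise ValueError("measurement and meaningful times must be positive")
    return T / T_m
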