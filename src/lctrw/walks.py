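"""Random-walk generators: Brownian tracks, blind-ant walks on fractal
supports (RWF), continuous-time random walks (CTRW) with heavy-tailed
waiting times, and limited CTRWs (LCTRW).

All walkers live on the integer lattice with unit step length ℓ₀ = 1 and
use the *blind ant* rule: at every tick a uniformly random neighbor is
proposed; if the proposal is inaccessible (deleted cell, bounding box, or
the LCTRW displacement cap) the walker stays put, but the tick — and for
CTRWs the waiting time — is consumed.

A CTRW draws an independent waiting time before every step attempt.  The
default waiting-time law is the inverse-gamma density
``ψ(t) = e^{−1/t} t^{−(1+γ)} / Γ(γ)`` with 0 < γ ≤ 1, whose first moment is
infinite: ensemble subdiffusion with exponent γ and broken ergodicity on
all time scales.  The LCTRW additionally caps the Euclidean displacement
from the start at ``r_max`` (the geometric size of the cell or nucleus) and
refuses configurations violating the single-molecule occupancy condition
N < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol

import numpy as np

from .fractal import FractalSupport

__all__ = [
    "WaitingTimeModel",
    "InverseGammaWaitingTimes",
    "FixedWaitingTimes",
    "Trajectory",
    "SingleMoleculeConditionError",
    "sample_waiting_times",
    "brownian_track",
    "rwf_walk",
    "ctrw_walk",
    "lctrw_walk",
    "brownian_ensemble",
    "rwf_ensemble",
    "ctrw_ensemble",
    "lctrw_ensemble",
]


class SingleMoleculeConditionError(ValueError):
    """Raised when a configuration implies N ≥ 1 molecules in ΔV."""


class WaitingTimeModel(Protocol):
    """Pluggable waiting-time law: anything with a ``sample`` method."""

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray: ...


@dataclass(frozen=True)
class InverseGammaWaitingTimes:
    """Inverse-gamma waiting times, shape ``γ ∈ (0, 1]``, unit scale.

    Sampled as the reciprocal of Gamma(γ, 1) draws; the survival function
    decays as ``t^{−γ}``, so the mean waiting time is infinite for γ ≤ 1.
    """

    gamma: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"γ must lie in (0, 1], got {self.gamma}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.scale / rng.gamma(self.gamma, size=n)


@dataclass(frozen=True)
class FixedWaitingTimes:
    """Degenerate (deterministic) waiting times; the γ → CTRW-free limit."""

    dt: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, self.dt)


def sample_waiting_times(model: WaitingTimeModel, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. waiting times from ``model``."""
    if n < 1:
        raise ValueError("need at least one waiting time")
    rng = np.random.default_rng(seed)
    return model.sample(n, rng)


@dataclass
class Trajectory:
    """Timestamped lattice positions of one simulated molecule.

    ``times`` is strictly increasing with ``t₀ = 0``; ``positions`` has one
    row per event.  Between events the molecule sits on the last visited
    site (right-continuous step function).  Consecutive positions differ by
    one unit step or are equal (a blocked blind-ant attempt).
    """

    times: np.ndarray
    positions: np.ndarray
    kind: str = "brownian"
    gamma: float = 1.0
    support: Optional[FractalSupport] = None
    seed: Optional[int] = None
    r_max: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions))
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions length mismatch")
        if len(self.times) and self.times[0] != 0.0:
            raise ValueError("trajectories start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def positions_at(self, t: np.ndarray) -> np.ndarray:
        """Positions at arbitrary times (piecewise-constant CTRW convention)."""
        t = np.asarray(t, dtype=float)
        tol = 1e-9 * max(self.duration, 1.0)  # grid round-off at the horizon
        if np.any(t < 0) or np.any(t > self.duration + tol):
            raise ValueError("requested times outside the simulated horizon")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.positions[np.minimum(idx, len(self.positions) - 1)]


def _directions(dim: int) -> np.ndarray:
    """The 2·dim signed unit basis steps."""
    eye = np.eye(dim, dtype=np.int64)
    return np.concatenate([eye, -eye])


def brownian_track(n: int, dim: int = 3, seed=None) -> Trajectory:
    """Free lattice walk: ``n`` i.i.d. unit steps, one per unit time."""
    if n < 0:
        raise ValueError("step count must be ≥ 0")
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    rng = np.random.default_rng(seed)
    dirs = _directions(dim)
    if n == 0:
        pos = np.zeros((1, dim), dtype=np.int64)
        return Trajectory(np.array([0.0]), pos, kind="brownian", seed=seed)
    choices = rng.integers(0, 2 * dim, size=n)
    steps = dirs[choices]
    positions = np.vstack([np.zeros((1, dim), np.int64), np.cumsum(steps, axis=0)])
    times = np.arange(n + 1, dtype=float)
    return Trajectory(times, positions, kind="brownian", seed=seed)


def _blind_ant_path(
    support: FractalSupport,
    n: int,
    start: np.ndarray,
    rng: np.random.Generator,
    r_max: Optional[float] = None,
) -> np.ndarray:
    """Single blind-ant path: returns (n+1, dim) positions including start."""
    start = np.asarray(start, dtype=np.int64)
    if not support.accessible(start)[0]:
        raise ValueError(f"start site {tuple(start)} is not accessible")
    dirs = _directions(support.dim)
    choices = rng.integers(0, 2 * support.dim, size=n)
    path = np.empty((n + 1, support.dim), dtype=np.int64)
    path[0] = start
    pos = start.copy()
    cap2 = None if r_max is None or np.isinf(r_max) else float(r_max) ** 2
    side = support.side
    for i in range(n):
        cand = pos + dirs[choices[i]]
        ok = bool(((cand >= 0) & (cand < side)).all())
        if ok and cap2 is not None:
            d = cand - start
            ok = float(d @ d) <= cap2
        if ok:
            ok = bool(support.accessible(cand)[0])
        if ok:
            pos = cand
        path[i + 1] = pos
    return path


def rwf_walk(support: FractalSupport, n: int, start, seed=None) -> Trajectory:
    """Blind-ant random walk on a fractal support, unit time per tick."""
    if n < 1:
        raise ValueError("step count must be ≥ 1")
    rng = np.random.default_rng(seed)
    path = _blind_ant_path(support, n, np.asarray(start), rng)
    return Trajectory(
        np.arange(n + 1, dtype=float), path, kind="rwf", support=support, seed=seed
    )


def _check_occupancy(dV_config) -> None:
    """Enforce the single-molecule condition N < 1 on an LCTRW setup."""
    if dV_config is None:
        return
    from .counting import CountingConfig  # local import avoids cycle

    if isinstance(dV_config, CountingConfig):
        C = dV_config.expected_count
    else:
        C = float(dV_config)
    if C >= 1.0:
        raise SingleMoleculeConditionError(
            f"mean occupancy C = {C:.3g} ≥ 1 violates the single-molecule "
            "condition N < 1 (aliasing: two or more molecules in ΔV)"
        )


def lctrw_walk(
    support: FractalSupport,
    model: WaitingTimeModel,
    T: float,
    start,
    seed=None,
    r_max: float = np.inf,
    dV_config=None,
) -> Trajectory:
    """Limited CTRW: blind-ant CTRW with a displacement cap.

    Steps that would carry the molecule beyond Euclidean distance ``r_max``
    from its start are rejected (the tick and waiting time are consumed),
    so the MSD can never exceed ``r_max²``.  If ``dV_config`` (a mean
    occupancy C or a :class:`~lctrw.counting.CountingConfig`) implies
    N ≥ 1 molecules in the observation volume, the configuration is refused.
    """
    if T <= 0:
        raise ValueError("total time T must be positive")
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    _check_occupancy(dV_config)
    rng = np.random.default_rng(seed)
    start = np.asarray(start, dtype=np.int64)
    if not support.accessible(start)[0]:
        raise ValueError(f"start site {tuple(start)} is not accessible")
    dirs = _directions(support.dim)
    cap2 = None if np.isinf(r_max) else float(r_max) ** 2
    side = support.side

    times = [0.0]
    path = [start.copy()]
    pos = start.copy()
    t = 0.0
    # Waiting times are drawn in blocks to amortize generator calls while
    # keeping the draw order identical to one-at-a-time sampling.
    block: np.ndarray = np.empty(0)
    bi = 0
    while True:
        if bi >= len(block):
            block = model.sample(256, rng)
            bi = 0
        wait = float(block[bi])
        bi += 1
        t += wait
        if t > T:
            break
        cand = pos + dirs[int(rng.integers(0, 2 * support.dim))]
        ok = bool(((cand >= 0) & (cand < side)).all())
        if ok and cap2 is not None:
            d = cand - start
            ok = float(d @ d) <= cap2
        if ok:
            ok = bool(support.accessible(cand)[0])
        if ok:
            pos = cand
        times.append(t)
        path.append(pos.copy())
    kind = "lctrw" if cap2 is not None else "ctrw"
    return Trajectory(
        np.array(times),
        np.array(path),
        kind=kind,
        gamma=getattr(model, "gamma", 1.0),
        support=support,
        seed=seed,
        r_max=None if cap2 is None else float(r_max),
    )


def ctrw_walk(
    support: FractalSupport, model: WaitingTimeModel, T: float, start, seed=None
) -> Trajectory:
    """Blind-ant CTRW: each step attempt is preceded by a random waiting
    time; the simulation stops at the first event time exceeding ``T``."""
    return lctrw_walk(support, model, T, start, seed=seed, r_max=np.inf)


# ---------------------------------------------------------------------------
# Vectorized ensembles.  These run many walkers in lock-step with numpy and
# are the workhorses for MSD/exponent estimation; the per-trajectory
# functions above remain the reference implementation (cross-checked in the
# test suite).
# ---------------------------------------------------------------------------


def brownian_ensemble(
    n_steps: int, dim: int, n_walkers: int, seed=None
) -> list[Trajectory]:
    """``n_walkers`` independent free lattice walks of ``n_steps`` steps."""
    rng = np.random.default_rng(seed)
    dirs = _directions(dim)
    choices = rng.integers(0, 2 * dim, size=(n_walkers, n_steps))
    steps = dirs[choices]
    paths = np.concatenate(
        [np.zeros((n_walkers, 1, dim), np.int64), np.cumsum(steps, axis=1)], axis=1
    )
    times = np.arange(n_steps + 1, dtype=float)
    return [Trajectory(times, p, kind="brownian", seed=seed) for p in paths]


def _blind_ant_paths(
    support: FractalSupport,
    n_steps: int,
    n_walkers: int,
    start: Optional[np.ndarray],
    rng: np.random.Generator,
    r_max: Optional[float] = None,
) -> np.ndarray:
    """Lock-step blind-ant ensemble: (n_walkers, n_steps+1, dim) positions.

    ``start`` may be one site (shared), an ``(n_walkers, dim)`` array, or
    ``None`` for uniformly random accessible start sites (translation
    averaging over the support — the natural ensemble for exponent
    estimation on a fractal).
    """
    from .fractal import random_accessible_sites

    if start is None:
        starts = random_accessible_sites(support, n_walkers, rng)
    else:
        start = np.asarray(start, dtype=np.int64)
        starts = np.atleast_2d(start)
        if not support.accessible(starts).all():
            raise ValueError("start site is not accessible")
        if len(starts) == 1:
            starts = np.tile(starts[0], (n_walkers, 1))
        elif len(starts) != n_walkers:
            raise ValueError("need one start site per walker")
    dirs = _directions(support.dim)
    cap2 = None if r_max is None or np.isinf(r_max) else float(r_max) ** 2
    side = support.side
    pos = starts.copy()
    paths = np.empty((n_walkers, n_steps + 1, support.dim), dtype=np.int64)
    paths[:, 0] = pos
    for i in range(n_steps):
        cand = pos + dirs[rng.integers(0, 2 * support.dim, size=n_walkers)]
        ok = ((cand >= 0) & (cand < side)).all(axis=1)
        if cap2 is not None:
            d = cand - starts
            ok &= (d * d).sum(axis=1) <= cap2
        if ok.any():
            ok[ok] = support.accessible(cand[ok])
        pos = np.where(ok[:, None], cand, pos)
        paths[:, i + 1] = pos
    return paths


def rwf_ensemble(
    support: FractalSupport, n_steps: int, n_walkers: int, start=None, seed=None
) -> list[Trajectory]:
    """Ensemble of blind-ant walks on a support, unit time per tick."""
    rng = np.random.default_rng(seed)
    paths = _blind_ant_paths(support, n_steps, n_walkers, start, rng)
    times = np.arange(n_steps + 1, dtype=float)
    return [
        Trajectory(times, p, kind="rwf", support=support, seed=seed) for p in paths
    ]


def ctrw_ensemble(
    support: FractalSupport,
    model: WaitingTimeModel,
    n_steps: int,
    n_walkers: int,
    start=None,
    seed=None,
    r_max: float = np.inf,
) -> list[Trajectory]:
    """CTRW/LCTRW ensemble with a fixed step budget per walker.

    The spatial part is a blind-ant ensemble; event times are independent
    cumulative sums of waiting-time draws (the CTRW subordination).  The
    usable common horizon is the smallest per-walker final event time.
    """
    rng = np.random.default_rng(seed)
    paths = _blind_ant_paths(
        support, n_steps, n_walkers, start, rng, r_max=r_max
    )
    waits = model.sample(n_steps * n_walkers, rng).reshape(n_walkers, n_steps)
    times = np.concatenate(
        [np.zeros((n_walkers, 1)), np.cumsum(waits, axis=1)], axis=1
    )
    kind = "ctrw" if np.isinf(r_max) else "lctrw"
    gamma = getattr(model, "gamma", 1.0)
    return [
        Trajectory(
            t,
            p,
            kind=kind,
            gamma=gamma,
            support=support,
            seed=seed,
            r_max=None if np.isinf(r_max) else float(r_max),
        )
        for t, p in zip(times, paths)
    ]


def lctrw_ensemble(
    support: FractalSupport,
    model: WaitingTimeModel,
    n_steps: int,
    n_walkers: int,
    start,
    r_max: float,
    seed=None,
    dV_config=None,
) -> list[Trajectory]:
    """Limited-CTRW ensemble (displacement cap + occupancy condition)."""
    _check_occupancy(dV_config)
    return ctrw_ensemble(
        support, model, n_steps, n_walkers, start, seed=seed, r_max=r_max
    )
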