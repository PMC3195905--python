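"""Shared fixtures: supports and simulation ensembles reused across tests.

The ensembles are the study conditions for the statistical checks
(exponent fits, ergodicity-breaking diagnostics): 500 walkers, 10⁴ ticks
for constant-time walks and 3000 steps for CTRWs, analyzed on log-spaced
grids.  All seeds are fixed.
"""

import numpy as np
import pytest

from lctrw.fractal import FractalSupport, full_mask, standard_carpet_mask
from lctrw.msd import log_grid
from lctrw.walks import InverseGammaWaitingTimes, ctrw_ensemble, rwf_ensemble


@pytest.fixture(scope="session")
def carpet6() -> FractalSupport:
    """Standard 3×3 carpet iterated to stage 6 (side 729)."""
    return FractalSupport(standard_carpet_mask(), k_max=6)


@pytest.fixture(scope="session")
def full_lattice() -> FractalSupport:
    """Unobstructed 2-D lattice, side 3^7 = 2187."""
    return FractalSupport(full_mask(3, 2), k_max=7)


@pytest.fixture(scope="session")
def rwf_carpet_trajs(carpet6):
    """500 blind-ant walks of 10⁴ ticks on the stage-6 carpet (random
    accessible starts)."""
    return rwf_ensemble(carpet6, n_steps=10_000, n_walkers=500, seed=42)


@pytest.fixture(scope="session")
def ctrw_full_trajs(full_lattice):
    """500 CTRW tracks, γ = 0.5, on the full lattice (3000 steps each)."""
    model = InverseGammaWaitingTimes(0.5)
    start = (full_lattice.side // 2,) * 2
    return ctrw_ensemble(full_lattice, model, 3000, 500, start, seed=7)


@pytest.fixture(scope="session")
def ctrw_carpet_trajs(carpet6):
    """500 CTRW tracks, γ = 0.5, on the stage-6 carpet."""
    model = InverseGammaWaitingTimes(0.5)
    return ctrw_ensemble(carpet6, model, 3000, 500, None, seed=8)


@pytest.fixture(scope="session")
def msd_times():
    """Log-spaced clock times for ensemble MSD curves, [1, 10⁶]."""
    return log_grid(1.0, 1e6, 25)


def group_exponent_se(trajs, times, window, n_groups=10):
    """Scaling exponent and its standard error from disjoint track groups."""
    from lctrw.msd import ensemble_msd, fit_scaling

    exps = [
        fit_scaling(ensemble_msd(trajs[i::n_groups], times), window=window).exponent
        for i in range(n_groups)
    ]
    return float(np.mean(exps)), float(np.std(exps, ddof=1) / np.sqrt(n_groups))
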