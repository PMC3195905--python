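"""Walk generators: Brownian, blind-ant on fractals, CTRW, limited CTRW."""

import numpy as np
import pytest
from scipy import stats

from lctrw.fractal import FractalSupport, GeneratorMask, full_mask, standard_carpet_mask
from lctrw.msd import ensemble_msd, fit_scaling, log_grid, time_averaged_msd
from lctrw.walks import (
    FixedWaitingTimes,
    InverseGammaWaitingTimes,
    SingleMoleculeConditionError,
    brownian_ensemble,
    brownian_track,
    ctrw_ensemble,
    ctrw_walk,
    lctrw_walk,
    rwf_ensemble,
    rwf_walk,
    sample_waiting_times,
)


class TestBrownian:
    def test_zero_steps_is_a_point(self):
        traj = brownian_track(0, dim=3, seed=0)
        assert len(traj.times) == 1
        assert np.all(traj.positions == 0)

    def test_unit_steps_and_unit_times(self):
        traj = brownian_track(500, dim=2, seed=1)
        steps = np.abs(np.diff(traj.positions, axis=0)).sum(axis=1)
        assert np.all(steps == 1)
        assert np.array_equal(traj.times, np.arange(501))

    def test_ensemble_msd_matches_step_count(self):
        # ⟨r²(n)⟩ = n·ℓ₀² exactly for orthogonal unit steps
        trajs = brownian_ensemble(1000, 3, 1000, seed=2)
        n_check = np.array([10.0, 100.0, 1000.0])
        curve = ensemble_msd(trajs, n_check)
        # Var(r²) per track ≈ 2n(n+2)/3 − n² in 3-D; use a generous 3·SE band
        for n, v in zip(n_check, curve.values):
            se = np.sqrt((2 * n * (n + 2) / 3 - n**2 / 3)) / np.sqrt(1000)
            assert abs(v - n) < 3 * max(se, 1.0)

    def test_direction_frequencies_uniform(self):
        traj = brownian_track(60_000, dim=3, seed=3)
        steps = np.diff(traj.positions, axis=0)
        dirs, counts = np.unique(steps, axis=0, return_counts=True)
        assert len(dirs) == 6
        # binomial CI: p = 1/6, n = 60000 → 4σ ≈ 0.006
        freqs = counts / 60_000
        assert np.all(np.abs(freqs - 1 / 6) < 4 * np.sqrt((1 / 6) * (5 / 6) / 60_000))

    def test_rejects_negative_step_count(self):
        with pytest.raises(ValueError):
            brownian_track(-1, dim=2)


class TestRWF:
    def test_full_lattice_recovers_normal_diffusion(self, full_lattice):
        trajs = rwf_ensemble(full_lattice, 2000, 500, seed=11)
        times = log_grid(1, 2000, 25)
        fit = fit_scaling(ensemble_msd(trajs, times), window=(5, 2000))
        assert abs(fit.exponent - 1.0) < 0.05

    def test_isolated_site_constant_trajectory(self):
        # center cell kept but all four neighbors deleted
        allowed = np.zeros((3, 3), dtype=bool)
        allowed[1, 1] = True
        for corner in [(0, 0), (0, 2), (2, 0), (2, 2)]:
            allowed[corner] = True
        support = FractalSupport(GeneratorMask(nu=3, allowed=allowed), k_max=1)
        traj = rwf_walk(support, 50, (1, 1), seed=4)
        assert np.all(traj.positions == [1, 1])

    def test_inaccessible_start_rejected(self):
        support = FractalSupport(standard_carpet_mask(), k_max=1)
        with pytest.raises(ValueError, match="not accessible"):
            rwf_walk(support, 10, (1, 1), seed=0)

    def test_carpet_walk_is_subdiffusive(self, rwf_carpet_trajs):
        times = log_grid(1, 1e4, 25)
        fit = fit_scaling(ensemble_msd(rwf_carpet_trajs, times), window=(10, 1e4))
        assert fit.exponent < 1.0

    def test_every_visited_site_accessible(self, carpet6):
        traj = rwf_walk(carpet6, 300, (0, 0), seed=5)
        assert carpet6.accessible(traj.positions).all()

    def test_single_and_ensemble_walkers_agree_statistically(self, carpet6):
        # the loop and lock-step implementations sample the same process
        n = 200
        singles = [rwf_walk(carpet6, 300, (0, 0), seed=100 + i) for i in range(n)]
        batch = rwf_ensemble(carpet6, 300, n, (0, 0), seed=999)
        r2_single = np.array(
            [((tr.positions[-1] - tr.positions[0]) ** 2).sum() for tr in singles]
        )
        r2_batch = np.array(
            [((tr.positions[-1] - tr.positions[0]) ** 2).sum() for tr in batch]
        )
        diff = r2_single.mean() - r2_batch.mean()
        se = np.sqrt(r2_single.var(ddof=1) / n + r2_batch.var(ddof=1) / n)
        assert abs(diff) < 3 * se


class TestWaitingTimes:
    def test_gamma_one_median(self):
        # CDF e^{−1/t} = 1/2 at t = 1/ln 2
        draws = sample_waiting_times(InverseGammaWaitingTimes(1.0), 40_000, seed=6)
        med = np.median(draws)
        assert abs(med - 1 / np.log(2)) < 0.03

    def test_density_normalizes(self):
        from scipy.integrate import quad
        from scipy.special import gamma as gamma_fn

        for g in (0.3, 0.689, 1.0):
            val, _ = quad(
                lambda t: np.exp(-1 / t) * t ** (-(1 + g)) / gamma_fn(g), 0, np.inf
            )
            assert abs(val - 1) < 1e-8

    def test_matches_inverse_gamma_law(self):
        draws = sample_waiting_times(InverseGammaWaitingTimes(0.5), 5000, seed=7)
        ks = stats.kstest(draws, stats.invgamma(a=0.5).cdf)
        assert ks.pvalue > 0.01

    def test_heavy_tail_slope(self):
        # empirical survival ∝ t^{−γ} at large t
        g = 0.6
        draws = sample_waiting_times(InverseGammaWaitingTimes(g), 200_000, seed=8)
        qs = np.quantile(draws, [0.95, 0.99, 0.999])
        surv = np.array([0.05, 0.01, 0.001])
        slope = np.polyfit(np.log(qs), np.log(surv), 1)[0]
        assert abs(slope + g) < 0.05

    def test_sample_means_diverge(self):
        # infinite first moment: the sample mean grows with the sample size
        model = InverseGammaWaitingTimes(0.5)
        small = sample_waiting_times(model, 500, seed=9).mean()
        large = sample_waiting_times(model, 500_000, seed=9).mean()
        assert large > 10 * small

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            InverseGammaWaitingTimes(1.5)
        with pytest.raises(ValueError):
            InverseGammaWaitingTimes(0.0)


class TestCTRW:
    def test_reproducible_events(self, full_lattice):
        model = InverseGammaWaitingTimes(0.5)
        start = (full_lattice.side // 2,) * 2
        a = ctrw_walk(full_lattice, model, 200.0, start, seed=10)
        b = ctrw_walk(full_lattice, model, 200.0, start, seed=10)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.positions, b.positions)

    def test_stops_at_horizon(self, full_lattice):
        model = InverseGammaWaitingTimes(0.7)
        start = (full_lattice.side // 2,) * 2
        traj = ctrw_walk(full_lattice, model, 50.0, start, seed=11)
        assert traj.duration <= 50.0

    def test_degenerate_waits_recover_brownian_law(self, full_lattice):
        start = (full_lattice.side // 2,) * 2
        trajs = ctrw_ensemble(
            full_lattice, FixedWaitingTimes(1.0), 400, 400, start, seed=12
        )
        assert np.array_equal(trajs[0].times, np.arange(401))
        curve = ensemble_msd(trajs, np.array([400.0]))
        se = 400 / np.sqrt(400)
        assert abs(curve.values[0] - 400.0) < 3 * se

    def test_subdiffusive_exponent_half(self, ctrw_full_trajs, msd_times):
        fit = fit_scaling(ensemble_msd(ctrw_full_trajs, msd_times), window=(1e2, 1e6))
        assert abs(fit.exponent - 0.5) < 0.07

    def test_nonergodic_amplitude_scatter(self, ctrw_full_trajs):
        # per-track time-averaged MSD amplitudes stay broad: broken ergodicity
        amps = np.array(
            [
                time_averaged_msd(tr, [10.0], T=1e4, n_origins=256).values[0]
                for tr in ctrw_full_trajs[:200]
            ]
        )
        cv = amps.std() / amps.mean()
        assert cv > 0.3

    def test_ergodic_brownian_amplitudes_concentrate(self):
        trajs = brownian_ensemble(10_000, 2, 100, seed=13)
        amps = np.array(
            [
                time_averaged_msd(tr, [10.0], T=1e4, n_origins=256).values[0]
                for tr in trajs
            ]
        )
        assert amps.std() / amps.mean() < 0.15


class TestLCTRW:
    def test_infinite_cap_identical_to_ctrw(self, full_lattice):
        model = InverseGammaWaitingTimes(0.6)
        start = (full_lattice.side // 2,) * 2
        a = ctrw_walk(full_lattice, model, 300.0, start, seed=14)
        b = lctrw_walk(full_lattice, model, 300.0, start, seed=14, r_max=np.inf)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.positions, b.positions)

    def test_unit_cap_bounds_msd(self, full_lattice):
        model = InverseGammaWaitingTimes(0.8)
        start = (full_lattice.side // 2,) * 2
        traj = lctrw_walk(full_lattice, model, 500.0, start, seed=15, r_max=1.0)
        disp = traj.positions - traj.positions[0]
        assert np.max((disp**2).sum(axis=1)) <= 1.0

    def test_time_averaged_msd_plateaus_at_cap(self, full_lattice):
        r_max = 10.0
        model = InverseGammaWaitingTimes(0.8)
        start = (full_lattice.side // 2,) * 2
        trajs = ctrw_ensemble(
            full_lattice, model, 2000, 50, start, seed=16, r_max=r_max
        )
        for tr in trajs[:10]:
            ta = time_averaged_msd(tr, [tr.duration / 10], n_origins=128)
            assert np.all(ta.values <= r_max**2)

    def test_occupancy_condition_enforced(self, full_lattice):
        from lctrw.counting import CountingConfig

        model = InverseGammaWaitingTimes(0.5)
        start = (full_lattice.side // 2,) * 2
        bad = CountingConfig(c_m=2e-8, dV=0.14e-15, tau_D=1e-3, T=1.0)  # C ≈ 1.7
        with pytest.raises(SingleMoleculeConditionError, match="N < 1"):
            lctrw_walk(
                full_lattice, model, 10.0, start, seed=17, r_max=5.0, dV_config=bad
            )
        ok = CountingConfig(c_m=5e-9, dV=0.14e-15, tau_D=1e-3, T=1.0)  # C ≈ 0.42
        traj = lctrw_walk(
            full_lattice, model, 10.0, start, seed=17, r_max=5.0, dV_config=ok
        )
        assert traj.kind == "lctrw"


def test_decoupling_of_spatial_and_temporal_exponents(
    rwf_carpet_trajs, ctrw_full_trajs, ctrw_carpet_trajs, msd_times
):
    """Exponent(CTRW on fractal) ≈ α·γ: spatial crowding and temporal
    trapping contribute multiplicatively."""
    from conftest import group_exponent_se

    alpha, se_a = group_exponent_se(
        rwf_carpet_trajs, log_grid(1, 1e4, 25), window=(10, 1e4)
    )
    g_t, se_t = group_exponent_se(ctrw_full_trajs, msd_times, window=(1e2, 1e6))
    g_f, se_f = group_exponent_se(ctrw_carpet_trajs, msd_times, window=(1e2, 1e6))
    combined_se = np.sqrt(
        (alpha * se_t) ** 2 + (g_t * se_a) ** 2 + se_f**2
    )
    assert abs(g_f - alpha * g_t) < 3 * combined_se
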