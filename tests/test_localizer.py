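import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from minsted import (
    LocalizerConfig,
    Schedule,
    StaticEmitter,
    UnbindingEmitter,
    epsf,
    position_estimate,
    ramp_schedule,
    run_localization,
    sample_photon,
    update_center,
)

from conftest import make_trace


class TestRampSchedule:
    def test_confocal_start(self, schedule, optics):
        E, F, R = schedule.at(1)
        assert E == 0.0
        assert F == optics.fwhm_conf
        assert R == optics.fwhm_conf / 2

    def test_gamma_value(self, schedule):
        assert schedule.gamma == pytest.approx((24.0 / 250.0) ** (1 / 79), rel=1e-6)

    def test_endpoint(self, schedule):
        for i in (80, 81, 200):
            E, F, R = schedule.at(i)
            assert E == pytest.approx(1.0, abs=1e-6)
            assert F == pytest.approx(24.0, abs=0.02)
            assert R == pytest.approx(12.0, abs=0.01)
        assert schedule.n_c == 80

    def test_radius_floor_invariant(self, schedule):
        cfg = schedule.cfg
        for i in range(1, 120):
            _, F, R = schedule.at(i)
            assert R == pytest.approx(max(cfg.r_min, cfg.r_over_fwhm * F), abs=1e-9)

    def test_energy_monotone(self, schedule):
        assert np.all(np.diff(schedule.energies) >= -1e-12)

    def test_ramp_schedule_function(self, optics):
        cfg = LocalizerConfig()
        E, F, R = ramp_schedule(1, cfg, optics)
        assert (E, F, R) == (0.0, optics.fwhm_conf, optics.fwhm_conf / 2)
        with pytest.raises(ValueError):
            ramp_schedule(0, cfg, optics)


class TestUpdateCenter:
    def test_shift_along_x(self):
        assert update_center((0.0, 0.0), 12.0, 0.0, alpha=0.15) == pytest.approx(
            (1.8, 0.0)
        )

    def test_shift_along_y(self):
        nx, ny = update_center((0.0, 0.0), 12.0, math.pi / 2, alpha=0.15)
        assert (nx, ny) == pytest.approx((0.0, 1.8), abs=1e-12)

    def test_alpha_zero_identity(self):
        assert update_center((3.0, -2.0), 12.0, 1.0, alpha=0.0) == pytest.approx(
            (3.0, -2.0)
        )

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            update_center((0.0, 0.0), 0.0, 0.0)


class TestSamplePhoton:
    def test_centered_emitter_uniform(self, optics, rng):
        cfg = LocalizerConfig()
        phis = np.array(
            [
                sample_photon((0, 0), (0, 0), 12.0, 1.0, cfg, optics, rng,
                              sbr=np.inf)[0]
                for _ in range(10_000)
            ]
        )
        stat, p = stats.kstest(phis / (2 * np.pi), "uniform")
        assert p > 0.001

    def test_displaced_emitter_mean_cos(self, optics, rng):
        cfg = LocalizerConfig()
        R, E, dx = 12.0, 1.0, 5.0
        n = 40_000
        samples = np.array(
            [
                sample_photon((dx, 0), (0, 0), R, E, cfg, optics, rng,
                              sbr=np.inf)[0]
                for _ in range(n)
            ]
        )
        # quadrature oracle for E[cos phi] of the stated density
        phi = np.linspace(0, 2 * np.pi, 20_001)[:-1]
        w = epsf(np.hypot(dx - R * np.cos(phi), -R * np.sin(phi)), E, optics)
        expected = float(np.sum(np.cos(phi) * w) / np.sum(w))
        se = np.std(np.cos(samples)) / math.sqrt(n)
        assert expected > 0
        assert np.mean(np.cos(samples)) == pytest.approx(expected, abs=3 * se)

    def test_background_probability_half(self, optics, rng):
        cfg = LocalizerConfig()
        flags = [
            sample_photon((0, 0), (0, 0), 12.0, 1.0, cfg, optics, rng, sbr=1.0)[1]
            for _ in range(5000)
        ]
        assert np.mean(flags) == pytest.approx(0.5, abs=0.03)

    def test_invalid_radius(self, optics, rng):
        with pytest.raises(ValueError):
            sample_photon((0, 0), (0, 0), 0.0, 1.0, LocalizerConfig(), optics, rng)


class TestRunLocalization:
    def test_unbiased_for_static_emitter(self, optics, quiet_schedule):
        cfg = replace(quiet_schedule.cfg, max_photons=400)
        ests = []
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            tr = run_localization(
                StaticEmitter((0.0, 0.0)), cfg, optics, rng,
                start=(20.0, -10.0), schedule=quiet_schedule,
            )
            ests.append(position_estimate(tr, tr.L))
        ests = np.array(ests)
        se = ests.std(axis=0, ddof=1) / math.sqrt(len(ests))
        assert abs(ests[:, 0].mean()) < 3 * se[0] + 1e-9
        assert abs(ests[:, 1].mean()) < 3 * se[1] + 1e-9

    def test_schedule_frozen_after_nc(self, optics, schedule, rng):
        cfg = replace(schedule.cfg, max_photons=300)
        tr = run_localization(
            StaticEmitter((0.0, 0.0)), cfg, optics, rng, start=(5.0, 5.0),
            schedule=schedule,
        )
        assert tr.n_c == 80
        assert np.all(tr.radii[tr.n_c - 1 :] == pytest.approx(12.0, abs=0.01))
        assert np.all(tr.energies[tr.n_c - 1 :] == pytest.approx(1.0, abs=1e-6))

    def test_unbind_terminates_within_window(self, optics, quiet_schedule):
        cfg = replace(quiet_schedule.cfg, max_photons=None, max_duration_ms=None)
        t_unbind = 5.0
        for s in range(5):
            rng = np.random.default_rng(s)
            tr = run_localization(
                UnbindingEmitter((0.0, 0.0), t_unbind_ms=t_unbind),
                cfg, optics, rng, start=(0.0, 0.0), schedule=quiet_schedule,
            )
            assert tr.end_time_ms <= t_unbind + 1.5 * cfg.term_window_ms
            assert tr.times_ms[-1] <= t_unbind + 1e-9

    def test_not_initiated_flag(self, optics, quiet_schedule):
        cfg = replace(quiet_schedule.cfg, max_photons=None, max_duration_ms=None)
        rng = np.random.default_rng(0)
        tr = run_localization(
            UnbindingEmitter((0.0, 0.0), t_unbind_ms=0.3),
            cfg, optics, rng, start=(0.0, 0.0), schedule=quiet_schedule,
        )
        assert tr.L < cfg.n_on
        assert not tr.initiated
        assert not tr.converged

    def test_duration_cap(self, optics, schedule):
        cfg = replace(schedule.cfg, max_photons=None, max_duration_ms=10.0)
        rng = np.random.default_rng(2)
        tr = run_localization(
            StaticEmitter((0.0, 0.0)), cfg, optics, rng, start=(0.0, 0.0),
            schedule=schedule,
        )
        assert tr.end_time_ms == 10.0
        assert tr.times_ms[-1] <= 10.0


@pytest.fixture(scope="module")
def steady_trace(optics, quiet_schedule):
    cfg = replace(quiet_schedule.cfg, max_photons=4079)
    rng = np.random.default_rng(77)
    return run_localization(
        StaticEmitter((0.0, 0.0)), cfg, optics, rng, start=(10.0, 0.0),
        schedule=quiet_schedule,
    )


class TestSteadyState:
    def test_centers_track_emitter(self, steady_trace):
        # scan-edge condition: the centers hug the emitter after burn-in
        post = steady_trace.post_centers()
        dist = np.hypot(post[:, 0], post[:, 1])
        assert np.mean(dist) < 12.0 / 2  # well inside the scan radius

    def test_ar1_autocorrelation_time(self, steady_trace):
        x = steady_trace.post_centers()[:, 0]
        x = x - x.mean()
        rho = float(np.sum(x[1:] * x[:-1]) / np.sum(x[:-1] ** 2))
        assert 0.0 < rho < 1.0
        tau = -1.0 / math.log(rho)
        alpha = 0.15
        assert 0.3 / alpha < tau < 3.0 / alpha

    def test_spread_monotone_in_alpha(self, optics):
        spreads = []
        for alpha in (0.05, 0.15, 0.3):
            cfg = LocalizerConfig(
                alpha=alpha, max_duration_ms=None, max_photons=2579
            )
            sch = Schedule(cfg, optics)
            sch.sbrs = np.full_like(sch.sbrs, np.inf)
            rng = np.random.default_rng(5)
            tr = run_localization(
                StaticEmitter((0.0, 0.0)), cfg, optics, rng,
                start=(0.0, 0.0), schedule=sch,
            )
            post = tr.post_centers()[500:]
            spreads.append(float(post.std(axis=0).mean()))
        assert spreads[0] < spreads[1] < spreads[2]


class TestPositionEstimate:
    def test_constant_centers(self):
        tr = make_trace(np.full((10, 2), 3.5), n_c=2)
        assert position_estimate(tr, 10) == pytest.approx((3.5, 3.5))

    def test_arithmetic_mean(self):
        xs = np.arange(1, 101, dtype=float)
        tr = make_trace(np.column_stack([xs, np.zeros(100)]), n_c=80)
        assert position_estimate(tr, 100)[0] == pytest.approx(90.0)

    def test_before_nc_returns_raw_center(self):
        xs = np.arange(1, 101, dtype=float)
        tr = make_trace(np.column_stack([xs, xs]), n_c=80)
        assert position_estimate(tr, 50) == pytest.approx((50.0, 50.0))

    def test_running_sum_oracle(self, rng):
        centers = rng.normal(0, 3, size=(200, 2))
        tr = make_trace(centers, n_c=30)
        for N in (30, 57, 200):
            sx = sy = 0.0
            cnt = 0
            for i in range(30, N + 1):  # independently coded running sum
                sx += centers[i - 1, 0]
                sy += centers[i - 1, 1]
                cnt += 1
            assert position_estimate(tr, N) == pytest.approx((sx / cnt, sy / cnt))

    def test_out_of_range(self):
        tr = make_trace(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            position_estimate(tr, 6)
        with pytest.raises(ValueError):
            position_estimate(tr, 0)


class TestConfigValidation:
    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            LocalizerConfig(alpha=0.0)
        with pytest.raises(ValueError):
            LocalizerConfig(alpha=1.0)

    def test_n_on_range(self):
        with pytest.raises(ValueError):
            LocalizerConfig(n_on=50)
        cfg = LocalizerConfig(n_on=50, n_on_override=True)
        assert cfg.n_on == 50
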