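"""Microscale cleft simulator: oracles, invariants, and summaries."""

import numpy as np
import pytest

from gliasim.dirt import (
    DirtConfig,
    DirtTimeCourse,
    fit_piecewise_linear,
    protrusion_sweep,
    simulate_dirt,
    summarize_timecourse,
)


def make_timecourse(times, active):
    times = np.asarray(times, dtype=float)
    active = np.asarray(active, dtype=float)
    return DirtTimeCourse(times=times, active=active, receptor_absorbed=0,
                          astro_absorbed=0, astro_left=0, astro_right=0,
                          cleared=0, free_at_cap=0, n_nt=0,
                          n_rec=int(active.max(initial=0)))


class TestSummarize:
    def test_rectangular_curve(self):
        # height 8 for duration 2 -> area 16, half-max width 2
        t = np.arange(0, 2.0, 0.005)
        tc = make_timecourse(t, np.full(t.size, 8.0))
        s = summarize_timecourse(tc, bin_width=0.05)
        assert s.strength == pytest.approx(8.0 * 2.0, rel=0.03)
        assert s.half_max_width == pytest.approx(2.0, abs=0.05)

    def test_all_zero_curve(self):
        t = np.arange(0, 1.0, 0.005)
        s = summarize_timecourse(make_timecourse(t, np.zeros(t.size)))
        assert s.strength == 0.0
        assert s.half_max_width == 0.0

    def test_triangular_curve(self):
        # symmetric triangle, peak 10, base 4 -> area 20, half-max width 2
        t = np.arange(0, 4.0, 0.005)
        active = 10.0 * (1.0 - np.abs(t - 2.0) / 2.0)
        s = summarize_timecourse(make_timecourse(t, active), bin_width=0.05)
        assert s.strength == pytest.approx(10.0 * 4.0 / 2.0, rel=0.03)
        assert s.half_max_width == pytest.approx(2.0, abs=0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_timecourse(make_timecourse([], []))


class TestConfigValidation:
    def test_phi_out_of_range(self):
        with pytest.raises(ValueError, match="phi"):
            DirtConfig(phi=1.0)
        with pytest.raises(ValueError, match="phi"):
            DirtConfig(phi=-1.2)

    def test_step_size_invariant(self):
        with pytest.raises(ValueError, match="dt_diff"):
            DirtConfig(dt_diff=1e-3)

    def test_bad_psd(self):
        with pytest.raises(ValueError, match="psd"):
            DirtConfig(psd=(0.75, 0.25))


class TestSimulate:
    def test_zero_absorption_rate_gives_zero_strength(self):
        tc = simulate_dirt(DirtConfig(n_nt=200, k_abs=0.0, seed=5))
        assert tc.receptor_absorbed == 0
        assert tc.astro_absorbed + tc.cleared + tc.free_at_cap == 200
        assert summarize_timecourse(tc).strength == 0.0

    def test_particle_conservation(self):
        tc = simulate_dirt(DirtConfig(n_nt=300, seed=2))
        total = (tc.receptor_absorbed + tc.astro_absorbed + tc.cleared +
                 tc.free_at_cap)
        assert total == 300
        assert tc.active.max() <= tc.n_rec

    def test_symmetric_exit_split(self):
        # no receptors, centered release, reflecting strip: left/right wall
        # exits are a fair coin
        tc = simulate_dirt(DirtConfig(n_nt=2000, n_rec=0, k_abs=0.0,
                                      phi=-1.0, seed=11,
                                      extracellular="reflecting"))
        frac_left = tc.astro_left / tc.astro_absorbed
        assert frac_left == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(2000))

    def test_1d_splitting_probability(self):
        # thin reflecting strip, off-center release: P(exit left) =
        # (R - x0)/(R - L), the harmonic splitting probability for Brownian
        # motion between two absorbing walls
        cfg = DirtConfig(n_nt=3000, n_rec=0, k_abs=0.0, phi=-1.0,
                         c_h=0.02, dt_diff=1e-5, release_x=0.8, seed=3,
                         extracellular="reflecting")
        tc = simulate_dirt(cfg)
        left_wall, right_wall = -0.5, 1.5
        p_left = (right_wall - 0.8) / (right_wall - left_wall)
        se = np.sqrt(p_left * (1 - p_left) / 3000)
        assert tc.astro_left / 3000 == pytest.approx(p_left, abs=3.5 * se)

    def test_protrusion_reduces_strength_and_width(self):
        cfg = DirtConfig(seed=17)
        s0 = [summarize_timecourse(simulate_dirt(DirtConfig(seed=s)))
              for s in (17, 18, 19)]
        s4 = [summarize_timecourse(simulate_dirt(DirtConfig(phi=0.4, seed=s)))
              for s in (27, 28, 29)]
        assert np.mean([x.strength for x in s4]) < np.mean([x.strength for x in s0])
        assert np.mean([x.half_max_width for x in s4]) <= np.mean([x.half_max_width for x in s0])

    def test_perfectly_absorbing_limit_matches_oracle(self):
        # K -> inf, tau_r -> 0 turns the PSD into a perfectly absorbing
        # segment; compare receptor-capture fraction against a brute-force
        # vectorized Brownian simulation with a perfectly absorbing PSD
        n = 3000
        cfg = DirtConfig(n_nt=n, k_abs=1e9, tau_r=1e-12, seed=23)
        tc = simulate_dirt(cfg)
        frac = tc.receptor_absorbed / n

        rng = np.random.default_rng(99)
        sig = np.sqrt(2 * cfg.d_coef * cfg.dt_diff)
        x = np.full(n, 0.5)
        y = np.full(n, cfg.c_h)
        alive = np.ones(n, dtype=bool)
        captured = 0
        for _ in range(2_000_000):
            if not alive.any():
                break
            idx = np.flatnonzero(alive)
            x[idx] += sig * rng.standard_normal(idx.size)
            y[idx] += sig * rng.standard_normal(idx.size)
            gone_wall = (x[idx] <= 0.0) | (x[idx] >= 1.0)
            over = y[idx] > cfg.c_h
            y[idx[over]] = 2 * cfg.c_h - y[idx[over]]
            below = y[idx] < 0.0
            on_psd = below & (x[idx] >= 0.25) & (x[idx] < 0.75) & ~gone_wall
            captured += int(on_psd.sum())
            y[idx[below & ~on_psd]] *= -1.0
            alive[idx[gone_wall | on_psd]] = False
        frac_oracle = captured / n
        se = np.sqrt(frac_oracle * (1 - frac_oracle) / n) * np.sqrt(2)
        assert frac == pytest.approx(frac_oracle, abs=3 * se)

    def test_diffusive_time_rescaling_invariance(self):
        # t -> t/c, D -> cD, K -> cK, tau_r -> tau_r/c, dt -> dt/c leaves
        # the capture process statistically unchanged (the Robin boundary
        # condition D du/dn = K u fixes K's scaling); areas scale by 1/c
        c = 2.0
        reps = 4
        base = [summarize_timecourse(
            simulate_dirt(DirtConfig(n_nt=400, seed=100 + r))).strength
            for r in range(reps)]
        scaled = [summarize_timecourse(
            simulate_dirt(DirtConfig(n_nt=400, d_coef=c, k_abs=c, tau_r=0.1 / c,
                                     dt_diff=1e-5 / c, seed=200 + r)),
            bin_width=0.05 / c).strength * c
            for r in range(reps)]
        sem = np.hypot(np.std(base, ddof=1), np.std(scaled, ddof=1)) / np.sqrt(reps)
        assert abs(np.mean(base) - np.mean(scaled)) < 3 * sem


class TestProtrusionSweep:
    def test_reps_and_sem(self):
        out = protrusion_sweep(DirtConfig(n_nt=150, seed=1), [0.0, 0.4], reps=3)
        assert len(out) == 2
        assert out[0].n_reps == 3
        assert out[0].strength_sem > 0
        assert out[1].phi == 0.4

    def test_invalid_reps(self):
        with pytest.raises(ValueError):
            protrusion_sweep(DirtConfig(), [0.0], reps=0)


class TestPiecewiseFit:
    def test_exact_recovery(self):
        phis = np.linspace(-1, 0.95, 12)
        vals = 5.0 - 4.0 * np.maximum(phis - (-0.2), 0.0)
        fit = fit_piecewise_linear(phis, vals)
        assert fit.plateau == pytest.approx(5.0, abs=1e-3)
        assert fit.breakpoint == pytest.approx(-0.2, abs=1e-3)
        assert fit.slope == pytest.approx(-4.0, abs=1e-3)

    def test_continuity_at_breakpoint(self):
        phis = np.linspace(-1, 0.95, 12)
        vals = 5.0 - 4.0 * np.maximum(phis + 0.2, 0.0)
        fit = fit_piecewise_linear(phis, vals)
        eps = 1e-9
        assert fit(fit.breakpoint - eps) == pytest.approx(fit(fit.breakpoint + eps), abs=1e-6)

    def test_pure_line(self):
        phis = np.linspace(-1, 1, 10)
        vals = 2.0 - 3.0 * phis
        fit = fit_piecewise_linear(phis, vals)
        assert fit.breakpoint <= phis[0] + 1e-6
        assert fit.slope == pytest.approx(-3.0, rel=1e-3)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(4)
        grid = np.linspace(-1, 0.95, 9)
        phis = np.repeat(grid, 20)
        vals = 5.0 - 4.0 * np.maximum(phis + 0.2, 0.0)
        vals = vals + rng.normal(0, 0.02 * 5.0, vals.size)
        fit = fit_piecewise_linear(phis, vals)
        assert fit.plateau == pytest.approx(5.0, rel=0.1)
        assert fit.slope == pytest.approx(-4.0, rel=0.1)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_piecewise_linear([0, 1, 2], [1, 1, 1])
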