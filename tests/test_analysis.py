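"""Raster and current diagnostics against constructed oracles."""

import numpy as np
import pytest

from gliasim.analysis import (
    classify_synchrony,
    correlation_vs_distance,
    firing_rates,
    rheobase,
    shared_current_decomposition,
    spike_count_correlations,
)
from gliasim.eifnet import CurrentRecord, SpikeRaster
from gliasim.netbuild import NetworkParams
from gliasim.workbench import generate_fixture


def raster_from(ids, times, n, t_total, **kw):
    order = np.argsort(times, kind="stable")
    return SpikeRaster(ids=np.asarray(ids, dtype=np.int64)[order],
                       times=np.asarray(times, dtype=float)[order],
                       n_neurons=n, t_total=t_total, n_e=n, **kw)


class TestSpikeCountCorrelations:
    def test_identical_trains(self):
        t = np.arange(10, 10_000, 37.0)
        raster = raster_from(np.r_[np.zeros(t.size), np.ones(t.size)],
                             np.r_[t, t], 2, 10_000.0)
        out = spike_count_correlations(raster, window=250.0, sample=np.array([0, 1]))
        assert out.mean_corr == pytest.approx(1.0)

    def test_alternating_windows(self):
        w = 250.0
        t0 = np.arange(0, 10_000, 2 * w) + 10.0   # even windows only
        t1 = np.arange(w, 10_000, 2 * w) + 10.0   # odd windows only
        raster = raster_from(np.r_[np.zeros(t0.size), np.ones(t1.size)],
                             np.r_[t0, t1], 2, 10_000.0)
        out = spike_count_correlations(raster, window=w, sample=np.array([0, 1]))
        assert out.mean_corr == pytest.approx(-1.0)

    def test_independent_poisson_near_zero(self):
        raster = generate_fixture("poisson_raster", seed=1, n=100, rate=10.0,
                                  t_total=200_000.0)
        out = spike_count_correlations(raster, window=250.0,
                                       sample=np.arange(100))
        assert abs(out.mean_corr) < 0.01

    def test_relabel_and_time_shift_invariance(self):
        raster = generate_fixture("poisson_raster", seed=2, n=30, rate=8.0,
                                  t_total=50_000.0)
        out = spike_count_correlations(raster, window=250.0, sample=np.arange(30))
        perm = np.random.default_rng(0).permutation(30)
        relabeled = raster_from(perm[raster.ids], raster.times, 30, 50_000.0)
        out2 = spike_count_correlations(relabeled, window=250.0,
                                        sample=np.arange(30))
        assert out2.mean_corr == pytest.approx(out.mean_corr, abs=1e-12)
        shifted = raster_from(raster.ids, raster.times + 500.0, 30, 50_500.0)
        out3 = spike_count_correlations(shifted, window=250.0,
                                        sample=np.arange(30), t_start=500.0)
        assert out3.mean_corr == pytest.approx(out.mean_corr, abs=1e-12)

    def test_group_partition_reconstructs_global_mean(self):
        raster = generate_fixture("two_group_raster", seed=3, n=60,
                                  t_total=30_000.0)
        out = spike_count_correlations(raster, window=250.0, sample=np.arange(60))
        g = raster.group_label[np.arange(60)]
        iu = np.triu_indices(60, k=1)
        same = g[iu[0]] == g[iu[1]]
        n_within, n_across = int(same.sum()), int((~same).sum())
        recon = (out.by_group["within"] * n_within +
                 out.by_group["across"] * n_across) / (n_within + n_across)
        assert recon == pytest.approx(out.mean_corr, abs=1e-9)

    def test_two_group_signs(self):
        raster = generate_fixture("two_group_raster", seed=4, n=80,
                                  t_total=60_000.0)
        out = spike_count_correlations(raster, window=250.0, sample=np.arange(80))
        assert out.by_group["within"] > 0 > out.by_group["across"]

    def test_zero_variance_neuron_excluded(self):
        t = np.arange(10, 5000, 100.0)
        raster = raster_from(np.r_[np.zeros(t.size), np.ones(t.size)],
                             np.r_[t, t], 3, 5000.0)  # neuron 2 never spikes
        out = spike_count_correlations(raster, window=250.0,
                                       sample=np.array([0, 1, 2]))
        assert out.n_excluded == 1
        assert out.n_pairs == 1


class TestCorrelationVsDistance:
    def test_shared_train_all_bins_one(self):
        n = 40
        t = np.arange(10, 20_000, 83.0)
        ids = np.repeat(np.arange(n), t.size)
        times = np.tile(t, n)
        rng = np.random.default_rng(0)
        pos = rng.random((n, 2))
        raster = raster_from(ids, times, n, 20_000.0, positions=pos)
        out = correlation_vs_distance(raster, window=250.0, bins=4,
                                      sample=np.arange(n))
        for _, mean, count in out.by_distance:
            if count > 0:
                assert mean == pytest.approx(1.0)

    def test_independent_near_zero(self):
        raster = generate_fixture("poisson_raster", seed=5, n=60, rate=10.0,
                                  t_total=100_000.0)
        rng = np.random.default_rng(1)
        raster.positions = rng.random((60, 2))
        out = correlation_vs_distance(raster, window=250.0, bins=4,
                                      sample=np.arange(60))
        for _, mean, count in out.by_distance:
            if count > 10:
                assert abs(mean) < 0.05

    def test_positions_required(self):
        raster = generate_fixture("poisson_raster", seed=6, n=10, t_total=5000.0)
        with pytest.raises(ValueError):
            correlation_vs_distance(raster, window=250.0)


class TestSynchrony:
    def test_volley_raster_synchronous(self):
        raster = generate_fixture("synchronous_raster", seed=0, n=200,
                                  period=100.0, t_total=5000.0)
        v = classify_synchrony(raster)
        assert v.synchronous and v.n_volleys >= 40

    def test_poisson_asynchronous(self):
        raster = generate_fixture("poisson_raster", seed=1, n=1000, rate=5.0,
                                  t_total=5000.0)
        v = classify_synchrony(raster)
        assert not v.synchronous
        assert v.sync_index < 3.0

    def test_empty_raster(self):
        raster = SpikeRaster(ids=np.array([], dtype=int), times=np.array([]),
                             n_neurons=10, t_total=1000.0, n_e=10)
        v = classify_synchrony(raster)
        assert not v.synchronous and v.sync_index == 0.0

    def test_compression_monotonicity(self):
        # moving spikes toward common bins can only raise the sync index
        raster = generate_fixture("poisson_raster", seed=2, n=500, rate=5.0,
                                  t_total=5000.0)
        v0 = classify_synchrony(raster)
        squeezed = raster_from(raster.ids,
                               np.round(raster.times / 100.0) * 100.0,
                               500, 5000.0)
        v1 = classify_synchrony(squeezed)
        assert v1.sync_index >= v0.sync_index
        assert v1.synchronous

    def test_truncated_raster_is_synchronous(self):
        raster = generate_fixture("poisson_raster", seed=3, n=10, t_total=1000.0)
        raster.truncated = True
        assert classify_synchrony(raster).synchronous


class TestRheobase:
    def test_excitatory_and_inhibitory_values(self):
        p = NetworkParams.nonspatial_defaults()
        assert rheobase(p, "e") == pytest.approx(8.0 / 15.0)
        assert rheobase(p, "i") == pytest.approx(0.95)

    def test_matches_numeric_maximum_of_drift(self):
        # rheobase = max_V [ (V - E_L)/tau_m - (Delta_T/tau_m) exp((V-V_T)/Delta_T) ]
        p = NetworkParams.nonspatial_defaults()
        v = np.linspace(-80.0, -45.0, 200_001)
        drift = (v - p.e_l) / p.tau_m_e - \
            (p.delta_t_e / p.tau_m_e) * np.exp((v - p.v_t_soft) / p.delta_t_e)
        assert rheobase(p, "e") == pytest.approx(drift.max(), abs=1e-6)

    def test_lif_limit(self):
        p = NetworkParams(delta_t_e=1e-9)
        assert rheobase(p, "e") == pytest.approx((p.v_t_soft - p.e_l) / p.tau_m_e,
                                                 rel=1e-6)


def record_from(traces, dt=0.5):
    n_s = traces["ffwd"].shape[-1]
    return CurrentRecord(neuron_ids=np.arange(traces["ffwd"].shape[0]),
                         times=np.arange(n_s) * dt,
                         ffwd=traces["ffwd"], rec_e=traces["rec_e"],
                         rec_i=traces["rec_i"])


class TestSharedCurrents:
    def test_constant_input_zero_trace(self):
        n_s = 2000
        rec = record_from({"ffwd": np.full((5, n_s), 2.0),
                           "rec_e": np.full((5, n_s), 1.0),
                           "rec_i": np.full((5, n_s), -3.0)})
        p = NetworkParams.nonspatial_defaults()
        sf = shared_current_decomposition(rec, p)
        assert np.abs(sf.ffwd).max() < 1e-9
        assert np.abs(sf.grand_total).max() < 1e-9

    def test_sinusoid_attenuation(self):
        # slow sinusoid A sin(wt): recovered with gain exp(-w^2 sigma^2 / 2)
        # and scaled by 1/rheobase
        dt, sigma, period, amp = 0.5, 15.0, 500.0, 0.2
        t = np.arange(0, 20_000.0, dt)
        omega = 2 * np.pi / period
        rec = record_from({"ffwd": np.tile(amp * np.sin(omega * t), (3, 1)),
                           "rec_e": np.zeros((3, t.size)),
                           "rec_i": np.zeros((3, t.size))}, dt=dt)
        p = NetworkParams.nonspatial_defaults()
        sf = shared_current_decomposition(rec, p, kernel_sigma=sigma)
        expected_amp = amp * np.exp(-omega**2 * sigma**2 / 2) / rheobase(p, "e")
        measured = sf.ffwd[2000:-2000]
        assert measured.max() == pytest.approx(expected_amp, rel=0.02)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        p = NetworkParams.nonspatial_defaults()
        a = {k: rng.standard_normal((4, 3000)) for k in ("ffwd", "rec_e", "rec_i")}
        b = {k: rng.standard_normal((4, 3000)) for k in ("ffwd", "rec_e", "rec_i")}
        combo = {k: 2.0 * a[k] + 0.5 * b[k] for k in a}
        sa = shared_current_decomposition(record_from(a), p)
        sb = shared_current_decomposition(record_from(b), p)
        sc = shared_current_decomposition(record_from(combo), p)
        np.testing.assert_allclose(sc.ffwd, 2.0 * sa.ffwd + 0.5 * sb.ffwd,
                                   atol=1e-9)
        np.testing.assert_allclose(sc.rec_total,
                                   2.0 * sa.rec_total + 0.5 * sb.rec_total,
                                   atol=1e-9)


class TestFiringRates:
    def test_empty(self):
        raster = SpikeRaster(ids=np.array([], dtype=int), times=np.array([]),
                             n_neurons=5, t_total=1000.0, n_e=3)
        out = firing_rates(raster)
        assert out["mean"] == 0.0

    def test_simple_counts(self):
        ids = np.zeros(50, dtype=int)
        times = np.linspace(1, 9999, 50)
        raster = raster_from(ids, times, 1, 10_000.0)
        assert firing_rates(raster)["mean"] == pytest.approx(5.0)

    def test_regular_train(self):
        times = np.arange(50.0, 5000.0, 100.0)
        raster = raster_from(np.zeros(times.size, dtype=int), times, 1, 5000.0)
        assert firing_rates(raster)["mean"] == pytest.approx(10.0, abs=0.25)
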