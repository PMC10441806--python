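"""Heterogeneous exponential integrate-and-fire (EIF) network simulator.

Membrane dynamics (Heun/RK2 steps, voltages in mV, time in ms):

    dV/dt = -(V - E_L)/tau_m + (Delta_T/tau_m) * exp((V - V_T)/Delta_T)
            + F(t) + R(t)

with a hard threshold V_th (spike, reset to V_re, absolute refractory
period) and a soft threshold V_T in the exponential spike-generating term.
The recurrent input is a sum of exponentially filtered presynaptic spike
trains.  Because ensheathment takes only two values per synapse, every
synapse falls into one of at most four (source population x ensheathment
state) kinetic classes, so each neuron carries one exponential filter state
per class; a presynaptic spike increments the target's class state by
``J_eff / (tau_class * sqrt(N))`` so that one spike delivers total
time-integrated input ``J_eff / sqrt(N)`` mV regardless of tau (charge
conservation; exact for the Euler-discretized filter).

Feedforward drive is either a shared Gaussian-process bias
``F_j = sqrt(N) m_a + sigma_s s(t)`` with squared-exponential autocovariance
``exp(-tau^2/tau_s^2)`` (one realization for the whole network or one per
half-population), or a layer of independent Poisson neurons filtered through
the excitatory synaptic kernel (spatial model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from numpy.random import SeedSequence
from scipy.ndimage import gaussian_filter1d

from gliasim.ensheathment import EnsheathmentParams, assign_ensheathment
from gliasim.netbuild import Connectivity, NetworkParams

NOISE_KINDS = ("shared_noise", "two_population_noise")


@dataclass
class SimConfig:
    """Integration and recording settings (ms)."""

    t_total: float = 5000.0
    dt: float = 0.01
    burn_in: float = 500.0
    seed_noise: int = 0
    seed_init: int = 1
    record_currents_for: Sequence[int] = field(default_factory=list)
    record_voltage_for: Sequence[int] = field(default_factory=list)
    record_stride: int = 10
    max_mean_rate: float = 250.0  # Hz; spike-buffer capacity per neuron

    def __post_init__(self) -> None:
        if self.dt > 0.1:
            raise ValueError(f"dt must be <= 0.1 ms, got {self.dt}")
        if not (0 <= self.burn_in < self.t_total):
            raise ValueError("burn_in must lie in [0, t_total)")


@dataclass
class FeedforwardDrive:
    """Feedforward input specification.

    kind: "shared_noise" (all neurons share one GP realization),
    "two_population_noise" (random half/half split, one realization each),
    or "poisson_layer" (spatial model).
    """

    kind: str = "shared_noise"
    m_e: float = 0.015
    m_i: float = 0.01
    sigma_s: float = 0.1
    tau_s: float = 40.0
    group_assignment: np.ndarray | None = None
    seed_groups: int = 0
    n_f: int = 0
    r_f: float = 0.0

    @classmethod
    def shared(cls, params: NetworkParams) -> "FeedforwardDrive":
        return cls(kind="shared_noise", m_e=params.m_e, m_i=params.m_i,
                   sigma_s=params.sigma_s, tau_s=params.tau_s)

    @classmethod
    def two_population(cls, params: NetworkParams, seed_groups: int = 0) -> "FeedforwardDrive":
        return cls(kind="two_population_noise", m_e=params.m_e, m_i=params.m_i,
                   sigma_s=params.sigma_s, tau_s=params.tau_s,
                   seed_groups=seed_groups)

    @classmethod
    def poisson(cls, params: NetworkParams) -> "FeedforwardDrive":
        return cls(kind="poisson_layer", n_f=params.n_f, r_f=params.r_f)

    def groups(self, n: int) -> np.ndarray:
        """Per-neuron noise-group labels (0 or 1)."""
        if self.group_assignment is not None:
            return np.asarray(self.group_assignment, dtype=np.int8)
        if self.kind == "two_population_noise":
            rng = np.random.default_rng(self.seed_groups)
            g = np.zeros(n, dtype=np.int8)
            g[rng.permutation(n)[: n // 2]] = 1
            return g
        return np.zeros(n, dtype=np.int8)


@dataclass
class SpikeRaster:
    """Spike events (neuron id, time in ms) with population metadata."""

    ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    t_total: float
    n_e: int | None = None
    group_label: np.ndarray | None = None
    positions: np.ndarray | None = None
    truncated: bool = False

    @property
    def pop_label(self) -> np.ndarray | None:
        if self.n_e is None:
            return None
        lab = np.zeros(self.n_neurons, dtype=np.int8)
        lab[self.n_e:] = 1
        return lab

    def counts(self, t_start: float = 0.0, t_end: float | None = None) -> np.ndarray:
        t_end = self.t_total if t_end is None else t_end
        mask = (self.times >= t_start) & (self.times < t_end)
        return np.bincount(self.ids[mask], minlength=self.n_neurons)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"neuron_id": self.ids, "time_ms": self.times})


@dataclass
class CurrentRecord:
    """Per-neuron input traces in mV/ms (current over capacitance)."""

    neuron_ids: np.ndarray
    times: np.ndarray
    ffwd: np.ndarray   # (n_recorded, n_samples)
    rec_e: np.ndarray
    rec_i: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.ffwd + self.rec_e + self.rec_i


def sample_shared_noise(t_total: float, dt: float, tau_s: float, seed: int,
                        base_dt: float | None = None) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian process with autocovariance
    exp(-lag^2 / tau_s^2), sampled on the dt grid.

    Generated by convolving white noise with a Gaussian kernel (the kernel's
    standard deviation tau_s/2 yields the target squared-exponential
    autocovariance exactly in the continuum limit) and standardizing.  The
    white noise lives on a coarser internal grid (``base_dt``, default
    tau_s/80) and the smooth process is linearly interpolated onto the dt
    grid, so the realization is independent of the integration step.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if base_dt is None:
        base_dt = tau_s / 80.0
    n_steps = int(round(t_total / dt))
    n_base = int(np.ceil(t_total / base_dt)) + 1
    sigma_samples = (tau_s / 2.0) / base_dt
    pad = int(np.ceil(6 * sigma_samples))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_base + 2 * pad)
    smooth = gaussian_filter1d(white, sigma_samples, mode="constant")[pad:pad + n_base]
    t_base = np.arange(n_base) * base_dt
    t_out = np.arange(n_steps) * dt
    s = np.interp(t_out, t_base, smooth)
    s = s - s.mean()
    return s / s.std()


def generate_poisson_ffwd(n_f: int, r_f: float, t_total: float, seed: int = 0) -> SpikeRaster:
    """Independent homogeneous Poisson spike trains (rate r_f in Hz)."""
    if r_f < 0:
        raise ValueError("r_f must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(r_f * t_total / 1000.0, size=n_f)
    ids = np.repeat(np.arange(n_f, dtype=np.int32), counts)
    times = rng.uniform(0.0, t_total, size=counts.sum())
    order = np.argsort(times, kind="stable")
    return SpikeRaster(ids=ids[order], times=times[order], n_neurons=n_f,
                       t_total=t_total)


def kernel_integral(tau: float) -> float:
    """Integral of the synaptic kernel eta(t) = (1/tau) exp(-t/tau) H(t).

    Equals 1 for every tau > 0: scaling tau changes the kinetics of a
    synapse but not the total transferred charge.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return 1.0


def discrete_kernel_charge(tau: float, dt: float) -> float:
    """Total dt-weighted sum of the Euler-discretized exponential filter.

    The simulator increments the filter state by 1/tau at the spike and
    decays it by (1 - dt/tau) each step; the geometric series sums to 1
    exactly, mirroring the continuous kernel.
    """
    if not (0 < dt < tau):
        raise ValueError("need 0 < dt < tau")
    x = 1.0 / tau
    total = 0.0
    decay = 1.0 - dt / tau
    while x * tau > 1e-14:
        total += x * dt
        x *= decay
    return total


# lookup table for the spike-initiation exponential: exp(arg) sampled at
# 1/128 mV resolution over arg in [-12, 30] (clamped outside; below -12 the
# term is negligible, above 30 the neuron fires within a step regardless).
# Linear interpolation keeps the relative error below ~1e-5 while avoiding
# two libm exp calls per neuron per step.
_EXP_LO, _EXP_HI, _EXP_RES = -12.0, 30.0, 128.0
_EXP_TAB = np.exp(np.arange(_EXP_LO, _EXP_HI + 2.0 / _EXP_RES, 1.0 / _EXP_RES))


@njit(cache=True, fastmath=True)
def _exp_psi(arg, tab):
    if arg <= _EXP_LO:
        return 0.0
    if arg > _EXP_HI:
        arg = _EXP_HI
    x = (arg - _EXP_LO) * _EXP_RES
    i = int(x)
    f = x - i
    return tab[i] * (1.0 - f) + tab[i + 1] * f


@njit(cache=True, fastmath=True, inline="always")
def _psi_tab(vj, v_th, v_t, inv_delta, scale, tab):
    vc = vj if vj < v_th else v_th
    arg = (vc - v_t) * inv_delta
    if arg <= _EXP_LO:
        return 0.0
    if arg > _EXP_HI:
        arg = _EXP_HI
    x = (arg - _EXP_LO) * _EXP_RES
    i = int(x)
    f = x - i
    return scale * (tab[i] * (1.0 - f) + tab[i + 1] * f)


@njit(cache=True, fastmath=True)
def _eif_core(n, n_e, v, ref_until, pop,
              tau_m, delta_t, v_t, v_th, v_re, tau_ref, e_l,
              indptr, targets, inc_w, cls,
              decay, n_cls,
              ff_bias, noise, group,
              ff_indptr, ff_targets, ff_inc, ff_cls,
              ffwd_spike_step, ffwd_spike_id,
              n_steps, dt,
              rec_ids, rec_stride,
              ffwd_tr, rec_e_tr, rec_i_tr,
              spike_id_buf, spike_step_buf, exp_tab):
    # filter state: one exponential synapse per (neuron, kinetic class);
    # layout (n, n_cls) keeps each neuron's classes on one cache line
    x = np.zeros((n, n_cls), dtype=np.float32)
    n_spikes = 0
    max_spikes = spike_id_buf.shape[0]
    ff_ptr = 0
    n_ff_spikes = ffwd_spike_step.shape[0]
    n_rec = rec_ids.shape[0]
    has_noise = noise.shape[1] > 0
    has_ffwd_cls = n_cls > 4
    sample_i = 0
    d0 = decay[0]
    d1 = decay[1]
    d2 = decay[2]
    d3 = decay[3]
    d4 = decay[n_cls - 1]

    for step in range(n_steps):
        t = step * dt
        # deliver this step's feedforward Poisson spikes
        while ff_ptr < n_ff_spikes and ffwd_spike_step[ff_ptr] == step:
            k = ffwd_spike_id[ff_ptr]
            for e in range(ff_indptr[k], ff_indptr[k + 1]):
                x[ff_targets[e], ff_cls[e]] += ff_inc[e]
            ff_ptr += 1
        if has_noise:
            noise0 = noise[0, step]
            noise1 = noise[1, step]
        else:
            noise0 = 0.0
            noise1 = 0.0

        # record post-decay currents for the sampled neurons
        if n_rec > 0 and step % rec_stride == 0:
            for r in range(n_rec):
                j = rec_ids[r]
                fj = ff_bias[j] + (noise1 if group[j] == 1 else noise0)
                if has_ffwd_cls:
                    fj += x[j, 4] * d4
                ffwd_tr[r, sample_i] = fj
                rec_e_tr[r, sample_i] = x[j, 0] * d0 + x[j, 1] * d1
                rec_i_tr[r, sample_i] = x[j, 2] * d2 + x[j, 3] * d3
            sample_i += 1

        spikes_before = n_spikes
        # one population block at a time so the membrane constants live in
        # registers; Heun (RK2) steps — the spike-initiation exponential is
        # stiff (Delta_T down to 0.5 mV) and forward Euler needs a
        # several-fold smaller dt to avoid spurious excitability
        for p in range(2):
            j_lo = 0 if p == 0 else n_e
            j_hi = n_e if p == 0 else n
            inv_tau = 1.0 / tau_m[p]
            inv_delta = 1.0 / delta_t[p]
            scale = delta_t[p] * inv_tau
            t_ref = tau_ref[p]
            for j in range(j_lo, j_hi):
                x0 = x[j, 0] * d0
                x1 = x[j, 1] * d1
                x2 = x[j, 2] * d2
                x3 = x[j, 3] * d3
                x[j, 0] = x0
                x[j, 1] = x1
                x[j, 2] = x2
                x[j, 3] = x3
                inp = ff_bias[j] + x0 + x1 + x2 + x3
                if has_noise:
                    inp += noise1 if group[j] == 1 else noise0
                if has_ffwd_cls:
                    x4 = x[j, 4] * d4
                    x[j, 4] = x4
                    inp += x4
                if t < ref_until[j]:
                    v[j] = v_re
                    continue
                vj = v[j]
                vc = vj if vj < v_th else v_th
                arg = (vc - v_t) * inv_delta
                psi1 = 0.0
                if arg > _EXP_LO:
                    a = arg if arg < _EXP_HI else _EXP_HI
                    xx = (a - _EXP_LO) * _EXP_RES
                    i0 = int(xx)
                    f = xx - i0
                    psi1 = scale * (exp_tab[i0] * (1.0 - f) + exp_tab[i0 + 1] * f)
                k1 = (e_l - vj) * inv_tau + psi1 + inp
                v1 = vj + dt * k1
                vc = v1 if v1 < v_th else v_th
                # Heun corrector; deep below threshold the exponential is
                # flat over one step, so the predictor's value is reused
                if arg > -4.0 or v1 >= v_t:
                    psi2 = _psi_tab(vc, v_th, v_t, inv_delta, scale, exp_tab)
                else:
                    psi2 = psi1
                k2 = (e_l - vc) * inv_tau + psi2 + inp
                vj += 0.5 * dt * (k1 + k2)
                if vj >= v_th:
                    if n_spikes >= max_spikes:
                        return n_spikes, sample_i, True, step
                    spike_id_buf[n_spikes] = j
                    spike_step_buf[n_spikes] = step + 1
                    n_spikes += 1
                    v[j] = v_re
                    ref_until[j] = t + dt + t_ref
                else:
                    v[j] = vj

        # deliver this step's recurrent spikes after the full sweep so the
        # one-step synaptic latency is identical for every target
        for si in range(spikes_before, n_spikes):
            j = spike_id_buf[si]
            for e in range(indptr[j], indptr[j + 1]):
                x[targets[e], cls[e]] += inc_w[e]

    return n_spikes, sample_i, False, n_steps


def _csr(pre: np.ndarray, post: np.ndarray, n_pre: int):
    order = np.argsort(pre, kind="stable")
    counts = np.bincount(pre, minlength=n_pre)
    indptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, post[order].astype(np.int32), order


def simulate_network(conn: Connectivity, ens: EnsheathmentParams,
                     params: NetworkParams, drive: FeedforwardDrive,
                     cfg: SimConfig,
                     flags: np.ndarray | None = None
                     ) -> tuple[SpikeRaster, CurrentRecord]:
    """Simulate the heterogeneous EIF network.

    ``flags`` (per-edge ensheathment indicators) defaults to a fresh draw
    from ``ens``; pass it explicitly to hold the ensheathed set fixed across
    variant modes.  Reproducible given (conn, ens, drive, cfg) seeds.
    """
    n = conn.n_total
    n_e = conn.n_e
    sqrt_n = np.sqrt(n)
    n_steps = int(round(cfg.t_total / cfg.dt))

    if flags is None:
        flags = assign_ensheathment(conn.pre_pop, ens)
    flags = np.asarray(flags, dtype=bool)
    if flags.shape[0] != conn.pre.shape[0]:
        raise ValueError("flags length must match the edge count")

    # kinetic classes: (pre E, unens), (pre E, ens), (pre I, unens),
    # (pre I, ens) [, feedforward]
    has_ffwd_layer = drive.kind == "poisson_layer"
    n_cls = 5 if has_ffwd_layer else 4
    tau_cls = np.array([
        params.tau_syn_e,
        params.tau_syn_e * ens.tau_factor,
        params.tau_syn_i,
        params.tau_syn_i * ens.tau_factor,
        params.tau_syn_e,
    ][:n_cls])
    decay = 1.0 - cfg.dt / tau_cls

    pre_pop = conn.pre_pop
    post_pop = conn.post_pop
    j_map = np.array([[params.j[("e", "e")], params.j[("e", "i")]],
                      [params.j[("i", "e")], params.j[("i", "i")]]])
    j_base = j_map[post_pop, pre_pop]
    j_eff = np.where(flags, j_base * ens.j_factor, j_base)
    edge_cls = (2 * pre_pop + flags).astype(np.int8)
    # merge the ensheathed class into the base class when their time
    # constants coincide (s_en = 0 or j_only mode): equal-tau filters are
    # mathematically one filter, and keeping them merged makes the s_en = 0
    # network bitwise identical to the default network (summing the same
    # inputs through two accumulators rounds differently)
    remap = np.arange(5, dtype=np.int8)
    if tau_cls[1] == tau_cls[0]:
        remap[1] = 0
    if tau_cls[3] == tau_cls[2]:
        remap[3] = 2
    edge_cls = remap[edge_cls]
    inc_w = j_eff / (tau_cls[edge_cls] * sqrt_n)

    indptr, targets, order = _csr(conn.pre, conn.post, n)
    inc_w = inc_w[order].astype(np.float32)
    edge_cls = edge_cls[order]

    # feedforward layer (spatial) or GP noise (non-spatial)
    group = drive.groups(n)
    if has_ffwd_layer:
        noise = np.zeros((2, 0))
        ff_bias = np.zeros(n)
        raster_f = generate_poisson_ffwd(drive.n_f, drive.r_f, cfg.t_total,
                                         seed=cfg.seed_noise)
        steps_f = np.minimum((raster_f.times / cfg.dt).astype(np.int64), n_steps - 1)
        ff_indptr, ff_targets, ff_order = _csr(conn.ffwd_pre, conn.ffwd_post, drive.n_f)
        jf = np.where(conn.ffwd_post < n_e, params.j_ffwd["e"], params.j_ffwd["i"])
        ff_inc = (jf / (params.tau_syn_e * sqrt_n))[ff_order].astype(np.float32)
        ff_cls = np.full(ff_inc.shape[0], 4, dtype=np.int8)
        ffwd_spike_step = steps_f
        ffwd_spike_id = raster_f.ids.astype(np.int32)
    else:
        if drive.kind not in NOISE_KINDS:
            raise ValueError(f"unknown drive kind {drive.kind!r}")
        n_groups = 2 if drive.kind == "two_population_noise" else 1
        noise = np.empty((2, n_steps))
        for g in range(n_groups):
            s_seed = int(SeedSequence([cfg.seed_noise, g]).generate_state(1)[0] % (2**31))
            noise[g] = drive.sigma_s * sample_shared_noise(
                cfg.t_total, cfg.dt, drive.tau_s, s_seed)
        if n_groups == 1:
            noise[1] = noise[0]
        m_pop = np.where(np.arange(n) < n_e, drive.m_e, drive.m_i)
        ff_bias = sqrt_n * m_pop
        ff_indptr = np.zeros(1, dtype=np.int64)
        ff_targets = np.empty(0, dtype=np.int32)
        ff_inc = np.empty(0, dtype=np.float32)
        ff_cls = np.empty(0, dtype=np.int8)
        ffwd_spike_step = np.empty(0, dtype=np.int64)
        ffwd_spike_id = np.empty(0, dtype=np.int32)

    pop = np.zeros(n, dtype=np.int8)
    pop[n_e:] = 1
    tau_m = np.array([params.tau_m_e, params.tau_m_i])
    delta_t = np.array([params.delta_t_e, params.delta_t_i])
    tau_ref = np.array([params.tau_ref_e, params.tau_ref_i])

    rng_init = np.random.default_rng(cfg.seed_init)
    v = rng_init.uniform(params.v_re, params.v_t_soft, size=n)
    ref_until = np.full(n, -1.0)

    rec_ids = np.asarray(cfg.record_currents_for, dtype=np.int64)
    n_samples = (n_steps + cfg.record_stride - 1) // cfg.record_stride
    ffwd_tr = np.zeros((rec_ids.size, n_samples), dtype=np.float32)
    rec_e_tr = np.zeros_like(ffwd_tr)
    rec_i_tr = np.zeros_like(ffwd_tr)

    max_spikes = int(n * cfg.t_total / 1000.0 * cfg.max_mean_rate) + 1000
    spike_id_buf = np.empty(max_spikes, dtype=np.int32)
    spike_step_buf = np.empty(max_spikes, dtype=np.int64)

    n_spikes, n_samp, truncated, last_step = _eif_core(
        n, n_e, v, ref_until, pop,
        tau_m, delta_t, params.v_t_soft, params.v_th, params.v_re, tau_ref,
        params.e_l,
        indptr, targets, inc_w, edge_cls,
        decay, n_cls,
        ff_bias, noise, group,
        ff_indptr, ff_targets, ff_inc, ff_cls,
        ffwd_spike_step, ffwd_spike_id,
        n_steps, cfg.dt,
        rec_ids, cfg.record_stride,
        ffwd_tr, rec_e_tr, rec_i_tr,
        spike_id_buf, spike_step_buf, _EXP_TAB)

    if np.any(np.isnan(v)):
        raise FloatingPointError("membrane potential became NaN during integration")

    raster = SpikeRaster(
        ids=spike_id_buf[:n_spikes].copy(),
        times=spike_step_buf[:n_spikes] * cfg.dt,
        n_neurons=n, t_total=cfg.t_total, n_e=n_e,
        group_label=group if drive.kind == "two_population_noise" else None,
        positions=conn.positions, truncated=bool(truncated))
    record = CurrentRecord(
        neuron_ids=rec_ids,
        times=np.arange(n_samp) * cfg.dt * cfg.record_stride,
        ffwd=ffwd_tr[:, :n_samp], rec_e=rec_e_tr[:, :n_samp],
        rec_i=rec_i_tr[:, :n_samp])
    return raster, record
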