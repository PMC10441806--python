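# gliasim

Astrocytes tightly wrap ("ensheathe") a large and region-dependent fraction
of synapses, modulating the extracellular space around the cleft and the
clearance of neurotransmitter.  `gliasim` is a two-scale toolkit for asking
what that does to network dynamics:

1. **Microscale** — a Monte-Carlo *diffusion with recharging traps* (DiRT)
   simulator of a single synaptic cleft: transmitter molecules diffuse in a
   2D cleft, partially absorbing receptors on the postsynaptic density
   capture them (probability `K sqrt(pi dt / D)` per contact) and recharge
   with mean time `tau_r`, and a perfectly absorbing astrocyte boundary
   protrudes a depth `phi` into the cleft.  Sweeping `phi` shows the synapse
   becomes **weaker** (smaller area under the active-receptor time course)
   and **faster** (smaller half-max width), linearly beyond a plateau.
2. **Network** — that result is encoded as an "effective astrocyte": an
   ensheathed synapse has weight and time constant scaled by `(1 - s_en)`,
   with each synapse independently ensheathed with probability `p_e` (`p_i`
   for inhibitory synapses).  The simulator runs densely connected,
   strongly coupled (tightly balanced) networks of exponential
   integrate-and-fire neurons — non-spatial with shared Gaussian-process
   drive, or on a torus with wrapped-Gaussian connectivity and a Poisson
   feedforward layer — and the analysis layer measures firing rates,
   spike-count correlations (global, within/across populations, versus
   distance), synchrony, and the feedforward/recurrent current
   cancellation that defines E-I balance.

The headline phenomenon: ensheathment of excitatory synapses makes them
faster, inhibition can no longer track excitation, and the asynchronous
balanced state gives way to synchronous population volleys — an effect of
the *heterogeneous* kinetics that a naive mean field (`s_hat = s_en p_e`)
cannot capture.

## Worked example

```python
from gliasim import (DirtConfig, protrusion_sweep, fit_piecewise_linear,
                     NetworkParams, build_nonspatial, EnsheathmentParams,
                     FeedforwardDrive, SimConfig, simulate_network,
                     classify_synchrony, firing_rates)

# microscale: how does protrusion change the synapse?
sweep = protrusion_sweep(DirtConfig(seed=0),
                         phis=[-1.0, -0.2, 0.0, 0.4, 0.8], reps=5)
for s in sweep:
    print(f"phi={s.phi:+.1f}  strength={s.strength:6.2f}"
          f"  half-max width={s.half_max_width:.2f}")

# network: default vs ensheathed, same connectivity and drive
params = NetworkParams.nonspatial_defaults().scaled(0.2)   # N = 4,000
conn = build_nonspatial(params, seed=1)
cfg = SimConfig(t_total=5000.0, dt=0.01, seed_noise=2, seed_init=3)
for ens in (EnsheathmentParams(),
            EnsheathmentParams(s_en=0.5, p_e=0.7, seed=4)):
    raster, _ = simulate_network(conn, ens, params,
                                 FeedforwardDrive.shared(params), cfg)
    v = classify_synchrony(raster, t_start=500.0)
    r = firing_rates(raster, t_start=500.0)
    print(f"s_en={ens.s_en} p_e={ens.p_e}: e-rate {r['e']:.1f} Hz, "
          f"synchronous={v.synchronous} ({v.n_volleys} volleys)")
```

prints (exact numbers vary with seeds):

```
phi=-1.0  strength= 14.39  half-max width=0.33
phi=-0.2  strength= 15.21  half-max width=0.34
phi=+0.0  strength= 13.79  half-max width=0.33
phi=+0.4  strength=  7.34  half-max width=0.19
phi=+0.8  strength=  1.24  half-max width=0.12
s_en=0.0 p_e=0.0: e-rate 8.0 Hz, synchronous=False (0 volleys)
s_en=0.5 p_e=0.7: e-rate 12.1 Hz, synchronous=True (66 volleys)
```

The microscale strength sits on a plateau while the astrocyte is retracted
(`phi <= -0.2`) and then falls roughly linearly to zero as the astrocyte
fills the cleft — the basis of the linear `(1 - s_en)` scaling.  In the
network, the same connectivity and drive that produce irregular ~8 Hz
asynchronous firing by default produce repeated population-wide volleys
once 70% of excitatory synapses are ensheathed at half strength.

A thin CLI wraps the same functions: `gliasim dirt sweep`,
`gliasim simulate --config cfg.json --out dir`, `gliasim analyze`,
`gliasim experiment --spec spec.json`.

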