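# Methods

## Scope

`gliasim` studies how astrocyte ensheathment of synapses shapes spiking
network dynamics, at two scales: a microscale Monte-Carlo model of
neurotransmitter diffusion in a single synaptic cleft, and network models of
exponential integrate-and-fire (EIF) neurons in the tightly balanced regime
in which the microscale result is encoded as per-synapse heterogeneity in
synaptic strength and kinetics.

## Microscale: diffusion with recharging traps

The cleft is the rectangle `[0, c_w] x [0, c_h]` (arbitrary diffusion
units; defaults `c_w = 1`, `c_h = 0.1`, diffusion coefficient `D = 1`).
`N_NT = 1000` transmitter molecules are released simultaneously at the
top-center point `(c_w/2, c_h)` and perform independent Brownian motion,
integrated by the Euler–Maruyama scheme with per-axis step standard
deviation `sqrt(2 D dt)`, `dt = 1e-5`.  Configuration is rejected unless the
rms step is below `c_h / 4`, so a particle cannot jump across a meaningful
fraction of the domain in one step.

Boundaries:

* the top wall and the bottom wall outside the postsynaptic density (PSD)
  reflect specularly (overshoot mirrored);
* the PSD interval `[0.25, 0.75]` is divided into `N_rec = 50` equal
  receptor segments.  A particle whose step crosses `y = 0` is assigned to
  the segment containing the crossing point (linear interpolation of the
  step).  If that receptor is available, the particle is captured with
  probability `K sqrt(pi dt / D)` — the standard discretization of a Robin
  (partially absorbing) boundary with absorption rate `K`; otherwise it
  reflects.  A capturing receptor becomes *active* (unavailable) for an
  `Exp(tau_r)` recharge time, `tau_r = 0.1`;
* two vertical astrocyte walls at `x = c_w phi/2` and `x = c_w (1 - phi/2)`
  absorb on first contact.  The protrusion depth `phi in [-1, 0.95]` sets
  how far the astrocyte penetrates the cleft; for `phi < 0` the walls lie
  outside the cleft and the strip between the cleft mouth and the wall is
  extracellular space;
* outside the cleft footprint (`x < 0` or `x > c_w`) the top and bottom of
  the strip are, by default, an *absorbing bath*: transmitter that leaves
  the cleft neighbourhood is cleared by the surrounding tissue and does
  not return (`extracellular="absorbing"`).  This choice is what produces
  the plateau in strength for `phi <= -0.2`: the astrocyte wall competes
  with the bath only within about one cleft height of the mouth, so its
  exact position farther away is irrelevant.  The alternative
  (`extracellular="reflecting"`, a closed strip) has *no* plateau — the
  transverse-averaged motion is then a recurrent 1D diffusion, so receptor
  captures grow roughly linearly with wall distance (measured: strength
  30.9 / 24.3 / 17.3 at `phi = -1 / -0.6 / -0.2`).  The reflecting variant
  is retained because its exit statistics have exact closed forms (the
  harmonic splitting probability) used as test oracles.

The synaptic time course is the number of active receptors versus time,
recorded every 0.005 time units; after the last free particle is absorbed
the tail of the curve is completed from the receptors' recharge clocks.  A
run ends when all particles are absorbed or at a 200-time-unit cap, with
particles still free tallied so the conservation identity
`receptor + astrocyte + cleared + free = N_NT` is checked on every run.

Summaries: **strength** is the trapezoidal area under the curve after
binning at 0.05 time units; the **half-max width** is the total measure of
time (sum over bins) the binned curve spends at or above half its maximum,
which handles multiple crossings without ambiguity.  Sweeping `phi` with 20
repetitions per value yields a plateau for `phi <= -0.2` and a roughly
linear decrease to zero as the astrocyte fills the cleft, summarized by a
continuous plateau-then-line least-squares fit whose breakpoint is scanned
over the grid and refined by bounded scalar minimization.

## The effective astrocyte

The microscale result — ensheathment makes a synapse weaker and faster, both
roughly linearly in protrusion — is carried to the network by a single
ensheathment strength `s_en in [0, 1)`: an ensheathed synapse from
population b to a has weight `J_ab (1 - s_en)` and time constant
`tau_b (1 - s_en)`.  Each recurrent synapse is independently ensheathed with
probability `p_e` (excitatory presynaptic neuron) or `p_i` (inhibitory);
feedforward projections are never ensheathed.  `s_en` stays below 1 so
connections are never effectively removed and the dense connectivity of the
balanced regime is preserved.  Variant modes (`j_only`, `tau_only`) scale
only one of the two parameters while the *same* ensheathed set is used
(assignment depends only on the seed and the probabilities), making the
strength-versus-kinetics dissociation a controlled comparison.  The naive
mean-field surrogate replaces the heterogeneous scaling by the uniform
average `s_hat = s_en p_e`; networks along an `s_hat` isoline behave very
differently, which is the core argument against averaging this
heterogeneity away.

## Networks

EIF membrane dynamics (mV, ms):

    dV/dt = -(V - E_L)/tau_m + (Delta_T/tau_m) exp((V - V_T)/Delta_T)
            + F(t) + R(t),

with hard threshold `V_th = -10`, reset `V_re = -65`, absolute refractory
period (1.5 ms E, 0.5 ms I), leak `E_L = -60`, soft threshold `V_T = -50`,
`tau_m = 15/10` ms and `Delta_T = 2/0.5` mV for E/I.  The E rheobase —
the constant drive at which the resting state vanishes — is
`(V_T - E_L - Delta_T)/tau_m = 8/15` mV/ms and is used to normalize
current traces.

Recurrent input is a sum of exponentially filtered spike trains,
`eta(t) = (1/tau) exp(-t/tau) H(t)`, whose integral is 1 for every `tau`:
scaling `tau` changes kinetics, not transferred charge.  Weights scale as
`J_ab / sqrt(N)` and the feedforward bias as `sqrt(N) m_a` (strong
coupling), so inhibition can track and cancel excitation with O(1/sqrt(N))
residuals.  Because ensheathment is binary and `s_en` global, every synapse
falls into one of at most four kinetic classes (source population x
ensheathment state), plus one class for the feedforward layer; the
simulator keeps one exponential filter state per (neuron, class), giving
O(N) state instead of O(edges).  A presynaptic spike increments the target
class state by `J_eff / (tau_class sqrt(N))`; for the Euler-discretized
filter the per-spike time-integrated input is then exactly
`J_eff / sqrt(N)`.

Connectivity fixes the out-degree exactly.  Non-spatial: each presynaptic
neuron of population b sends `K_ab_out` edges to uniformly chosen distinct
targets in population a (no self-connections).  Spatial: neurons sit on
uniform grids over the unit torus; each presynaptic neuron draws `K_ab_out`
displacement vectors from an isotropic wrapped Gaussian of width `alpha`
and snaps them to the nearest target-population grid site (contacts carry
multiplicity), so the expected contact count follows
`(K_ab_out/N_a) g(dx; alpha) g(dy; alpha)`.  This sampling construction
costs O(N K) instead of the O(N^2) of per-pair Bernoulli draws and has the
same expected contact counts.

Feedforward drive is either a shared Gaussian process,
`F = sqrt(N) m_a + sigma_s s(t)` with autocovariance
`exp(-lag^2/tau_s^2)` (`tau_s = 40` ms) — one realization shared by all
neurons, or two realizations split over a random half/half partition — or,
in the spatial model, a grid of `N_F` independent 5-Hz Poisson neurons
wired through the excitatory kernel.  The GP is produced by convolving
white noise with a Gaussian kernel of standard deviation `tau_s/2` (which
yields exactly the target squared-exponential autocovariance) and
standardizing; the white noise lives on a fixed internal grid (`tau_s/80`)
so the realization does not depend on the integration step.

Table-level defaults (non-spatial): `N_e = N_i = 10,000`, all
`K_out = 2,500`, `J = (12.5, 20, -50, -50)` mV for (ee, ie, ei, ii),
`tau_e = 5`, `tau_i = 4` ms, `m_e = 0.015`, `m_i = 0.01` mV/ms,
`sigma_s = 0.1` mV/ms.  Spatial: `N_e = 40,000`, `N_i = 10,000`,
`N_F = 5,625`, `K_out = (2000, 500, 2000, 500)`,
`J = (40, 120, -400, -400)` mV, `tau_e = 6`, `tau_i = 5` ms,
`alpha_rec = 0.05`, `alpha_ffwd = 0.1`.  The spatial feedforward weights
(`J_eF = 350`, `J_iF = 100` mV) and out-degrees
(`K_eF = 4,500`, `K_iF = 1,125`) are calibration constants; both are
ordinary config values.  In the balanced state the excitatory rate is
pinned by the drive difference, `r_e ~ (F_e - F_i)/(W_ie - W_ee)` with `W`
the recurrent gains, so `J_eF` sets the operating point almost directly;
the defaults give roughly 630 feedforward inputs per neuron and put the
excitatory population near 5 Hz (inhibitory near 9 Hz).

### Numerics

Membrane equations are integrated with Heun's method (RK2) at
`dt = 0.01` ms by default.  The spike-initiation exponential is stiff
(`Delta_T` as small as 0.5 mV for inhibitory neurons) and forward Euler
systematically inflates excitability unless the step is several-fold
smaller: under Euler at `dt = 0.01` the scaled default network's rates are
~40% high and it falls into spurious volley firing that vanishes at
`dt = 0.0025`; under Heun the rates at `dt = 0.01` match the
`dt = 0.0025` reference (8.0 Hz E, 3.1 Hz I at scale 0.2) and the quiet
state is recovered.  The exponential is evaluated from a 1/128-resolution
lookup table with linear interpolation (relative error ~1e-5), clamped at
`V_th` so the upswing cannot overflow; a NaN anywhere aborts with a
diagnostic.

Even with Heun, networks sitting near the stability boundary (elevated
rates after a perturbation, or the weight-only ensheathment variant) can
be pushed across it by the residual integration error, which always acts
in the direction of *more* excitability: coarse steps can create spurious
volleys but never suppress genuine ones (ensheathment-driven volley states
persist with ~60 volleys per 4.5 s at every step size from 0.02 down to
0.0025 ms).  Synchrony verdicts therefore use a refinement protocol
(`workbench.refined_synchrony_verdict`): a raster classified synchronous
at the working step is re-simulated at half the step and the finer
verdict is kept.  The weight-only (`j_only`) dissociation variant is the
most step-sensitive condition and is run directly at `dt = 0.0025` ms.

Initial voltages are uniform on `[V_re, V_T]`; the first 500 ms are
discarded from every statistic.  Spike output is bounded by a buffer sized
for a 250-Hz population mean rate; a run that overflows it (runaway firing)
is returned flagged as truncated and treated as synchronous/unstable by the
analyses.

The microscale simulator aggregates time steps for particles far from
every absorbing or reactive boundary: a particle at distance d takes one
Gaussian jump of k steps with `k = (d/4 sigma)^2`, so that crossing a
boundary mid-jump is a beyond-4-sigma event.  First-contact statistics are
unchanged to the same order as the base scheme (verified against the
analytic splitting-probability and perfectly-absorbing oracles).  One
dimensional-analysis point worth recording: the diffusive rescaling that
leaves the capture process invariant is `t -> t/c, D -> cD, K -> cK,
tau_r -> tau_r/c` — the absorption rate must scale with time like any
other rate, as the Robin condition `D du/dn = K u` dictates.

### Scaling

Experiments run at a configurable scale `s`: population sizes and
out-degrees are multiplied by `s` (spatial counts rounded to the nearest
perfect square); weights and drive parameters are untouched (the
`1/sqrt(N)` coupling factor adapts).  Two consequences are worth knowing.
First, the feedforward fluctuation-to-bias ratio `sigma_s/(sqrt(N) m_a)`
grows as `1/sqrt(s)`, so a scaled network sees relatively larger drive
excursions; the default network absorbs these (occasionally with a single
large excursion from which it recovers — which is why the synchrony
verdict requires repeated volleys), and the same excursions are what test
whether an ensheathed network can still balance.  Scaling `sigma_s` down
to preserve the ratio was evaluated and rejected: it suppresses the
ensheathment-induced loss of balance altogether, removing the phenomenon
under study.  Second, the recurrent gain `K J/sqrt(N)` shrinks by
`sqrt(s)`, so the `(p_e, s_en)` synchrony boundary sits elsewhere than at
full size (see Limitations).

## Analyses

* **Spike-count correlations**: Pearson correlations of counts in
  non-overlapping 250-ms windows (the convention of the balanced-network
  literature; window exposed as a parameter) over a sample of 1,000
  excitatory neurons; zero-variance neurons are excluded and counted.
  Group (within/across drive populations) and torus-distance breakdowns
  use the same machinery; distance bins span `[0, sqrt(2)/2]`.
* **Synchrony**: a raster is synchronous when it contains at least 10
  distinct volleys, a volley being an episode in which at least 25% of the
  population spikes inside a 10-ms window.  Requiring *repeated* volleys
  distinguishes sustained volley firing from isolated excursions the
  asynchronous state recovers from.  The two thresholds sit in wide empty
  bands of the model's own statistics: asynchronous rasters put well under
  10% of the population in any 10-ms window and show at most a handful of
  excursions, while volley-firing states produce 55-85 volleys per 4.5-s
  window, so the verdict is insensitive to the participation threshold
  over roughly [0.15, 0.5] and to the volley count over roughly [8, 40].
  The peak/mean index of the smoothed population rate (2-ms bins, 5-ms
  Gaussian) is computed alongside; it is reported rather than used as the
  verdict because it conflates volley amplitude with volley frequency (a
  perfect volley train at period T scores T/(sqrt(2 pi) sigma) regardless
  of participation).
* **Shared-current decomposition**: feedforward, recurrent-E and
  recurrent-I inputs averaged over 500 recorded neurons, smoothed with a
  15-ms Gaussian, mean-subtracted, and divided by the rheobase.  In the
  balanced state the recurrent trace mirrors the feedforward trace
  (correlation near -1) and their sum is small.
* **Rates**: spike counts over the analysis window divided by its length.

## What the experiments show

At scale 0.2 the default one-population network is asynchronous in all
realizations, with the recurrent shared current canceling the feedforward
drive.  Ensheathment of excitatory synapses breaks this balance and drives
repeated population volleys; scaling only the synaptic time constants
reproduces the synchrony while scaling only the weights does not, i.e. the
loss of balance is a kinetic effect (inhibition too slow to track the
accelerated excitation), not a strength effect.  In the two-population
configuration ensheathment amplifies the pre-existing within-population
correlations and deepens the across-population anticorrelation, with the
within-population correlation tracking the excitatory firing rate.  In the
spatial model with narrow recurrent projections the default network is
spatially asynchronous while ensheathment produces positive short-range
and negative mid-range correlations; with broad recurrent projections the
existing distance structure is amplified in magnitude without moving its
zero crossing.

## Limitations

* The cleft model is 2D with a single recharge state per receptor; no
  transporter kinetics, desensitization cascades, or gliotransmitter
  release.
* Scaled-down networks preserve the qualitative regime but not the
  quantitative synchrony boundary: the recurrent gain shrinks by
  `sqrt(scale)`, so the ensheathment threshold for synchrony sits at
  different `(p_e, s_en)` than in the full-size network, and very strong
  uniform weakening of excitation (`p_e = 1` with large `s_en`) can
  stabilize a scaled network that would synchronize at full size.
* The synthetic rasters used as analysis fixtures (Poisson, jittered
  volleys, anti-correlated doubly stochastic groups) exercise the
  statistics but have none of the spike-train fine structure of the
  simulated networks; passing those tests validates the estimators, not
  the network model.
* No synaptic delays, conductance-based synapses, or adaptation; exact
  (event-driven) integration is out of scope.
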