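"""Diffusion with recharging traps (DiRT) in an idealized 2D synaptic cleft.

Neurotransmitter molecules are released at the top-center of a rectangular
cleft and perform independent Brownian motion.  The bottom of the cleft
carries a postsynaptic density (PSD) divided into equal receptor segments.
A receptor is a partially absorbing trap: on contact a molecule is captured
with probability ``K * sqrt(pi * dt / D)`` (the Robin-boundary discretization
for a surface with absorption rate K), after which the receptor is *active*
(bound / recharging) for an exponentially distributed time and reflects
further molecules.  Two vertical astrocyte walls sit at ``x = c_w * phi / 2``
and ``x = c_w * (1 - phi / 2)`` and absorb perfectly on first contact;
``phi`` is the fraction of the cleft blocked by the protruding astrocyte
(negative phi places the walls outside the cleft).  Outside the cleft
footprint the surrounding extracellular space acts, by default, as an
absorbing bath — transmitter that leaves the cleft neighbourhood is cleared
and does not return — which is what makes the synapse insensitive to the
astrocyte's exact position once it is retracted beyond about one cleft
height (the strength plateau).

The synaptic time course is the number of active receptors over time; its
area is the synaptic strength and its half-max width the synaptic timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit
from numpy.random import SeedSequence


@dataclass
class DirtConfig:
    """Parameters of one DiRT simulation (arbitrary diffusion units).

    Defaults are the standard cleft: 1000 transmitters, 50 receptors on the
    central half of the bottom boundary, unit diffusion coefficient in a
    1 x 0.1 cleft, absorption rate 1, mean recharge time 0.1, step 1e-5.
    """

    n_nt: int = 1000
    n_rec: int = 50
    tau_r: float = 0.1
    k_abs: float = 1.0
    d_coef: float = 1.0
    c_w: float = 1.0
    c_h: float = 0.1
    psd: tuple[float, float] = (0.25, 0.75)
    phi: float = 0.0
    dt_diff: float = 1e-5
    seed: int = 0
    t_max: float = 200.0
    record_dt: float = 0.005
    release_x: float | None = None  # default c_w / 2
    extracellular: str = "absorbing"

    def __post_init__(self) -> None:
        if self.extracellular not in ("absorbing", "reflecting"):
            raise ValueError(
                f"extracellular must be 'absorbing' or 'reflecting', got {self.extracellular!r}")
        if not (-1.0 <= self.phi <= 0.95):
            raise ValueError(f"phi must lie in [-1, 0.95], got {self.phi}")
        psd1, psd2 = self.psd
        if not (0.0 <= psd1 < psd2 <= self.c_w):
            raise ValueError(f"psd interval must satisfy 0 <= psd1 < psd2 <= c_w, got {self.psd}")
        if self.d_coef <= 0 or self.c_w <= 0 or self.c_h <= 0 or self.dt_diff <= 0:
            raise ValueError("d_coef, c_w, c_h and dt_diff must be positive")
        if self.k_abs < 0:
            raise ValueError("k_abs must be non-negative")
        step = np.sqrt(2.0 * self.d_coef * self.dt_diff)
        if step >= self.c_h / 4.0:
            raise ValueError(
                f"dt_diff too large: rms step {step:.3g} must be below c_h/4 = {self.c_h / 4:.3g}"
            )


@dataclass
class DirtTimeCourse:
    """Receptor-activation time course and absorption tallies of one run."""

    times: np.ndarray
    active: np.ndarray
    receptor_absorbed: int
    astro_absorbed: int
    astro_left: int
    astro_right: int
    cleared: int
    free_at_cap: int
    n_nt: int
    n_rec: int

    def check_conservation(self) -> None:
        total = (self.receptor_absorbed + self.astro_absorbed + self.cleared +
                 self.free_at_cap)
        if total != self.n_nt:
            raise AssertionError(
                f"particle conservation violated: {total} accounted for, {self.n_nt} released"
            )


@dataclass
class DirtSummary:
    """Strength (area under the activation curve) and half-max width."""

    strength: float
    half_max_width: float
    phi: float = np.nan
    n_reps: int = 1
    strength_sem: float = 0.0
    width_sem: float = 0.0
    receptor_absorbed_mean: float = np.nan
    astro_absorbed_mean: float = np.nan


@dataclass
class PiecewiseLinearFit:
    """Continuous plateau-then-line model: constant below the breakpoint,
    linear at and above it."""

    plateau: float
    breakpoint: float
    slope: float
    residual: float

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        return self.plateau + self.slope * np.maximum(phi - self.breakpoint, 0.0)


@njit(cache=True)
def _dirt_core(n_nt, n_rec, tau_r, k_abs, d_coef, c_w, c_h, psd1, psd2, phi,
               dt, t_max, record_every, release_x, seed, clearing):
    np.random.seed(seed)
    left = c_w * (phi / 2.0)
    right = c_w * (1.0 - phi / 2.0)
    sig = np.sqrt(2.0 * d_coef * dt)
    p_abs = k_abs * np.sqrt(np.pi * dt / d_coef)
    if p_abs > 1.0:
        p_abs = 1.0
    seg_w = (psd2 - psd1) / n_rec if n_rec > 0 else 1.0

    x = np.full(n_nt, release_x)
    y = np.full(n_nt, c_h)
    recharge_until = np.full(n_rec, -1.0)
    # adaptive time aggregation: a particle whose distance d to the nearest
    # absorbing/reactive boundary is large sleeps for k steps and then takes
    # one Gaussian jump of std sig*sqrt(k), with k chosen so the jump stays
    # below d/4 (crossing a boundary mid-jump is a >4-sigma tail event).
    # Statistics of first contact are unchanged to the same order as the
    # base scheme; receptors keep a single global clock.
    wake = np.zeros(n_nt, np.int64)
    jump_k = np.ones(n_nt, np.int64)
    max_jump = 20 * record_every

    n_steps_max = int(np.ceil(t_max / dt))
    n_samples = n_steps_max // record_every + 2
    active = np.zeros(n_samples, np.int32)
    sample_times = np.empty(n_samples)

    n_free = n_nt
    rec_abs = 0
    astro_left_n = 0
    astro_right_n = 0
    cleared_n = 0
    t = 0.0
    step = 0
    sample_i = 0
    sample_times[0] = 0.0

    while n_free > 0 and step < n_steps_max:
        t += dt
        step += 1
        i = 0
        while i < n_free:
            if step < wake[i]:
                i += 1
                continue
            x0 = x[i]
            y0 = y[i]
            sj = sig * np.sqrt(jump_k[i])
            xn = x0 + sj * np.random.standard_normal()
            yn = y0 + sj * np.random.standard_normal()
            absorbed = False
            if xn <= left:
                astro_left_n += 1
                absorbed = True
            elif xn >= right:
                astro_right_n += 1
                absorbed = True
            elif clearing and (xn < 0.0 or xn > c_w) and (yn <= 0.0 or yn >= c_h):
                # outside the cleft the surrounding extracellular space acts
                # as an absorbing bath: transmitter leaving the cleft
                # neighbourhood is cleared and does not return
                cleared_n += 1
                absorbed = True
            else:
                if yn > c_h:
                    yn = 2.0 * c_h - yn
                if yn < 0.0:
                    # crossing point of the bottom boundary
                    xc = x0 + (xn - x0) * (y0 / (y0 - yn))
                    if n_rec > 0 and psd1 <= xc < psd2:
                        r = int((xc - psd1) / seg_w)
                        if r >= n_rec:
                            r = n_rec - 1
                        if t >= recharge_until[r] and np.random.random() < p_abs:
                            rec_abs += 1
                            absorbed = True
                            recharge_until[r] = t + np.random.exponential(tau_r)
                    if not absorbed:
                        yn = -yn
                if yn > c_h:
                    yn = c_h
                elif yn < 0.0:
                    yn = 0.0
            if absorbed:
                n_free -= 1
                x[i] = x[n_free]
                y[i] = y[n_free]
                wake[i] = wake[n_free]
                jump_k[i] = jump_k[n_free]
            else:
                x[i] = xn
                y[i] = yn
                d = xn - left
                if right - xn < d:
                    d = right - xn
                if yn < d:
                    d = yn
                if clearing and (left < 0.0 or right > c_w):
                    # keep jumps clear of the cleft mouths and, outside the
                    # cleft, of the absorbing bath boundaries
                    dm = xn if xn > 0.0 else -xn
                    dm2 = c_w - xn if xn < c_w else xn - c_w
                    if dm2 < dm:
                        dm = dm2
                    if dm < d:
                        d = dm
                    if xn < 0.0 or xn > c_w:
                        if c_h - yn < d:
                            d = c_h - yn
                k = int((d / (4.0 * sig)) * (d / (4.0 * sig)))
                if k < 1:
                    k = 1
                elif k > max_jump:
                    k = max_jump
                jump_k[i] = k
                wake[i] = step + k
                i += 1
        if step % record_every == 0:
            sample_i += 1
            sample_times[sample_i] = t
            cnt = 0
            for r in range(n_rec):
                if recharge_until[r] > t:
                    cnt += 1
            active[sample_i] = cnt

    # all particles gone (or cap hit): finish the tail of the activation
    # curve as bound receptors recharge, without further diffusion steps
    record_dt = record_every * dt
    while t < t_max:
        cnt = 0
        for r in range(n_rec):
            if recharge_until[r] > t:
                cnt += 1
        if cnt == 0:
            break
        t += record_dt
        sample_i += 1
        sample_times[sample_i] = t
        cnt = 0
        for r in range(n_rec):
            if recharge_until[r] > t:
                cnt += 1
        active[sample_i] = cnt

    return (sample_times[: sample_i + 1], active[: sample_i + 1],
            rec_abs, astro_left_n, astro_right_n, cleared_n, n_free)


def simulate_dirt(config: DirtConfig) -> DirtTimeCourse:
    """Run one DiRT realization and return the activation time course.

    The run ends when every particle has been absorbed (by a receptor or by
    the astrocyte walls) and all receptors have recharged, or at
    ``config.t_max``; particles still free at the cap are tallied in
    ``free_at_cap`` so particle conservation is always checkable.
    """
    psd1, psd2 = config.psd
    release_x = config.c_w / 2.0 if config.release_x is None else config.release_x
    record_every = max(1, int(round(config.record_dt / config.dt_diff)))
    times, active, rec_abs, a_left, a_right, cleared, n_free = _dirt_core(
        config.n_nt, config.n_rec, config.tau_r, config.k_abs, config.d_coef,
        config.c_w, config.c_h, psd1, psd2, config.phi, config.dt_diff,
        config.t_max, record_every, release_x, config.seed % (2**31),
        config.extracellular == "absorbing",
    )
    tc = DirtTimeCourse(
        times=times, active=np.asarray(active),
        receptor_absorbed=int(rec_abs), astro_absorbed=int(a_left + a_right),
        astro_left=int(a_left), astro_right=int(a_right), cleared=int(cleared),
        free_at_cap=int(n_free), n_nt=config.n_nt, n_rec=config.n_rec,
    )
    tc.check_conservation()
    return tc


def _bin_curve(times: np.ndarray, values: np.ndarray, bin_width: float):
    """Average a sampled curve onto contiguous bins [k*b, (k+1)*b)."""
    idx = np.floor(times / bin_width).astype(np.int64)
    n_bins = int(idx.max()) + 1
    sums = np.bincount(idx, weights=values.astype(float), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        binned = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return centers, binned


def summarize_timecourse(tc: DirtTimeCourse, bin_width: float = 0.05) -> DirtSummary:
    """Reduce a time course to (strength, half-max width).

    Strength is the trapezoidal area under the binned activation curve;
    the half-max width is the total measure of time the binned curve spends
    at or above half its maximum (a sum over bins, so multiple crossings are
    handled naturally).  An all-zero curve maps to (0, 0).
    """
    if tc.times.size == 0:
        raise ValueError("empty time course")
    if tc.active.max(initial=0) == 0:
        return DirtSummary(strength=0.0, half_max_width=0.0)
    centers, binned = _bin_curve(tc.times, tc.active, bin_width)
    strength = float(np.trapezoid(binned, centers))
    half = binned.max() / 2.0
    width = float(np.count_nonzero(binned >= half) * bin_width)
    return DirtSummary(strength=strength, half_max_width=width)


def protrusion_sweep(config: DirtConfig, phis: Sequence[float], reps: int = 20,
                     bin_width: float = 0.05) -> list[DirtSummary]:
    """Mean +/- SEM of strength and half-max width over a protrusion grid.

    Each (phi, rep) cell runs an independent simulation whose seed is derived
    deterministically from ``config.seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    out: list[DirtSummary] = []
    for i, phi in enumerate(phis):
        strengths = np.empty(reps)
        widths = np.empty(reps)
        rec_counts = np.empty(reps)
        astro_counts = np.empty(reps)
        for rep in range(reps):
            seed = int(SeedSequence([config.seed, i, rep]).generate_state(1)[0] % (2**31))
            cfg = replace(config, phi=float(phi), seed=seed)
            tc = simulate_dirt(cfg)
            s = summarize_timecourse(tc, bin_width)
            strengths[rep] = s.strength
            widths[rep] = s.half_max_width
            rec_counts[rep] = tc.receptor_absorbed
            astro_counts[rep] = tc.astro_absorbed + tc.cleared
        sem = lambda a: float(a.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
        out.append(DirtSummary(
            strength=float(strengths.mean()), half_max_width=float(widths.mean()),
            phi=float(phi), n_reps=reps,
            strength_sem=sem(strengths), width_sem=sem(widths),
            receptor_absorbed_mean=float(rec_counts.mean()),
            astro_absorbed_mean=float(astro_counts.mean()),
        ))
    return out


def fit_piecewise_linear(phis: Sequence[float], values: Sequence[float]) -> PiecewiseLinearFit:
    """Least-squares fit of a continuous plateau-then-line model.

    The model is constant for ``phi < breakpoint`` and linear for
    ``phi >= breakpoint`` (continuous at the breakpoint).  The breakpoint is
    found by scanning every candidate on the input grid and refining by
    golden-section search between the best candidate's neighbours.
    """
    phis = np.asarray(phis, dtype=float)
    values = np.asarray(values, dtype=float)
    if phis.size < 4:
        raise ValueError("need at least 4 points to fit a plateau-then-line model")
    order = np.argsort(phis)
    phis, values = phis[order], values[order]

    def solve(bp: float):
        design = np.column_stack([np.ones_like(phis), np.maximum(phis - bp, 0.0)])
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
        rss = float(np.sum((design @ coef - values) ** 2))
        return coef, rss

    candidates = phis.copy()
    rss_grid = np.array([solve(bp)[1] for bp in candidates])
    best = int(np.argmin(rss_grid))
    lo = candidates[max(best - 1, 0)]
    hi = candidates[min(best + 1, candidates.size - 1)]

    from scipy.optimize import minimize_scalar
    if hi > lo:
        res = minimize_scalar(lambda bp: solve(bp)[1], bounds=(lo, hi), method="bounded")
        bp = float(res.x) if res.fun <= rss_grid[best] else float(candidates[best])
    else:
        bp = float(candidates[best])
    coef, rss = solve(bp)
    return PiecewiseLinearFit(plateau=float(coef[0]), breakpoint=bp,
                              slope=float(coef[1]), residual=rss)
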