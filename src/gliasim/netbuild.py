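"""Recurrent connectivity builders for the balanced EIF networks.

Two architectures are supported:

* **Non-spatial**: every presynaptic neuron of population b sends exactly
  ``K_ab_out`` edges into population a, targets drawn uniformly without
  replacement (fixed out-degree; no self-connections or duplicates).
* **Spatial**: neurons sit on uniform grids normalized to the unit torus
  Gamma = [0, 1)^2.  Each presynaptic neuron draws ``K_ab_out`` 2D
  displacements from an isotropic wrapped Gaussian of width ``alpha`` and
  snaps each to the nearest grid site of the target population, so the
  expected number of contacts from a neuron at y onto a neuron at x is
  ``(K_ab_out / N_a) * g(x1 - y1; alpha) * g(x2 - y2; alpha)`` with g the
  wrapped Gaussian density.  Multiple contacts onto one target are allowed
  and counted with multiplicity.  A feedforward layer of Poisson neurons is
  wired the same way with its own width ``alpha_ffwd``.

Default parameters place both networks in the tightly balanced, strongly
coupled regime (dense O(1) connection probabilities, synaptic weights that
are O(1/sqrt(N)) after scaling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

Pop = str  # "e" or "i"


def _round_to_square(n: float) -> int:
    """Nearest perfect square to n (at least 1)."""
    r = max(1, round(math.sqrt(n)))
    candidates = [max(1, r - 1), r, r + 1]
    return int(min((abs(c * c - n), c * c) for c in candidates)[1])


@dataclass
class NetworkParams:
    """EIF network parameters (units: mV, ms, mV/ms; rates in Hz).

    ``k_out[(a, b)]`` is the exact number of outgoing connections each
    neuron of population b makes into population a; ``j[(a, b)]`` the
    corresponding synaptic weight in mV (positive for excitatory b,
    negative for inhibitory).  The unscaled weights are divided by
    sqrt(N) inside the simulator (strong-coupling regime).
    """

    n_e: int = 10_000
    n_i: int = 10_000
    n_f: int = 0
    tau_m_e: float = 15.0
    tau_m_i: float = 10.0
    v_th: float = -10.0
    v_t_soft: float = -50.0
    e_l: float = -60.0
    v_re: float = -65.0
    tau_ref_e: float = 1.5
    tau_ref_i: float = 0.5
    tau_syn_e: float = 5.0
    tau_syn_i: float = 4.0
    delta_t_e: float = 2.0
    delta_t_i: float = 0.5
    tau_s: float = 40.0
    m_e: float = 0.015
    m_i: float = 0.01
    sigma_s: float = 0.1
    r_f: float = 0.0
    k_out: Mapping[tuple[Pop, Pop], int] = field(default_factory=lambda: {
        ("e", "e"): 2500, ("i", "e"): 2500, ("e", "i"): 2500, ("i", "i"): 2500})
    j: Mapping[tuple[Pop, Pop], float] = field(default_factory=lambda: {
        ("e", "e"): 12.5, ("i", "e"): 20.0, ("e", "i"): -50.0, ("i", "i"): -50.0})
    j_ffwd: Mapping[Pop, float] = field(default_factory=dict)
    k_out_ffwd: Mapping[Pop, int] = field(default_factory=dict)
    alpha_rec: float = 0.05
    alpha_ffwd: float = 0.1

    def __post_init__(self) -> None:
        for (a, b), val in self.j.items():
            if b == "e" and val <= 0:
                raise ValueError(f"J[{a},{b}] must be positive, got {val}")
            if b == "i" and val >= 0:
                raise ValueError(f"J[{a},{b}] must be negative, got {val}")
        pop_n = {"e": self.n_e, "i": self.n_i}
        for (a, b), k in self.k_out.items():
            if k > pop_n[a]:
                raise ValueError(f"k_out[{a},{b}] = {k} exceeds target population size {pop_n[a]}")

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i

    @classmethod
    def nonspatial_defaults(cls) -> "NetworkParams":
        return cls()

    @classmethod
    def spatial_defaults(cls) -> "NetworkParams":
        """Spatial torus network driven by a Poisson feedforward layer.

        The feedforward weights and out-degrees are calibration constants,
        exposed in the config like every other parameter.  In the balanced
        state the excitatory rate is set by the feedforward drive
        difference, r_e ~ (F_e - F_i) / (W_ie - W_ee) with W the recurrent
        gains, so J_eF controls the operating rate almost directly; the
        defaults put the excitatory population near 5 Hz (inhibitory near
        9 Hz) with ~630 feedforward inputs per neuron.
        """
        return cls(
            n_e=40_000, n_i=10_000, n_f=5_625,
            tau_syn_e=6.0, tau_syn_i=5.0,
            tau_s=float("nan"), m_e=0.0, m_i=0.0, sigma_s=0.0, r_f=5.0,
            k_out={("e", "e"): 2000, ("i", "e"): 500,
                   ("e", "i"): 2000, ("i", "i"): 500},
            j={("e", "e"): 40.0, ("i", "e"): 120.0,
               ("e", "i"): -400.0, ("i", "i"): -400.0},
            j_ffwd={"e": 350.0, "i": 100.0},
            k_out_ffwd={"e": 4500, "i": 1125},
            alpha_rec=0.05, alpha_ffwd=0.1,
        )

    def scaled(self, scale: float, spatial: bool = False) -> "NetworkParams":
        """Scale population sizes and out-degrees by ``scale``.

        Weights and drive parameters are left unchanged: the 1/sqrt(N)
        coupling factor adjusts automatically, preserving the dense,
        strongly coupled regime.  Note that the shared-noise amplitude
        sigma_s is deliberately NOT scaled: the drive excursions that test
        the stability of E-I balance are part of the study conditions, and
        scaling them away suppresses the ensheathment-induced loss of
        balance.  A scaled network therefore sees relatively larger drive
        fluctuations than the full-size network (see docs/methods.md).
        Spatial population counts are rounded to the nearest perfect square.
        """
        if not (0 < scale <= 1):
            raise ValueError("scale must lie in (0, 1]")
        if spatial:
            n_e = _round_to_square(self.n_e * scale)
            n_i = _round_to_square(self.n_i * scale)
            n_f = _round_to_square(self.n_f * scale) if self.n_f else 0
        else:
            n_e = max(1, round(self.n_e * scale))
            n_i = max(1, round(self.n_i * scale))
            n_f = max(1, round(self.n_f * scale)) if self.n_f else 0
        k_out = {ab: max(1, round(k * scale)) for ab, k in self.k_out.items()}
        k_out_ffwd = {a: max(1, round(k * scale)) for a, k in self.k_out_ffwd.items()}
        return replace(self, n_e=n_e, n_i=n_i, n_f=n_f,
                       k_out=k_out, k_out_ffwd=k_out_ffwd)


@dataclass
class Connectivity:
    """Edge lists of a recurrent (and optionally feedforward) network.

    Neuron ids are global: 0..n_e-1 excitatory, n_e..n_e+n_i-1 inhibitory.
    Feedforward ids index the separate feedforward layer.
    """

    n_e: int
    n_i: int
    pre: np.ndarray
    post: np.ndarray
    positions: np.ndarray | None = None
    n_f: int = 0
    ffwd_pre: np.ndarray | None = None
    ffwd_post: np.ndarray | None = None
    ffwd_positions: np.ndarray | None = None

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i

    @property
    def pre_pop(self) -> np.ndarray:
        """0 for excitatory presynaptic neuron, 1 for inhibitory."""
        return (self.pre >= self.n_e).astype(np.int8)

    @property
    def post_pop(self) -> np.ndarray:
        return (self.post >= self.n_e).astype(np.int8)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.pre, minlength=self.n_total)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "pre_id": self.pre, "post_id": self.post,
            "pre_pop": np.where(self.pre_pop == 0, "E", "I"),
            "post_pop": np.where(self.post_pop == 0, "E", "I"),
        })


def build_nonspatial(params: NetworkParams, seed: int = 0) -> Connectivity:
    """Fixed-out-degree uniform random connectivity.

    Every presynaptic neuron of population b sends exactly ``k_out[(a, b)]``
    edges into population a, targets sampled uniformly without replacement
    and excluding the neuron itself.
    """
    rng = np.random.default_rng(seed)
    n_e, n_i = params.n_e, params.n_i
    offsets = {"e": 0, "i": n_e}
    sizes = {"e": n_e, "i": n_i}
    pres, posts = [], []
    for b in ("e", "i"):
        for j_pre in range(offsets[b], offsets[b] + sizes[b]):
            for a in ("e", "i"):
                k = params.k_out[(a, b)]
                if k == 0:
                    continue
                n_a = sizes[a]
                self_local = j_pre - offsets[a] if a == b else -1
                if self_local >= 0:
                    if k > n_a - 1:
                        raise ValueError("k_out too large to exclude self-connections")
                    idx = rng.choice(n_a - 1, size=k, replace=False)
                    idx = np.where(idx >= self_local, idx + 1, idx)
                else:
                    idx = rng.choice(n_a, size=k, replace=False)
                pres.append(np.full(k, j_pre, dtype=np.int32))
                posts.append((idx + offsets[a]).astype(np.int32))
    pre = np.concatenate(pres) if pres else np.empty(0, np.int32)
    post = np.concatenate(posts) if posts else np.empty(0, np.int32)
    return Connectivity(n_e=n_e, n_i=n_i, pre=pre, post=post)


def wrapped_gaussian(u, alpha: float):
    """Wrapped Gaussian density on the unit circle, g(u; alpha).

    ``g(u; alpha) = sum_k N(u + k; 0, alpha^2)`` with the sum truncated once
    additional terms fall below 1e-12.  Periodic with period 1, symmetric
    about 0 and 1/2, and integrates to 1 over one period.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    u = np.asarray(u, dtype=float)
    k_max = int(np.ceil(8.0 * alpha)) + 1
    ks = np.arange(-k_max, k_max + 1)
    z = u[..., None] + ks
    dens = np.exp(-0.5 * (z / alpha) ** 2) / (alpha * np.sqrt(2 * np.pi))
    return dens.sum(axis=-1)


def torus_distance(x, y) -> np.ndarray:
    """Euclidean distance on the unit torus (per-coordinate wrap-around)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.abs(x - y)
    d = np.minimum(d, 1.0 - d)
    return np.sqrt((d * d).sum(axis=-1))


def _grid_positions(n: int, offset: tuple[float, float]) -> np.ndarray:
    m = int(round(math.sqrt(n)))
    if m * m != n:
        raise ValueError(f"population size {n} is not a perfect square")
    gx, gy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    pos = np.column_stack([(gx.ravel() + 0.5) / m, (gy.ravel() + 0.5) / m])
    return np.mod(pos + np.asarray(offset), 1.0)


def _wrapped_targets(pos_pre: np.ndarray, k: int, alpha: float, m_post: int,
                     rng: np.random.Generator,
                     offset: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Sample k wrapped-Gaussian displacements per presynaptic neuron and
    snap to the nearest site of an m_post x m_post target grid (returns
    local target indices, shape (n_pre, k))."""
    n_pre = pos_pre.shape[0]
    disp = rng.normal(0.0, alpha, size=(n_pre, k, 2))
    # work in the target grid frame: site g has coordinate (g + 0.5)/m + offset
    tgt = pos_pre[:, None, :] + disp - np.asarray(offset)
    g = np.mod(np.rint(tgt * m_post - 0.5).astype(np.int64), m_post)
    return g[..., 0] * m_post + g[..., 1]


def build_spatial(params: NetworkParams, seed: int = 0,
                  grid_offset: tuple[float, float] = (0.0, 0.0)) -> Connectivity:
    """Wrapped-Gaussian connectivity on the unit torus.

    Recurrent projections use width ``alpha_rec`` for both populations; the
    feedforward layer (if ``n_f > 0``) uses ``alpha_ffwd``.  Out-degrees are
    exact; contacts onto one target carry multiplicity.
    """
    rng = np.random.default_rng(seed)
    n_e, n_i, n_f = params.n_e, params.n_i, params.n_f
    pos_e = _grid_positions(n_e, grid_offset)
    pos_i = _grid_positions(n_i, grid_offset)
    positions = np.vstack([pos_e, pos_i])
    m = {"e": int(round(math.sqrt(n_e))), "i": int(round(math.sqrt(n_i)))}
    offsets = {"e": 0, "i": n_e}
    pos = {"e": pos_e, "i": pos_i}

    pres, posts = [], []
    for b in ("e", "i"):
        for a in ("e", "i"):
            k = params.k_out[(a, b)]
            if k == 0:
                continue
            tgt = _wrapped_targets(pos[b], k, params.alpha_rec, m[a], rng, grid_offset)
            n_pre = pos[b].shape[0]
            pres.append(np.repeat(np.arange(n_pre, dtype=np.int32) + offsets[b], k))
            posts.append((tgt.ravel() + offsets[a]).astype(np.int32))
    pre = np.concatenate(pres)
    post = np.concatenate(posts)

    ffwd_pre = ffwd_post = ffwd_positions = None
    if n_f > 0:
        ffwd_positions = _grid_positions(n_f, grid_offset)
        fp, fq = [], []
        for a in ("e", "i"):
            k = params.k_out_ffwd.get(a, 0)
            if k == 0:
                continue
            tgt = _wrapped_targets(ffwd_positions, k, params.alpha_ffwd, m[a], rng, grid_offset)
            fp.append(np.repeat(np.arange(n_f, dtype=np.int32), k))
            fq.append((tgt.ravel() + offsets[a]).astype(np.int32))
        ffwd_pre = np.concatenate(fp)
        ffwd_post = np.concatenate(fq)

    return Connectivity(n_e=n_e, n_i=n_i, pre=pre, post=post,
                        positions=positions, n_f=n_f,
                        ffwd_pre=ffwd_pre, ffwd_post=ffwd_post,
                        ffwd_positions=ffwd_positions)
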