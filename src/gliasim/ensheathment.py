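"""The "effective astrocyte": per-synapse ensheathment and its (J, tau) map.

Microscale simulations show an ensheathed synapse is weaker and faster in
proportion to the astrocyte's protrusion.  At network level this is encoded
by a single ensheathment strength ``s_en`` in [0, 1): an ensheathed synapse
from population b to a has

    J_eff  = J_ab * (1 - s_en),      tau_eff = tau_b * (1 - s_en),

while an unsheathed synapse keeps the default parameters.  Each recurrent
synapse is independently ensheathed with probability ``p_e`` (excitatory
presynaptic neuron) or ``p_i`` (inhibitory); feedforward synapses are never
ensheathed.  Variant modes scale only J or only tau, used to dissociate the
roles of synaptic strength and kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODES = ("both", "j_only", "tau_only")


@dataclass
class EnsheathmentParams:
    """Global ensheathment condition of a network.

    s_en : float in [0, 1)
        Strength of ensheathment; kept below 1 so connections are never
        effectively removed (dense connectivity is preserved).
    p_e, p_i : float in [0, 1]
        Probability that a synapse with an excitatory (inhibitory)
        presynaptic neuron is ensheathed.
    mode : {"both", "j_only", "tau_only"}
        Which synaptic parameters ensheathment scales.
    """

    s_en: float = 0.0
    p_e: float = 0.0
    p_i: float = 0.0
    seed: int = 0
    mode: str = "both"

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_en < 1.0):
            raise ValueError(f"s_en must lie in [0, 1), got {self.s_en}")
        for name, p in (("p_e", self.p_e), ("p_i", self.p_i)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def j_factor(self) -> float:
        """Multiplier applied to J at an ensheathed synapse."""
        return 1.0 - self.s_en if self.mode in ("both", "j_only") else 1.0

    @property
    def tau_factor(self) -> float:
        """Multiplier applied to tau at an ensheathed synapse."""
        return 1.0 - self.s_en if self.mode in ("both", "tau_only") else 1.0


def assign_ensheathment(pre_pop: np.ndarray, params: EnsheathmentParams) -> np.ndarray:
    """Flag each recurrent synapse as ensheathed or not.

    ``pre_pop`` holds the presynaptic population per edge (0 = E, 1 = I).
    Each edge is flagged independently with probability ``p_e`` or ``p_i``.
    The draw depends only on ``(seed, p_e, p_i)`` and the edge order, not on
    the variant mode, so j_only / tau_only / both comparisons share the
    identical ensheathed set.
    """
    pre_pop = np.asarray(pre_pop)
    rng = np.random.default_rng(params.seed)
    u = rng.random(pre_pop.shape[0])
    p_edge = np.where(pre_pop == 0, params.p_e, params.p_i)
    return u < p_edge


def effective_params(j_base: float, tau_base: float, s_en: float,
                     ensheathed: bool, mode: str = "both") -> tuple[float, float]:
    """Map base (J, tau) of one synapse to its effective values."""
    if not (0.0 <= s_en < 1.0):
        raise ValueError(f"s_en must lie in [0, 1), got {s_en}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not ensheathed:
        return j_base, tau_base
    jf = 1.0 - s_en if mode in ("both", "j_only") else 1.0
    tf = 1.0 - s_en if mode in ("both", "tau_only") else 1.0
    return j_base * jf, tau_base * tf


def naive_mean_field_strength(s_en: float, p: float) -> float:
    """Homogeneous-network surrogate for heterogeneous ensheathment.

    Averaging the per-synapse scaling over the population gives an effective
    uniform ensheathment strength s_hat = s_en * p (the ensheathed fraction p
    contributes s_en, the rest contributes 0).  Networks along an isoline of
    s_hat behave very differently, which is the sense in which this mean
    field is naive.
    """
    return s_en * p
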