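"""Parkinsonian lesioning of the SNc population and dopamine routing.

A lesion kills a seeded random subset of SNc neurons by clamping their
membrane potential at rest, which silences their terminals.  Two disease
routings are distinguished: in PD1 the dopamine deficit affects the
striatum only (the STN lateral coupling still follows the *computed*
value difference), while in PD2 it affects both striatum and STN (the
STN lateral coupling follows the dopamine-derived value difference, which
collapses as cells die).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .snc_dopamine import DANetworkState, V_DEAD

__all__ = ["LesionConfig", "EpsilonMap", "apply_lesion", "epsilon_s_source"]

MODES = ("control", "PD1", "PD2")


@dataclass(frozen=True)
class LesionConfig:
    """Lesion mode, percentage of *surviving* SNc cells and selection seed."""

    mode: str = "control"
    P_SNc: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not (0.0 < self.P_SNc <= 100.0):
            raise ValueError("P_SNc must be in (0, 100]")
        if self.mode == "control" and self.P_SNc != 100.0:
            raise ValueError("control implies P_SNc = 100")

    @property
    def cell_loss_percent(self) -> float:
        return 100.0 - self.P_SNc


def apply_lesion(network: DANetworkState, cfg: LesionConfig) -> DANetworkState:
    """Kill ``round(N * (1 - P_SNc/100))`` neurons, selected uniformly
    without replacement under the lesion seed; returns a new state with the
    dead cells voltage-clamped and their terminals silenced."""
    out = network.copy()
    n_dead = int(round(network.n * (1.0 - cfg.P_SNc / 100.0)))
    if n_dead == 0:
        return out
    rng = np.random.default_rng(cfg.seed)
    dead = rng.choice(network.n, size=n_dead, replace=False)
    out.alive = out.alive.copy()
    out.alive[dead] = False
    out.V[dead] = V_DEAD
    out.w[dead] = 0.0
    out.Ca[dead] = 0.0
    for arr in (out.LDOPA, out.DA_c, out.DA_v, out.DA_e):
        arr[dead] = 0.0
    return out


@dataclass(frozen=True)
class EpsilonMap:
    """Calibrated affine, clipped map from a value difference to the STN
    lateral strength.

    Lower dopamine-derived value difference means weaker nigral control of
    STN and stronger lateral coupling, hence more synchrony; the map is
    therefore decreasing in its argument.
    """

    eps_lo: float = 0.2    # coupling at/above the healthy operating point
    eps_hi: float = 2.5    # coupling for a fully collapsed dopamine signal
    delta_lo: float = -0.056   # value difference mapped to eps_hi
    delta_hi: float = -0.034   # value difference mapped to eps_lo

    def __call__(self, delta_v: float) -> float:
        if self.delta_hi <= self.delta_lo:
            return self.eps_lo
        frac = (self.delta_hi - delta_v) / (self.delta_hi - self.delta_lo)
        frac = float(np.clip(frac, 0.0, 1.0))
        return self.eps_lo + frac * (self.eps_hi - self.eps_lo)


def epsilon_s_source(
    cfg: LesionConfig,
    delta_v: float,
    delta_v_snc: float,
    eps_map: EpsilonMap,
) -> float:
    """STN lateral strength for the current instant.

    Control and PD2 route the dopamine-derived value difference into the
    STN (the nigro-subthalamic pathway); PD1 leaves that pathway intact by
    definition, so the computed value difference is used instead.
    """
    if cfg.mode == "PD1":
        return eps_map(delta_v)
    return eps_map(delta_v_snc)
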