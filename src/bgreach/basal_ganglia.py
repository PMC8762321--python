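"""Value computation, dopamine-gated pathway routing and STN-GPe dynamics.

The striatum evaluates the hand position with a Gaussian value function of
the hand-target distance and gates the cortical difference signal into
the direct (D1, "Go") and indirect (D2, "NoGo"/"Explore") pathways with
complementary sigmoids of the dopamine-derived value difference.  The
indirect pathway drives an excitatory-inhibitory STN-GPe lattice whose
irregular oscillations supply the exploratory drive; GPi linearly
combines the two pathways.

The STN-GPe lattice integrates with explicit Euler at a fine timestep
(0.02 ms by default) for 2500 iterations per 50-ms behavioural step.
Lateral connections are Gaussian without inhibition; mild seeded
heterogeneity of the unit time constants gives the population a frequency
dispersion, so weak lateral coupling leaves the phases scattered while
strong coupling locks the lattice -- the synchrony read-out therefore
grows with the STN lateral strength ``eps_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cortical_maps import make_gaussian_kernel
from .metrics import synchrony as _synchrony

__all__ = [
    "MSNGating",
    "STNGPeNetwork",
    "compute_value",
    "value_difference",
    "msn_gating",
    "striatal_outputs",
    "stn_gpe_step",
    "run_stn_gpe_window",
    "synchrony_vs_coupling_curve",
    "gpi_combine",
]


def compute_value(X_arm: np.ndarray, X_targ: np.ndarray, sigma_V: float) -> float:
    """Gaussian value of the hand position: 1 at the target, decaying with
    squared distance over the spatial sensitivity ``sigma_V`` (m)."""
    d2 = float(np.sum((np.asarray(X_targ, float) - np.asarray(X_arm, float)) ** 2))
    return float(np.exp(-d2 / sigma_V**2))


def value_difference(v_now: float, v_prev: float) -> float:
    """Temporal difference of the value signal."""
    return float(v_now - v_prev)


@dataclass(frozen=True)
class MSNGating:
    """Sigmoid gains/thresholds of the D1 and D2 medium spiny neurons.

    The D2 gain is the negative of the D1 gain, so with equal thresholds
    the two gating values are complementary: ``lambda_D1 + lambda_D2 = 1``.
    """

    a_D1: float = 25.0
    theta_D1: float = 0.0
    theta_D2: float = 0.0

    @property
    def a_D2(self) -> float:
        return -self.a_D1


def msn_gating(delta_v_snc: float, gating: MSNGating) -> tuple[float, float]:
    """Dopamine gating of the two pathways.

    Positive dopamine-derived value difference selects the direct
    pathway, negative the indirect pathway.
    """
    lam_d1 = 1.0 / (1.0 + np.exp(-gating.a_D1 * (delta_v_snc - gating.theta_D1)))
    lam_d2 = 1.0 / (1.0 + np.exp(-gating.a_D2 * (delta_v_snc - gating.theta_D2)))
    return float(lam_d1), float(lam_d2)


def striatal_outputs(
    delta_g_mc: np.ndarray,
    lam_d1: float,
    lam_d2: float,
    gain_d1: float = 1.0,
    gain_d2: float = 1.0,
    W_d1: np.ndarray | None = None,
    W_d2: np.ndarray | None = None,
    y_sat: float = np.inf,
    y_sat_d1: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gated striatal outputs of the cortical difference signal.

    The corticostriatal weights default to the identity scaled by the
    pathway gains (no corticostriatal learning).  MSN outputs are firing
    rates: only the positive part of the cortical signal is transmitted,
    and the rate saturates smoothly at ``y_sat``.
    """
    x = np.asarray(delta_g_mc, float)
    flat = x.ravel()
    y1 = (W_d1 @ flat).reshape(x.shape) if W_d1 is not None else x
    y2 = (W_d2 @ flat).reshape(x.shape) if W_d2 is not None else x
    y1 = gain_d1 * np.maximum(y1, 0.0)
    y2 = gain_d2 * np.maximum(y2, 0.0)
    sat1 = y_sat if y_sat_d1 is None else y_sat_d1
    if np.isfinite(sat1):
        y1 = sat1 * np.tanh(y1 / sat1)
    if np.isfinite(y_sat):
        y2 = y_sat * np.tanh(y2 / y_sat)
    return lam_d1 * y1, lam_d2 * y2


# ---------------------------------------------------------------------------
# STN-GPe lattice
# ---------------------------------------------------------------------------

@dataclass
class STNGPeNetwork:
    """Coupled excitatory (STN) / inhibitory (GPe) lattices.

    ``eps_s`` scales the STN lateral excitation (the dopamine-controlled
    knob); ``tau_jitter`` is the fractional spread of per-unit time
    constants that desynchronises weak-coupling regimes.
    """

    N: int = 8
    tau_GPe: float = 15.0      # ms
    tau_STN: float = 15.0      # ms
    eps_g: float = 0.2
    eps_s: float = 1.2
    w_sg: float = 1.6
    w_gs: float = 1.6
    lambda_STN: float = 3.0
    sigma_lat_g: float = 1.2
    sigma_lat_s: float = 1.2
    tau_jitter: float = 0.08
    self_excitation: bool = False  # include autapse (kernel centre) terms
    noise_amp: float = 0.0     # intrinsic noise current (0 = deterministic)
    noise_every: int = 25      # internal steps per frozen noise sample
    seed: int = 0
    x_GPe: np.ndarray = field(default=None)  # type: ignore[assignment]
    x_STN: np.ndarray = field(default=None)  # type: ignore[assignment]
    _L_g: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _L_s: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _tau_g: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _tau_s: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tau_GPe <= 0 or self.tau_STN <= 0:
            raise ValueError("time constants must be > 0")
        n2 = self.N * self.N
        rng = np.random.default_rng(self.seed)
        if self.x_GPe is None:
            self.x_GPe = 0.1 * rng.standard_normal(n2)
        else:
            self.x_GPe = np.asarray(self.x_GPe, float).ravel().copy()
        if self.x_STN is None:
            self.x_STN = 0.1 * rng.standard_normal(n2)
        else:
            self.x_STN = np.asarray(self.x_STN, float).ravel().copy()
        self._L_g = _lateral_matrix(self.N, self.sigma_lat_g, self.self_excitation)
        self._L_s = _lateral_matrix(self.N, self.sigma_lat_s, self.self_excitation)
        jit_g = 1.0 + self.tau_jitter * rng.uniform(-1, 1, n2)
        jit_s = 1.0 + self.tau_jitter * rng.uniform(-1, 1, n2)
        self._tau_g = self.tau_GPe * jit_g
        self._tau_s = self.tau_STN * jit_s
        self._noise_rng = rng

    @property
    def y_STN(self) -> np.ndarray:
        return np.tanh(self.lambda_STN * self.x_STN)

    def y_STN_grid(self) -> np.ndarray:
        return self.y_STN.reshape(self.N, self.N)


def _lateral_matrix(N: int, sigma: float, include_self: bool = False) -> np.ndarray:
    """Dense circular-convolution operator for the Gaussian lateral kernel.

    Lateral connectivity couples a unit to its *neighbours*; by default the
    centre (autapse) term is excluded, so the coupling strength never feeds
    a unit back onto itself.
    """
    kernel = make_gaussian_kernel(N, sigma=sigma, form="gauss")
    if not include_self:
        kernel = kernel.copy()
        kernel[0, 0] = 0.0
    n2 = N * N
    out = np.empty((n2, n2))
    for k in range(N):
        for l_ in range(N):
            shifted = np.roll(np.roll(kernel, k, axis=0), l_, axis=1)
            out[k * N + l_] = shifted.ravel()
    return out


def stn_gpe_step(net: STNGPeNetwork, y_D2: np.ndarray, dt: float) -> None:
    """One Euler step of the coupled lattices; mutates the network state."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    u = np.asarray(y_D2, float).ravel()
    y = np.tanh(net.lambda_STN * net.x_STN)
    dxg = (-net.x_GPe + net.eps_g * (net._L_g @ net.x_GPe) + net.w_sg * y + u) / net._tau_g
    dxs = (-net.x_STN + net.eps_s * (net._L_s @ y) - net.w_gs * net.x_GPe) / net._tau_s
    net.x_GPe = net.x_GPe + dt * dxg
    net.x_STN = net.x_STN + dt * dxs
    if not (np.all(np.isfinite(net.x_GPe)) and np.all(np.isfinite(net.x_STN))):
        raise ArithmeticError("STN-GPe state blew up; reduce dt")


def run_stn_gpe_window(
    net: STNGPeNetwork,
    y_D2: np.ndarray,
    dt: float,
    n_steps: int,
    record_every: int = 0,
) -> np.ndarray | None:
    """Advance the lattice ``n_steps`` with the striatal drive held fixed.

    With ``record_every=k`` the STN output of every unit is recorded every
    k-th step; returns an array of shape (n_units, n_records) or ``None``.
    """
    from . import _fastpath as _fp

    u = np.asarray(y_D2, float).ravel()
    lam = net.lambda_STN
    n2 = net.N * net.N
    n_chunks = n_steps // net.noise_every + 1
    if net.noise_amp > 0:
        noise_g = net.noise_amp * net._noise_rng.standard_normal((n_chunks, n2))
        noise_s = net.noise_amp * net._noise_rng.standard_normal((n_chunks, n2))
    else:
        noise_g = np.zeros((n_chunks, n2))
        noise_s = np.zeros((n_chunks, n2))

    if _fp.HAVE_NUMBA:
        n_rec_max = n_steps // record_every if record_every else 0
        records = np.empty((n2, max(n_rec_max, 1)))
        _fp.stn_gpe_window_kernel(
            net.x_GPe, net.x_STN, u, net._L_g * net.eps_g, net._L_s,
            net._tau_g, net._tau_s, net.eps_s, net.w_sg, net.w_gs,
            lam, dt, n_steps, record_every, records,
            noise_g, noise_s, net.noise_every,
        )
        if not (np.all(np.isfinite(net.x_GPe)) and np.all(np.isfinite(net.x_STN))):
            raise ArithmeticError("STN-GPe state blew up; reduce dt")
        return records[:, :n_rec_max] if record_every else None

    wg = dt / net._tau_g
    ws = dt / net._tau_s
    Lg = net._L_g * net.eps_g
    Ls = net._L_s
    eps_s = net.eps_s
    xg, xs = net.x_GPe, net.x_STN
    records = [] if record_every else None
    for i in range(n_steps):
        chunk = i // net.noise_every
        y = np.tanh(lam * xs)
        xg_new = xg + wg * (-xg + Lg @ xg + net.w_sg * y + u + noise_g[chunk])
        xs = xs + ws * (-xs + eps_s * (Ls @ y) - net.w_gs * xg + noise_s[chunk])
        xg = xg_new
        if record_every and (i + 1) % record_every == 0:
            records.append(np.tanh(lam * xs))
    net.x_GPe, net.x_STN = xg, xs
    if not (np.all(np.isfinite(xg)) and np.all(np.isfinite(xs))):
        raise ArithmeticError("STN-GPe state blew up; reduce dt")
    if records is not None:
        return np.asarray(records).T
    return None


def synchrony_vs_coupling_curve(
    eps_values: np.ndarray,
    duration_ms: float = 1000.0,
    dt: float = 0.02,
    N: int = 8,
    seed: int = 0,
    record_every: int = 25,
    settle_ms: float = 200.0,
    **net_kwargs,
) -> np.ndarray:
    """Mean-field synchrony of the STN lattice at each lateral strength.

    Runs an unforced lattice from a seeded random state at each ``eps_s``,
    discards a settling transient, and reports the variance-of-mean-field
    synchrony.  Used to calibrate the dopamine -> ``eps_s`` map.
    """
    eps_values = np.atleast_1d(np.asarray(eps_values, float))
    if eps_values.size < 1 or duration_ms <= 0:
        raise ValueError("need >= 1 eps_s value and positive duration")
    out = np.empty(eps_values.size)
    n_settle = int(round(settle_ms / dt))
    n_run = int(round(duration_ms / dt))
    zero = np.zeros(N * N)
    for i, eps in enumerate(eps_values):
        net = STNGPeNetwork(N=N, eps_s=float(eps), seed=seed, **net_kwargs)
        run_stn_gpe_window(net, zero, dt, n_settle)
        traces = run_stn_gpe_window(net, zero, dt, n_run, record_every=record_every)
        out[i] = _synchrony(traces)
    return out


def gpi_combine(
    y_D1: np.ndarray, y_STN: np.ndarray, A_D1: float, A_D2: float
) -> np.ndarray:
    """GPi output: direct-pathway drive minus the STN contribution."""
    y1 = np.asarray(y_D1, float)
    ys = np.asarray(y_STN, float)
    if y1.shape != ys.shape:
        raise ValueError("GPi inputs must share a shape")
    return A_D1 * y1 - A_D2 * ys
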