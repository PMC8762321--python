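"""Cortical representations: self-organising maps and attractor lattices.

The proprioceptive cortex (PC), prefrontal cortex (PFC) and the feature
layer of the motor cortex (MC) are Kohonen self-organising maps (SOMs)
responding with a Gaussian of the input-to-weight distance.  The MC
proper and the thalamus are continuous attractor neural networks (CANNs):
square lattices with short-range excitation, global inhibition and
divisive output normalisation, integrated with explicit Euler and
circular (wrap-around) boundaries.  Inter-map projections (PFC->MC,
MC->motor neurons) are linear maps trained with outer-product delta
rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SOMNetwork",
    "CANNNetwork",
    "ProjectionGains",
    "som_activation",
    "train_som",
    "quantization_error",
    "make_gaussian_kernel",
    "cann_step",
    "cann_output",
    "mc_total_input",
    "pfc_drive",
    "train_pfc_to_mc",
    "mn_activation",
    "train_mc_to_mn",
]


# ---------------------------------------------------------------------------
# Self-organising maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SOMNetwork:
    """An N x N grid of weight vectors with Gaussian response width."""

    W: np.ndarray          # (N, N, d)
    sigma_resp: float

    def __post_init__(self) -> None:
        w = np.asarray(self.W, float)
        if w.ndim != 3 or w.shape[0] != w.shape[1]:
            raise ValueError("SOM weights must be (N, N, d)")
        if not np.all(np.isfinite(w)):
            raise ValueError("SOM weights must be finite")
        if self.sigma_resp <= 0:
            raise ValueError("sigma_resp must be > 0")
        object.__setattr__(self, "W", w)

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def dim(self) -> int:
        return self.W.shape[2]


def som_activation(x: np.ndarray, som: SOMNetwork) -> np.ndarray:
    """Gaussian response grid ``U_ij = exp(-||x - W_ij||^2 / sigma^2)``."""
    x = np.asarray(x, float).ravel()
    if x.shape[0] != som.dim:
        raise ValueError(f"input dim {x.shape[0]} != SOM dim {som.dim}")
    d2 = np.sum((som.W - x[None, None, :]) ** 2, axis=2)
    return np.exp(-d2 / som.sigma_resp**2)


def _grid_coords(N: int) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    return np.stack([ii, jj], axis=-1).astype(float)


def train_som(
    som: SOMNetwork,
    samples: np.ndarray,
    n_epochs: int = 10,
    rate_start: float = 0.5,
    rate_end: float = 0.01,
    radius_start: float | None = None,
    radius_end: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> SOMNetwork:
    """Online Kohonen training with exponentially decaying rate and radius.

    Each epoch presents every sample once in a seeded random order; the
    best-matching unit and its Gaussian neighbourhood move toward the
    sample.  Deterministic under a fixed seed.
    """
    X = np.atleast_2d(np.asarray(samples, float))
    if X.shape[0] < 1:
        raise ValueError("training needs at least one sample")
    if X.shape[1] != som.dim:
        raise ValueError("sample dim mismatch")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    N = som.N
    W = som.W.copy()
    coords = _grid_coords(N)
    r0 = radius_start if radius_start is not None else N / 2.0
    total = n_epochs * X.shape[0]
    step = 0
    for _ in range(n_epochs):
        for idx in rng.permutation(X.shape[0]):
            frac = step / max(total - 1, 1)
            rate = rate_start * (rate_end / rate_start) ** frac
            radius = r0 * (radius_end / r0) ** frac
            x = X[idx]
            d2 = np.sum((W - x[None, None, :]) ** 2, axis=2)
            bi, bj = np.unravel_index(np.argmin(d2), d2.shape)
            g2 = np.sum((coords - coords[bi, bj]) ** 2, axis=2)
            h = np.exp(-g2 / (2 * radius**2))
            W += rate * h[:, :, None] * (x[None, None, :] - W)
            step += 1
    return replace(som, W=W)


def quantization_error(som: SOMNetwork, samples: np.ndarray) -> float:
    """Mean distance from each sample to its best-matching weight vector."""
    X = np.atleast_2d(np.asarray(samples, float))
    flat = som.W.reshape(-1, som.dim)
    d = np.sqrt(((X[:, None, :] - flat[None, :, :]) ** 2).sum(axis=2))
    return float(d.min(axis=1).mean())


# ---------------------------------------------------------------------------
# Lateral kernels and CANN dynamics
# ---------------------------------------------------------------------------

def make_gaussian_kernel(
    N: int,
    A: float = 1.0,
    sigma: float = 1.0,
    K: float = 0.0,
    form: str = "excite-inhibit",
) -> np.ndarray:
    """Full-lattice lateral kernel centred on the (0, 0) node.

    ``form="excite-inhibit"``: ``A * exp(-d^2 / (2 sigma^2)) - K`` --
    short-range excitation with uniform global inhibition (cortical and
    thalamic CANNs).  ``form="gauss"``: ``exp(-d^2 / sigma^2)`` with unit
    amplitude and no inhibition (STN/GPe lateral spread).  Distances use
    circular (torus) geometry so the kernel can be applied by circular
    convolution.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    idx = np.arange(N)
    d = np.minimum(idx, N - idx).astype(float)  # circular distance per axis
    d2 = d[:, None] ** 2 + d[None, :] ** 2
    if form == "excite-inhibit":
        return A * np.exp(-d2 / (2.0 * sigma**2)) - K
    if form == "gauss":
        return np.exp(-d2 / sigma**2)
    raise ValueError(f"unknown kernel form: {form!r}")


def circular_convolve(grid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2-D circular convolution of equal-shaped grids via the FFT."""
    return np.real(np.fft.ifft2(np.fft.fft2(grid) * np.fft.fft2(kernel)))


@dataclass
class CANNNetwork:
    """Lattice with local excitation, global inhibition and divisive output.

    The internal state ``g`` relaxes toward recurrent plus external input
    with time constant ``tau`` (ms); the output is
    ``G = g^2 / (1 + (2 pi / N^2) * b * sum(g^2))``.
    """

    N: int
    tau: float = 150.0       # ms
    A_lat: float = 1.0
    sigma_lat: float = 1.5
    K: float = 0.2
    b: float = 1.0
    g: np.ndarray = field(default=None)  # type: ignore[assignment]
    _kernel_fft: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.g is None:
            self.g = np.zeros((self.N, self.N))
        kernel = make_gaussian_kernel(self.N, self.A_lat, self.sigma_lat, self.K)
        self._kernel_fft = np.fft.fft2(kernel)

    def reset(self) -> None:
        self.g = np.zeros((self.N, self.N))


def cann_output(net: CANNNetwork) -> np.ndarray:
    """Divisively normalised squared output ``G`` of the lattice."""
    g2 = net.g**2
    denom = 1.0 + (2.0 * np.pi / net.N**2) * net.b * g2.sum()
    return g2 / denom


def cann_step(net: CANNNetwork, I_ext: np.ndarray, dt: float) -> np.ndarray:
    """One Euler step; mutates ``net.g`` and returns the new output grid."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    I_ext = np.asarray(I_ext, float)
    if I_ext.shape != net.g.shape:
        raise ValueError("input grid shape mismatch")
    G = cann_output(net)
    rec = np.real(np.fft.ifft2(np.fft.fft2(G) * net._kernel_fft))
    net.g = net.g + (dt / net.tau) * (-net.g + rec + I_ext)
    if not np.all(np.isfinite(net.g)):
        raise ArithmeticError("CANN state blew up; reduce dt or gains")
    return cann_output(net)


# ---------------------------------------------------------------------------
# Inter-map projections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProjectionGains:
    """Afferent gains of the MC CANN and the motor-neuron readout."""

    A_PC: float = 1.0
    A_PFC: float = 1.0
    A_BG: float = 1.0
    A_MN: float = 1.0


def mc_total_input(
    G_PC: np.ndarray, G_PFC: np.ndarray, G_BG: np.ndarray, gains: ProjectionGains
) -> np.ndarray:
    """Weighted sum of proprioceptive, prefrontal and BG drive to MC."""
    if not (G_PC.shape == G_PFC.shape == G_BG.shape):
        raise ValueError("MC input grids must share a shape")
    return gains.A_PC * G_PC + gains.A_PFC * G_PFC + gains.A_BG * G_BG


def pfc_drive(U_PFC: np.ndarray, W_pfc_mc: np.ndarray) -> np.ndarray:
    """Linear PFC->MC drive, reshaped to the MC grid.

    ``W_pfc_mc`` has shape (N_MC^2, N_PFC^2); ``U_PFC`` is the PFC SOM
    activation grid.
    """
    u = np.asarray(U_PFC, float).ravel()
    if W_pfc_mc.shape[1] != u.shape[0]:
        raise ValueError("PFC->MC weight shape mismatch")
    n_mc = int(np.sqrt(W_pfc_mc.shape[0]))
    return (W_pfc_mc @ u).reshape(n_mc, n_mc)


def train_pfc_to_mc(
    W: np.ndarray,
    U_PFC: np.ndarray,
    G_MC_target: np.ndarray,
    G_MC_pfc: np.ndarray,
    eta: float,
) -> np.ndarray:
    """Outer-product delta rule moving the PFC-driven MC pattern toward the
    pattern observed at a successful reach.

    Callers apply this only when the hand is inside the reach threshold.
    """
    err = (np.asarray(G_MC_target, float) - np.asarray(G_MC_pfc, float)).ravel()
    u = np.asarray(U_PFC, float).ravel()
    return W + eta * np.outer(err, u)


def mn_activation(
    G_MC: np.ndarray,
    W_mc_mn: np.ndarray,
    A_MN: float,
    normalize: bool = True,
) -> np.ndarray:
    """Motor-neuron activations: clipped linear readout of the MC output.

    With ``normalize=True`` (the default) the MC output is divided by its
    total activity before the readout -- a population-vector decode, so
    mixtures of activity bumps map to amplitude-weighted averages of the
    postures they encode instead of amplitude-dependent distortions.
    """
    g = np.asarray(G_MC, float).ravel()
    if W_mc_mn.shape != (4, g.shape[0]):
        raise ValueError("MC->MN weight shape mismatch")
    if normalize:
        total = g.sum()
        if total > 0:
            g = g / total
    return np.clip(A_MN * (W_mc_mn @ g), 0.0, 1.0)


def train_mc_to_mn(
    W: np.ndarray,
    phi_desired: np.ndarray,
    phi_actual: np.ndarray,
    G_MC: np.ndarray,
    eta: float,
) -> np.ndarray:
    """Supervised delta rule on the MC->MN readout."""
    err = np.asarray(phi_desired, float) - np.asarray(phi_actual, float)
    g = np.asarray(G_MC, float).ravel()
    return W + eta * np.outer(err, g)
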