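"""Kinematic two-link arm driven by four antagonist muscle activations.

The arm has a shoulder and an elbow joint, each controlled by an
agonist/antagonist muscle pair.  Motor-neuron activations are mapped to
joint angles, joint angles to muscle lengths (the proprioceptive feature
vector) and to the planar end-effector position.  The model is purely
kinematic: no inertia, torque, or gravity; hand velocity and acceleration
are finite differences of the end-effector position at the behavioural
timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArmGeometry",
    "MuscleActivations",
    "ArmState",
    "activations_to_joint_angles",
    "joint_angles_to_muscle_lengths",
    "forward_kinematics",
    "arm_state_from_activations",
    "reachable_workspace_samples",
    "inverse_kinematics",
    "complementary_activations",
]


@dataclass(frozen=True)
class ArmGeometry:
    """Link lengths and muscle moment-lever distances, all in metres.

    ``l_S`` is the shoulder-to-elbow distance, ``l_E`` the elbow-to-hand
    distance.  ``a_S``/``b_S`` and ``a_E``/``b_E`` are the distances from
    the shoulder and elbow joint centres to the attachment points of the
    corresponding muscle levers.
    """

    l_S: float = 0.3
    l_E: float = 0.35
    a_S: float = 0.05
    b_S: float = 0.05
    a_E: float = 0.05
    b_E: float = 0.05

    def __post_init__(self) -> None:
        for name in ("l_S", "l_E", "a_S", "b_S", "a_E", "b_E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ArmGeometry.{name} must be > 0")
        if self.a_S >= self.l_S:
            raise ValueError("ArmGeometry requires a_S < l_S")

    @property
    def reach_radius_max(self) -> float:
        return (self.l_S - self.a_S) + self.l_E

    @property
    def reach_radius_min(self) -> float:
        return abs((self.l_S - self.a_S) - self.l_E)


@dataclass(frozen=True)
class MuscleActivations:
    """Four muscle activations in [0, 1].

    Order: shoulder agonist (flexor), shoulder antagonist (extensor),
    elbow agonist, elbow antagonist.  Values outside [0, 1] are clipped on
    construction so the learning loop stays total.
    """

    phi: np.ndarray = field(default_factory=lambda: np.full(4, 0.5))

    def __post_init__(self) -> None:
        arr = np.asarray(self.phi, dtype=float)
        if arr.shape != (4,):
            raise ValueError("MuscleActivations.phi must be a 4-vector")
        object.__setattr__(self, "phi", np.clip(arr, 0.0, 1.0))


@dataclass(frozen=True)
class ArmState:
    """Joint angles (rad), muscle lengths (m) and end-effector position (m)."""

    theta_S: float
    theta_E: float
    M_L: np.ndarray
    X_arm: np.ndarray


def activations_to_joint_angles(phi: MuscleActivations) -> tuple[float, float]:
    """Map the four activations to shoulder and elbow joint angles.

    Each joint angle is ``(phi_Ag - phi_An) * pi/2 + pi/2`` so equal
    co-contraction gives the mid-range angle pi/2 and the angles stay in
    [0, pi].
    """
    p = phi.phi
    theta_S = (p[0] - p[1]) * np.pi / 2 + np.pi / 2
    theta_E = (p[2] - p[3]) * np.pi / 2 + np.pi / 2
    return float(theta_S), float(theta_E)


def joint_angles_to_muscle_lengths(
    theta_S: float, theta_E: float, geom: ArmGeometry
) -> np.ndarray:
    """Law-of-cosines muscle lengths for both joints.

    Agonist length grows with the joint angle through ``+2ab cos(theta)``
    under the radical, the antagonist with ``-2ab cos(theta)``.
    """
    out = np.empty(4)
    for k, (a, b, th) in enumerate(
        (
            (geom.a_S, geom.b_S, theta_S),
            (geom.a_S, geom.b_S, theta_S),
            (geom.a_E, geom.b_E, theta_E),
            (geom.a_E, geom.b_E, theta_E),
        )
    ):
        sign = 1.0 if k % 2 == 0 else -1.0
        rad = a * a + b * b + sign * 2 * a * b * np.cos(th)
        if rad < -1e-12:
            raise ArithmeticError("negative radicand in muscle-length formula")
        out[k] = np.sqrt(max(rad, 0.0))
    return out


def forward_kinematics(
    theta_S: float, theta_E: float, geom: ArmGeometry
) -> np.ndarray:
    """Planar end-effector position of the two-link chain.

    The effective shoulder link length is ``l_S - a_S`` (the muscle lever
    offsets the proximal attachment); the elbow angle is measured relative
    to the shoulder link.
    """
    r1 = geom.l_S - geom.a_S
    x1 = r1 * np.cos(theta_S) + geom.l_E * np.cos(theta_S + theta_E)
    x2 = r1 * np.sin(theta_S) + geom.l_E * np.sin(theta_S + theta_E)
    return np.array([x1, x2])


def arm_state_from_activations(
    phi: MuscleActivations, geom: ArmGeometry
) -> ArmState:
    """Full forward pass: activations -> angles -> lengths -> hand position."""
    theta_S, theta_E = activations_to_joint_angles(phi)
    M_L = joint_angles_to_muscle_lengths(theta_S, theta_E, geom)
    X_arm = forward_kinematics(theta_S, theta_E, geom)
    return ArmState(theta_S=theta_S, theta_E=theta_E, M_L=M_L, X_arm=X_arm)


def reachable_workspace_samples(
    geom: ArmGeometry,
    n: int,
    seed: int | np.random.Generator = 0,
    complementary: bool = False,
) -> np.ndarray:
    """Sample ``n`` reachable hand positions by random motor babbling.

    Activations are drawn uniformly in [0, 1]^4 (or, with
    ``complementary=True``, on the agonist+antagonist=1 manifold) and
    pushed through the forward kinematics.  Deterministic under a fixed
    seed.  Returns an (n, 2) array.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    phis = sample_babbling_activations(rng, n, complementary=complementary)
    out = np.empty((n, 2))
    for i in range(n):
        st = arm_state_from_activations(MuscleActivations(phis[i]), geom)
        out[i] = st.X_arm
    return out


def inverse_kinematics(x: np.ndarray, geom: ArmGeometry) -> tuple[float, float]:
    """Joint angles whose forward kinematics land on ``x`` (elbow-up branch).

    The elbow angle comes from the cosine rule on the two effective links;
    positions outside the reachable annulus are projected onto its nearest
    boundary.  Both angles are clipped to the joint range [0, pi].
    """
    x = np.asarray(x, float)
    L1 = geom.l_S - geom.a_S
    L2 = geom.l_E
    r = float(np.linalg.norm(x))
    r = float(np.clip(r, abs(L1 - L2) + 1e-9, L1 + L2 - 1e-9))
    c_e = (r * r - L1 * L1 - L2 * L2) / (2 * L1 * L2)
    theta_E = float(np.arccos(np.clip(c_e, -1.0, 1.0)))
    theta_S = float(np.arctan2(x[1], x[0])
                    - np.arctan2(L2 * np.sin(theta_E),
                                 L1 + L2 * np.cos(theta_E)))
    return float(np.clip(theta_S, 0.0, np.pi)), theta_E


def complementary_activations(theta_S: float, theta_E: float) -> np.ndarray:
    """Activations on the agonist+antagonist=1 manifold for given angles."""
    return np.array([theta_S / np.pi, 1 - theta_S / np.pi,
                     theta_E / np.pi, 1 - theta_E / np.pi])


def sample_babbling_activations(
    rng: np.random.Generator, n: int, complementary: bool = True
) -> np.ndarray:
    """Random desired activations for motor babbling, shape (n, 4).

    With ``complementary=True`` (the training default) each joint's
    antagonist activation is 1 minus its agonist activation, which makes
    the activation vector uniquely recoverable from the arm posture.
    """
    if complementary:
        ag = rng.uniform(0.0, 1.0, size=(n, 2))
        return np.stack([ag[:, 0], 1 - ag[:, 0], ag[:, 1], 1 - ag[:, 1]], axis=1)
    return rng.uniform(0.0, 1.0, size=(n, 4))
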