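"""Behavioural and network read-outs of a reaching trial.

Movement time, velocity statistics and RMS acceleration are computed from
the hand trajectory sampled at the behavioural timestep (50 ms by
default).  Network read-outs cover a variance-of-mean-field synchrony
measure for the STN lattice, a short-time Fourier spectrogram of its mean
output, the green/yellow/red movement-time classification and the
therapeutic-window duration of a medication session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "NON_REACHABLE",
    "ReachTrajectory",
    "ReachMetrics",
    "movement_time",
    "velocity_profile",
    "rms_acceleration",
    "compute_reach_metrics",
    "synchrony",
    "spectrogram",
    "band_power",
    "classify_movement_time",
    "therapeutic_window",
]

#: Sentinel for trials that never enter the reach threshold.
NON_REACHABLE = float("inf")


@dataclass(frozen=True)
class ReachTrajectory:
    """Uniformly sampled hand trajectory toward a fixed target.

    ``times`` in seconds, ``positions`` an (n, 2) array in metres,
    ``target`` the goal position, ``eps_reach`` the distance threshold (m)
    below which the target counts as reached.
    """

    times: np.ndarray
    positions: np.ndarray
    target: np.ndarray
    eps_reach: float = 0.1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        p = np.asarray(self.positions, float)
        if p.ndim != 2 or p.shape[0] != t.shape[0] or p.shape[1] != 2:
            raise ValueError("positions must be (n, 2) matching times")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "target", np.asarray(self.target, float))

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def distances(self) -> np.ndarray:
        return np.linalg.norm(self.positions - self.target[None, :], axis=1)


@dataclass(frozen=True)
class ReachMetrics:
    """Per-trial summary; ``movement_time`` is ``inf`` when non-reachable."""

    movement_time: float
    peak_velocity: float
    time_to_peak: float
    average_velocity: float
    rms_acceleration: float
    reached: bool


def movement_time(traj: ReachTrajectory) -> float:
    """Time of first entry within the reach threshold, or ``NON_REACHABLE``."""
    inside = traj.distances() < traj.eps_reach
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        return NON_REACHABLE
    return float(traj.times[idx[0]])


def velocity_profile(
    traj: ReachTrajectory,
) -> tuple[np.ndarray, float, float, float]:
    """Finite-difference speed profile and its summary statistics.

    Returns ``(speeds, peak_velocity, time_to_peak, average_velocity)``.
    Speeds are forward differences aligned with the *later* sample, with
    speed 0 at t=0.  The average is taken over the interval up to the
    movement time (full trajectory if the target is never reached).
    """
    if traj.times.shape[0] < 2:
        raise ValueError("velocity profile needs at least 2 samples")
    dt = traj.dt
    steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1) / dt
    speeds = np.concatenate([[0.0], steps])
    mt = movement_time(traj)
    if np.isfinite(mt):
        upto = speeds[traj.times <= mt + 1e-12]
    else:
        upto = speeds
    k = int(np.argmax(speeds))
    return speeds, float(speeds[k]), float(traj.times[k]), float(np.mean(upto[1:])) if upto.size > 1 else 0.0


def rms_acceleration(traj: ReachTrajectory) -> float:
    """RMS of the second finite difference of position over time (m/s^2)."""
    if traj.times.shape[0] < 3:
        raise ValueError("rms acceleration needs at least 3 samples")
    dt = traj.dt
    acc = np.diff(traj.positions, n=2, axis=0) / dt**2
    return float(np.sqrt(np.mean(np.sum(acc**2, axis=1))))


def compute_reach_metrics(traj: ReachTrajectory) -> ReachMetrics:
    mt = movement_time(traj)
    _, pv, tp, av = velocity_profile(traj)
    return ReachMetrics(
        movement_time=mt,
        peak_velocity=pv,
        time_to_peak=tp,
        average_velocity=av,
        rms_acceleration=rms_acceleration(traj),
        reached=bool(np.isfinite(mt)),
    )


def synchrony(traces: np.ndarray) -> float:
    """Variance-of-mean-field synchrony of a population, in [0, 1].

    ``traces`` has shape (n_units, n_times).  The measure is
    ``Var_t(mean field) / mean_units(Var_t(unit))`` -- 1 for identical
    units, tending to 0 for independent units as the population grows.
    Raises ``ValueError`` when every unit is constant in time (synchrony
    is undefined for silent populations).
    """
    x = np.asarray(traces, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("synchrony needs >= 2 equal-length traces")
    unit_var = np.var(x, axis=1)
    denom = float(np.mean(unit_var))
    if denom <= 0.0:
        raise ValueError("synchrony undefined: all traces are constant")
    chi2 = float(np.var(x.mean(axis=0))) / denom
    return float(np.clip(chi2, 0.0, 1.0))


def spectrogram(
    trace: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier power of the mean population trace.

    Hann window of ``window_s`` seconds with fractional ``overlap``.
    Returns ``(freqs, times, power)`` with power = |STFT|^2.
    """
    x = np.asarray(trace, float)
    nper = int(round(window_s * fs))
    if nper > x.shape[0]:
        raise ValueError("window longer than trace")
    nover = int(nper * overlap)
    f, t, s = _signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nper, noverlap=nover, mode="psd"
    )
    return f, t, s


def band_power(
    freqs: np.ndarray, power: np.ndarray, lo_hz: float, hi_hz: float
) -> float:
    """Total spectrogram power integrated over a frequency band."""
    sel = (freqs >= lo_hz) & (freqs <= hi_hz)
    return float(np.sum(power[sel]))


def classify_movement_time(mt: float) -> str:
    """Green (< 2 s, normal), yellow (2-4 s, bradykinesia), red (> 4 s or
    non-reachable, akinesia).  Boundary values fall in the yellow band."""
    if mt < 0:
        raise ValueError("movement time must be >= 0")
    if mt < 2.0:
        return "green"
    if mt <= 4.0:
        return "yellow"
    return "red"


def therapeutic_window(
    times_h: np.ndarray, movement_times_s: np.ndarray, dose_time_h: float
) -> float:
    """Duration (h) of the first contiguous green interval after the dose.

    The window opens at the first post-dose sample classified green and
    closes when the series leaves the green band; 0 if the series is never
    green after the dose.
    """
    t = np.asarray(times_h, float)
    mt = np.asarray(movement_times_s, float)
    if t.shape != mt.shape:
        raise ValueError("times and movement times must align")
    post = t >= dose_time_h
    green = np.array([classify_movement_time(v) == "green" for v in mt]) & post
    idx = np.flatnonzero(green)
    if idx.size == 0:
        return 0.0
    start = idx[0]
    end = start
    while end + 1 < t.size and green[end + 1]:
        end += 1
    if end == start:
        # a single green sample spans one sampling interval
        step = t[1] - t[0] if t.size > 1 else 0.0
        return float(step)
    return float(t[end] - t[start])
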