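"""Structured simulation configuration with YAML loading and validation.

The configuration mirrors the model's loops: arm geometry, cortical map
sizes and training schedule, CANN dynamics, basal-ganglia gains, SNc
population, lesion routing, levodopa PK, and the multi-rate timing table.
A bundled fixture file (``data/fixture.yaml``) carries the calibrated
reference parameter set; any YAML file with the same structure can
override parts of it.  Unknown keys fail loudly with their full path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .ldopa_pkpd import PKParams
from .pd_lesion import EpsilonMap
from .snc_dopamine import DACalibration, SNcParams

__all__ = ["SimulationConfig", "load_config", "default_config", "dump_config"]


@dataclass(frozen=True)
class ArmConfig:
    l_S: float = 0.3
    l_E: float = 0.35
    a_S: float = 0.05
    b_S: float = 0.05
    a_E: float = 0.05
    b_E: float = 0.05
    start_phi: tuple = (0.5, 0.5, 0.5, 0.5)
    eps_reach: float = 0.1


@dataclass(frozen=True)
class CANNConfig:
    tau: float = 150.0
    A_lat: float = 0.15
    sigma_lat: float = 1.5
    K: float = 0.01
    b: float = 1.5


@dataclass(frozen=True)
class MapsConfig:
    N_pc: int = 20
    N_pfc: int = 20
    N_mc: int = 20
    N_thal: int = 20
    sigma_pc: float = 0.02      # muscle-length feature scale (m)
    sigma_pfc: float = 0.15     # workspace scale (m)
    sigma_mc: float = 1.2       # PC-pattern scale (activation units)
    n_babble: int = 1500
    som_epochs: int = 8
    mc_relax_steps: int = 30
    readout_epochs: int = 40
    eta_mc_mn: float = 0.15
    eta_pfc_mc: float = 0.3
    aim_rounds: int = 2          # closed-loop aim-correction rounds
    aim_samples: int = 400       # positions re-aimed per round
    recall_sharpen: float = 3.0  # exponent sharpening the recalled pattern
    recall_amp: float = 1.2      # peak of the recalled pattern
    closed_loop_trials: int = 0
    mc_cann: CANNConfig = field(default_factory=CANNConfig)
    thal_cann: CANNConfig = field(default_factory=lambda: CANNConfig(
        tau=150.0, A_lat=0.05, K=0.0, b=0.05))


@dataclass(frozen=True)
class STNGPeConfig:
    N: int = 8
    tau_GPe: float = 20.0
    tau_STN: float = 10.0
    eps_g: float = 0.2
    w_sg: float = 2.5
    w_gs: float = 2.5
    lambda_STN: float = 3.0
    sigma_lat_g: float = 0.9
    sigma_lat_s: float = 0.9
    tau_jitter: float = 0.05
    noise_amp: float = 0.15


@dataclass(frozen=True)
class BGConfig:
    sigma_V: float = 0.8
    a_D1: float = 30.0
    theta_D1: float = 0.08
    theta_D2: float = 0.08
    A_D1: float = 0.2
    A_D2: float = 0.8
    d1_gain: float = 1.0       # corticostriatal scaling of W_CTX->D1
    d2_gain: float = 8.0       # corticostriatal scaling of W_CTX->D2
    y_sat: float = 100.0       # D2-MSN firing-rate ceiling (smooth saturation)
    y_sat_d1: float = 100.0    # D1-MSN firing-rate ceiling
    A_PC: float = 1.0
    A_PFC: float = 0.65
    A_BG: float = 40.0
    A_MN: float = 1.0
    mn_beta: float = 0.35      # per-stage constant of the 2nd-order muscle filter
    stn: STNGPeConfig = field(default_factory=STNGPeConfig)
    record_every: int = 25          # STN trace subsampling (internal steps)
    sync_block_windows: int = 4     # behavioural windows per synchrony block


@dataclass(frozen=True)
class SNcConfig:
    n: int = 64
    jitter: float = 0.05
    settle_windows: int = 10
    params: SNcParams = field(default_factory=SNcParams)
    calibration: DACalibration = field(default_factory=DACalibration)


@dataclass(frozen=True)
class EpsCalibrationConfig:
    eps_map: EpsilonMap = field(default_factory=EpsilonMap)
    scan_lo: float = 0.15
    scan_hi: float = 3.0
    scan_n: int = 8
    sync_low_target: float = 0.1
    sync_high_target: float = 0.9
    rest_frac_hi: float = 0.55   # eps_lo anchor, fraction of the rest-to-deep-lesion span
    rest_frac_lo: float = 0.95   # eps_hi anchor, fraction of the same span
    eps_hi_margin: float = 2.7         # drive-robustness margin on the calibrated eps_hi


@dataclass(frozen=True)
class PKConfig:
    params: PKParams = field(default_factory=PKParams)
    dose_mg: float = 150.0
    dose_time_h: float = 2.0
    horizon_h: float = 12.0
    sample_every_h: float = 0.5
    session_trials: int = 3
    equilibrate_s: float = 600.0


@dataclass(frozen=True)
class TimingConfig:
    dt_mc_ms: float = 50.0
    n_mc_steps: int = 100
    dt_stn_ms: float = 0.02
    n_stn_steps: int = 2500
    dt_snc_ms: float = 0.025
    n_snc_steps: int = 2000
    terminal_every: int = 10

    def validate(self) -> None:
        """The per-window products of the inner loops must equal the
        behavioural timestep unless explicitly overridden."""
        for dt, n, name in (
            (self.dt_stn_ms, self.n_stn_steps, "STN-GPe"),
            (self.dt_snc_ms, self.n_snc_steps, "SNc"),
        ):
            if not np.isclose(dt * n, self.dt_mc_ms, rtol=1e-9):
                raise ValueError(
                    f"{name} loop: dt * iterations = {dt * n} ms "
                    f"!= behavioural step {self.dt_mc_ms} ms"
                )


@dataclass(frozen=True)
class SimulationConfig:
    arm: ArmConfig = field(default_factory=ArmConfig)
    maps: MapsConfig = field(default_factory=MapsConfig)
    bg: BGConfig = field(default_factory=BGConfig)
    snc: SNcConfig = field(default_factory=SNcConfig)
    eps: EpsCalibrationConfig = field(default_factory=EpsCalibrationConfig)
    pk: PKConfig = field(default_factory=PKConfig)
    timing: TimingConfig = field(default_factory=TimingConfig)
    target: tuple = (0.3, 0.35)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        self.timing.validate()
        return self


def _update_dataclass(obj, data: dict, path: str):
    """Recursively apply a dict of overrides to a (frozen) dataclass."""
    if not isinstance(data, dict):
        raise ValueError(f"config section '{path}' must be a mapping")
    names = {f.name: f for f in dataclasses.fields(obj)}
    updates = {}
    for key, value in data.items():
        if key not in names:
            raise ValueError(f"unknown config key '{path}.{key}'" if path else
                             f"unknown config key '{key}'")
        current = getattr(obj, key)
        sub_path = f"{path}.{key}" if path else key
        if dataclasses.is_dataclass(current) and not isinstance(current, type):
            updates[key] = _update_dataclass(current, value, sub_path)
        elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
            updates[key] = tuple(value)
        else:
            updates[key] = type(current)(value) if current is not None else value
    return replace(obj, **updates)


def default_config() -> SimulationConfig:
    """The bundled calibrated fixture configuration."""
    with resources.files("bgreach").joinpath("data/fixture.yaml").open() as fh:
        data = yaml.safe_load(fh) or {}
    return _update_dataclass(SimulationConfig(), data, "").validate()


def load_config(path: str | Path | None = None) -> SimulationConfig:
    """Load the fixture config, optionally overridden by a user YAML file."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _update_dataclass(cfg, data, "").validate()


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def dump_config(cfg: SimulationConfig, path: str | Path) -> None:
    """Serialize a full configuration to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_as_plain(cfg), fh, sort_keys=False)
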