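"""Run configuration: every tunable of the pipeline in one place.

The configuration mirrors the analysis blocks (tensor, motion, helix,
thresholds, grid, qcc, classification bounds) with defaults matching the
published analysis conditions where those are printed, and documented
package choices otherwise.  Configs load from YAML; unknown keys are
rejected so typos cannot silently fall back to defaults.  Every run
summary echoes the fully resolved configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import constants as C


@dataclass
class TensorConfig:
    sigma11: float = C.SIGMA11_DEFAULT
    sigma22: float = C.SIGMA22_DEFAULT
    sigma33: float = C.SIGMA33_DEFAULT
    beta_nh: float = C.BETA_NH_DEFAULT


@dataclass
class MotionConfig:
    wobble_sd: float = C.WOBBLE_SD_DEFAULT
    azimuth_sd: float = C.AZIMUTH_SD_DEFAULT
    n_points: int = C.QUADRATURE_POINTS_DEFAULT


@dataclass
class HelixConfig:
    phi: float = C.PHI_DEFAULT
    psi: float = C.PSI_DEFAULT
    omega: float = C.OMEGA_DEFAULT
    sequence: str = C.SAAP148_SEQUENCE


@dataclass
class AnalysisConfig:
    grid_step: float = 1.0
    min_area: float = 3.0
    ha_threshold: float = C.HA_THRESHOLD_DEFAULT
    ca_threshold: float = C.CA_THRESHOLD_DEFAULT
    min_helix_run: int = C.MIN_HELIX_RUN_DEFAULT
    qcc_khz: float = C.QCC_DEFAULT_KHZ
    in_plane_tilt_min: float = C.IN_PLANE_TILT_RANGE[0]
    in_plane_tilt_max: float = C.IN_PLANE_TILT_RANGE[1]
    transmembrane_tilt_max: float = C.TRANSMEMBRANE_TILT_MAX


@dataclass
class RunConfig:
    tensor: TensorConfig = field(default_factory=TensorConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)
    helix: HelixConfig = field(default_factory=HelixConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def resolved(self) -> dict:
        """Fully resolved configuration for run-log provenance."""
        return asdict(self)


def _build(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


def load_config(path=None) -> RunConfig:
    """Load a RunConfig from YAML; missing blocks keep their defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    blocks = {"tensor": TensorConfig, "motion": MotionConfig,
              "helix": HelixConfig, "analysis": AnalysisConfig}
    unknown = set(data) - set(blocks)
    if unknown:
        raise ValueError(f"{path}: unknown config block(s) {sorted(unknown)}")
    kwargs = {name: _build(cls, data.get(name, {}) or {}, name)
              for name, cls in blocks.items()}
    return RunConfig(**kwargs)
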