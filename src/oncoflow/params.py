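"""Parameter containers.

Grouped dataclasses mirror the physics modules; :func:`load_parameters` reads
the versioned YAML parameter file shipped with the package (or a user copy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path

import yaml


@dataclass
class FluidParams:
    mu_blood: float = 3.5e-3
    mu_plasma: float = 1.2e-3
    mu_interstitial: float = 1.0e-3
    K_int_tumour: float = 5.0e-15
    K_int_host: float = 6.4e-15
    sigma_osmotic: float = 0.82
    pi_vascular: float = 2666.0
    pi_interstitial: float = 1995.0
    p_inlet: float = 3333.0
    p_outlet: float = 1333.0

    def __post_init__(self):
        for name in ("mu_blood", "mu_plasma", "mu_interstitial",
                     "K_int_tumour", "K_int_host"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.sigma_osmotic <= 1.0:
            raise ValueError("sigma_osmotic must lie in [0, 1]")


@dataclass
class LymphParams:
    K_lmp: float = 1.0e-11
    S_lmp_host: float = 7000.0
    S_lmp_tumour: float = 0.0
    p_lmp: float = 0.0

    def __post_init__(self):
        if self.K_lmp < 0 or self.S_lmp_host < 0 or self.S_lmp_tumour < 0:
            raise ValueError("lymphatic permeability/density must be >= 0")


@dataclass
class WallParams:
    gamma_p: float = 0.06
    thickness: float = 5.0e-6
    pore_radius: float = 1.5e-7

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("vessel wall thickness must be positive")


@dataclass
class DrugParams:
    molecule_size: float = 1.0e-9
    temperature: float = 310.0
    k_on: float = 5.0
    k_off: float = 5.0e-2
    k_int: float = 1.0e-4
    delta_i: float = 3.0e-6
    c_v_max: float = 1.0
    tau_c: float = 21600.0


@dataclass
class OxygenParams:
    diffusivity: float = 2.0e-9
    uptake_tumour: float = 2.0e-3
    decay_host: float = 1.0e-3


@dataclass
class MDEParams:
    diffusivity: float = 2.0e-10
    decay: float = 5.0e-4


@dataclass
class TissueParams:
    lambda_ecm: float = 0.15
    delta_ecm: float = 0.025
    ecm_scale: float = 4.0
    delta_d: float = 1.0
    ecm_threshold: float = 0.05
    ci_threshold: float = 0.05
    a_d: float = 1.0
    alpha_g: float = 80.0
    beta_g: float = 1.0
    gamma_g: float = 3.0
    delta_g: float = 3.0
    tau_growth: float = 1.0
    ecm_tumour_init: float = 0.2
    ecm_host_init: float = 1.0
    a_w: float = 1.0
    mu_shear: float = 1000.0
    kappa_bulk: float = 20000.0

    def __post_init__(self):
        if self.a_w <= 0:
            raise ValueError("stiffness exponent a_w must be > 0")


@dataclass
class VesselStateParams:
    compress_threshold: float = 200.0
    collapse_threshold: float = 900.0
    compressed_factor: float = 0.6
    wss_setpoint: float = 0.5
    remodel_gain: float = 0.05
    radius_min: float = 2.0e-6
    radius_max: float = 1.2e-5
    sprout_rate: float = 0.5
    sprout_length: float = 3.0e-4
    sprout_radius: float = 3.0e-6
    hypoxia_threshold: float = 0.35
    anastomosis_radius: float = 1.5e-4
    max_segment_factor: float = 2.5

    def __post_init__(self):
        if not self.collapse_threshold >= self.compress_threshold >= 0:
            raise ValueError(
                "need collapse_threshold >= compress_threshold >= 0")


@dataclass
class MetricsParams:
    perfusion_velocity: float = 1.0e-4
    supply_velocity_factor: float = 0.01
    sample_resolution: int = 16
    analysis_halfwidth_frac: float = 0.42
    shell_width: float = 1.0e-3
    lambda_offset: float = 1.4
    lambda_slope: float = 4.0


_SECTIONS = {
    "fluid": FluidParams,
    "lymph": LymphParams,
    "wall": WallParams,
    "drug": DrugParams,
    "oxygen": OxygenParams,
    "mde": MDEParams,
    "tissue": TissueParams,
    "vessels": VesselStateParams,
    "metrics": MetricsParams,
}


@dataclass
class Parameters:
    """All physical/model parameters for one simulation."""

    fluid: FluidParams = field(default_factory=FluidParams)
    lymph: LymphParams = field(default_factory=LymphParams)
    wall: WallParams = field(default_factory=WallParams)
    drug: DrugParams = field(default_factory=DrugParams)
    oxygen: OxygenParams = field(default_factory=OxygenParams)
    mde: MDEParams = field(default_factory=MDEParams)
    tissue: TissueParams = field(default_factory=TissueParams)
    vessels: VesselStateParams = field(default_factory=VesselStateParams)
    metrics: MetricsParams = field(default_factory=MetricsParams)

    def to_dict(self) -> dict:
        out = {}
        for name, cls in _SECTIONS.items():
            section = getattr(self, name)
            out[name] = {f.name: getattr(section, f.name) for f in fields(cls)}
        return out


def _from_mapping(data: dict) -> Parameters:
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = dict(data.get(name, {}))
        unknown = set(section) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown parameter(s) in [{name}]: {sorted(unknown)}")
        kwargs[name] = cls(**section)
    return Parameters(**kwargs)


def default_parameters() -> Parameters:
    """Parameters from the versioned YAML file shipped with the package."""
    text = resources.files("oncoflow").joinpath("data/params_default.yaml").read_text()
    return _from_mapping(yaml.safe_load(text))


def load_parameters(path: str | Path | None = None) -> Parameters:
    if path is None:
        return default_parameters()
    with open(path) as fh:
        return _from_mapping(yaml.safe_load(fh))
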