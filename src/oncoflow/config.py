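"""Simulation configuration and the desk/paper-scale profiles."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml


@dataclass
class SimulationConfig:
    """One simulation cell of the poresize × affinity × injection-day matrix.

    Times are in days, geometry in metres.  ``inject_day = None`` is the
    untreated control.  The module time steps honour the staggered scheme:
    drug (sub-second, CFL-adaptive) ≤ biochemical (seconds) ≤ outer
    solid/fluid/network step (hours).
    """

    edge_length: float = 0.0119          # m (≈1.7 cm³ cube)
    resolution: int = 12                 # elements per edge
    tumour_diameter: float = 1.0e-3      # m
    n_segments: int = 420
    pore_radius: float = 1.5e-7          # m (r_p)
    k_on: float = 5.0                    # 1/s
    molecule_size: float = 1.0e-9        # m (s_c)
    inject_day: float | None = None
    end_day: float = 40.0
    dt_outer_hours: float = 6.0
    dt_bio_seconds: float = 10.0
    drug_chunk_minutes: float = 15.0     # inlet-bolus re-evaluation interval
    seed: int = 1
    params_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self):
        if self.inject_day is not None and not (0 <= self.inject_day
                                                < self.end_day):
            raise ValueError("injection day must precede the end day")
        if min(self.dt_outer_hours, self.dt_bio_seconds,
               self.drug_chunk_minutes) <= 0:
            raise ValueError("all module time steps must be positive")
        if self.dt_bio_seconds > self.dt_outer_hours * 3600:
            raise ValueError("biochemical step must not exceed the outer step")

    @property
    def tumour_radius(self) -> float:
        return self.tumour_diameter / 2.0

    def label(self) -> str:
        inj = "control" if self.inject_day is None else f"D{self.inject_day:g}"
        return (f"rp{self.pore_radius * 1e9:g}nm_kon{self.k_on:g}_{inj}")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    @classmethod
    def coarse(cls, **kw) -> "SimulationConfig":
        """Reduced profile for quick sweeps (smaller mesh/network, 12 h
        coupling step)."""
        base = dict(resolution=12, n_segments=420, dt_outer_hours=12.0)
        base.update(kw)
        return cls(**base)

    @classmethod
    def paper_scale(cls, **kw) -> "SimulationConfig":
        """Fidelity profile approaching the full-scale study geometry."""
        base = dict(resolution=15, n_segments=2880, dt_outer_hours=6.0)
        base.update(kw)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
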