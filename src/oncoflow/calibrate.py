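"""One-time, seed-deterministic calibration of the growth amplitude α_g.

The control trajectory must respect two anchors: a day 10–15 volume growth
rate of ≈5.3 mm³/day in the low-poresize configuration, and a 40-day final
equivalent diameter below 10 mm.  α_g (the only free amplitude of the
Gompertz growth law) is fitted by a bounded secant iteration on reduced
control runs; the result is written to a parameter YAML for versioning.
"""

from __future__ import annotations

import logging

import numpy as np
import yaml

from .config import SimulationConfig
from .orchestrator import run_simulation
from .params import load_parameters

log = logging.getLogger(__name__)


def _day10_15_rate(alpha: float, seed: int, end_day: float = 16.0) -> float:
    params = load_parameters()
    params.tissue.alpha_g = alpha
    cfg = SimulationConfig(pore_radius=1.0e-8, inject_day=None,
                           end_day=end_day, seed=seed)
    res = run_simulation(cfg, params=params)
    return (res.volume_mm3(15.0) - res.volume_mm3(10.0)) / 5.0


def calibrate_growth(seed: int = 1, target_rate: float = 5.3,
                     out_path: str | None = None, max_iter: int = 6):
    """Secant iteration for α_g against the day 10–15 rate anchor."""
    a0, a1 = 20.0, 45.0
    r0 = _day10_15_rate(a0, seed)
    r1 = _day10_15_rate(a1, seed)
    log.info("calibrate: alpha %g -> rate %g; alpha %g -> rate %g",
             a0, r0, a1, r1)
    for _ in range(max_iter):
        if abs(r1 - target_rate) / target_rate < 0.08:
            break
        if r1 == r0:
            break
        a2 = a1 + (target_rate - r1) * (a1 - a0) / (r1 - r0)
        a2 = float(np.clip(a2, 5.0, 200.0))
        a0, r0, a1 = a1, r1, a2
        r1 = _day10_15_rate(a1, seed)
        log.info("calibrate: alpha %g -> rate %g", a1, r1)
    if out_path:
        params = load_parameters()
        params.tissue.alpha_g = float(a1)
        with open(out_path, "w") as fh:
            yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
    return float(a1), float(r1)
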