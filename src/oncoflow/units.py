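"""Unit helpers.  Everything inside the package is SI; these converters are
for I/O convenience only (clinical pressures in mmHg, vessel sizes in μm)."""

MMHG = 133.322  # Pa per mmHg
DAY = 86400.0  # s
HOUR = 3600.0  # s

BOLTZMANN = 1.380649e-23  # J/K


def mmhg_to_pa(p: float) -> float:
    return p * MMHG


def pa_to_mmhg(p: float) -> float:
    return p / MMHG


def um_to_m(x: float) -> float:
    return x * 1e-6


def m_to_um(x: float) -> float:
    return x * 1e6


def halflife_to_efolding(t_half: float) -> float:
    """Convert a plasma half-life to the e-folding time τ_c of the bolus
    c_v-max·exp[−t/τ_c]."""
    import math

    return t_half / math.log(2.0)
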