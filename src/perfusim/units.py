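"""Unit conversions at the package boundary.

Everything inside perfusim is SI: pressures in Pa, flows in m³/s, lengths in m.
Human-facing interfaces (config files, telemetry, the CLI) speak mbar and
µL/min, the units of the instrument world this package models.
"""

MBAR_PER_PA = 0.01
PA_PER_MBAR = 100.0

#: 1 µL/min expressed in m³/s.
M3S_PER_ULMIN = 1e-9 / 60.0
ULMIN_PER_M3S = 60.0 / 1e-9

#: Standard gravity, m/s².
G = 9.81


def mbar_to_pa(p: float) -> float:
    return p * PA_PER_MBAR


def pa_to_mbar(p: float) -> float:
    return p * MBAR_PER_PA


def ulmin_to_m3s(q: float) -> float:
    return q * M3S_PER_ULMIN


def m3s_to_ulmin(q: float) -> float:
    return q * ULMIN_PER_M3S


def ml_to_m3(v: float) -> float:
    return v * 1e-6


def m3_to_ml(v: float) -> float:
    return v * 1e6
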