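"""Unit conversions between clinical pump units and SI.

All public interfaces in this package speak clinical units (L/min, mmHg,
rpm, mm); internal fluid-dynamic computation is in SI. The conversion
constants are fixed here so every module agrees on them.
"""

import math

#: 1 mmHg in Pa
MMHG_TO_PA = 133.322
#: 1 L/min in m^3/s
LPM_TO_M3S = 1.0 / 60000.0
#: 1 rpm in rad/s
RPM_TO_RADS = 2.0 * math.pi / 60.0
#: 1 mm in m
MM_TO_M = 1e-3


def lpm_to_m3s(q_lpm):
    return q_lpm * LPM_TO_M3S


def m3s_to_lpm(q_m3s):
    return q_m3s / LPM_TO_M3S


def mmhg_to_pa(dp_mmhg):
    return dp_mmhg * MMHG_TO_PA


def pa_to_mmhg(dp_pa):
    return dp_pa / MMHG_TO_PA


def rpm_to_rads(omega_rpm):
    return omega_rpm * RPM_TO_RADS


def rads_to_rpm(omega_rads):
    return omega_rads / RPM_TO_RADS
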