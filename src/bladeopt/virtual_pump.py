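"""Analytic mean-line pump model used as the simulation truth.

This module plays the role of the flow solver in the design loop: it maps a
blade design and a rotational speed to HQ and etaQ curves. It is a
deliberately simple Euler-equation loss model, constructed so that

* every pressure term is homogeneous of degree 2 in (omega, Q) and the
  shaft power of degree 3, making the model *exactly* affinity-consistent:
  psi and eta are functions of phi alone, so similitude scaling round-trips
  are exact to machine precision;
* it is smooth in all five blade parameters, so surrogate models have
  signal in every input;
* its curves are qualitatively realistic for a small axial blood pump:
  head falling with flow over the region of interest, efficiency with an
  interior maximum, dP of order 100 mmHg and eta of order 0.1-0.35 near
  0.5-2 L/min at 15,000-20,000 rpm.

Model, at mid-span radius r_m with annulus area A (velocities in SI):

    U      = omega r_m                       blade speed
    c_x    = Q / A                           axial velocity
    c_th   = sigma_s (U - c_x cot beta2)     slip-corrected outlet swirl
    dP     = rho U c_th                      Euler head
           - k_inc  1/2 rho (U - c_x cot beta1)^2       impeller incidence
           - k_dif  1/2 rho (c_th - c_x cot alpha2)^2   diffuser incidence
           - k_fric ((C_imp + C_diff)/c_ref) 1/2 rho c_x^2   passage drag
    P      = rho Q U c_th + k_par rho omega^3 r_m^5     shaft power
    eta    = Q dP / P

Off-design the head and efficiency may legitimately go negative; values are
reported raw. Optional Gaussian noise can be added to dP (only) to mimic
solver scatter; it requires a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import units
from .curves import PerformanceCurve
from .geometry import BladeDesign, PumpConstants

__all__ = [
    "LossCoefficients",
    "DEFAULT_FLOW_GRID_LPM",
    "simulate_curve",
    "simulate_point",
    "zero_incidence_flow_lpm",
]

#: default flow grid: 8 flow rates, 0.5 to 4.0 L/min in steps of 0.5
DEFAULT_FLOW_GRID_LPM = tuple(np.arange(0.5, 4.01, 0.5))


@dataclass(frozen=True)
class LossCoefficients:
    """Loss-model coefficients (all dimensionless, all >= 0).

    Defaults are calibrated once so that, across the factorial design box,
    HQ curves fall monotonically over the region of interest, etaQ curves
    peak inside the sampled flow range, and design-point efficiencies land
    in a plausible 0.1-0.35 band. ``c_ref_mm`` is the total chord (impeller
    plus diffuser) at which the drag loss has unit chord weighting.
    """

    slip_factor: float = 0.85
    k_inc: float = 0.02
    k_dif: float = 0.02
    k_fric: float = 10.0
    k_par: float = 2.0
    c_ref_mm: float = 23.0

    def __post_init__(self):
        if not (0.0 < self.slip_factor <= 1.0):
            raise ValueError("slip factor must be in (0, 1]")
        for name in ("k_inc", "k_dif", "k_fric", "k_par"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.c_ref_mm <= 0:
            raise ValueError("reference chord must be positive")


def _cot(angle_deg: float) -> float:
    if angle_deg <= 0:
        raise ValueError(f"blade angle {angle_deg} deg hits the cotangent singularity")
    return 1.0 / math.tan(math.radians(angle_deg))


def simulate_point(
    design: BladeDesign,
    omega_rpm: float,
    q_lpm: np.ndarray | float,
    constants: PumpConstants = PumpConstants(),
    losses: LossCoefficients = LossCoefficients(),
):
    """Head (mmHg), efficiency and shaft power (W) at given flow(s)."""
    if omega_rpm <= 0:
        raise ValueError("rotational speed must be positive")
    q = np.asarray(q_lpm, dtype=float) * units.LPM_TO_M3S
    w = units.rpm_to_rads(omega_rpm)
    rho = constants.density_kgm3
    r_m = constants.mid_radius_mm * units.MM_TO_M
    area = constants.annulus_area_m2

    cot_b1 = _cot(design.beta1)
    cot_b2 = _cot(design.beta2)
    cot_a2 = _cot(design.alpha2)

    u = w * r_m
    c_x = q / area
    c_th = losses.slip_factor * (u - c_x * cot_b2)

    euler = rho * u * c_th
    inc_imp = losses.k_inc * 0.5 * rho * (u - c_x * cot_b1) ** 2
    inc_dif = losses.k_dif * 0.5 * rho * (c_th - c_x * cot_a2) ** 2
    chord_ratio = (design.cl_imp + design.cl_diff) / losses.c_ref_mm
    drag = losses.k_fric * chord_ratio * 0.5 * rho * c_x**2

    dp_pa = euler - inc_imp - inc_dif - drag
    power_w = rho * q * u * c_th + losses.k_par * rho * w**3 * r_m**5
    eta = q * dp_pa / power_w
    return dp_pa * 1.0 / units.MMHG_TO_PA, eta, power_w


def simulate_curve(
    design: BladeDesign,
    omega_rpm: float,
    flow_grid_lpm: Sequence[float] = DEFAULT_FLOW_GRID_LPM,
    constants: PumpConstants = PumpConstants(),
    losses: LossCoefficients = LossCoefficients(),
    noise_sd_mmhg: float = 0.0,
    seed: Optional[int] = None,
) -> PerformanceCurve:
    """Simulate the HQ and etaQ curves of one design at one speed.

    The flow grid must be strictly increasing and positive. When
    ``noise_sd_mmhg`` > 0, i.i.d. Gaussian noise is added to the pressure
    head only (efficiency is left at its noise-free value) and a seed is
    required so runs are reproducible.
    """
    q = np.asarray(flow_grid_lpm, dtype=float)
    if q.size < 2 or np.any(q <= 0) or np.any(np.diff(q) <= 0):
        raise ValueError("flow grid must be strictly increasing and positive")
    dp_mmhg, eta, _ = simulate_point(design, omega_rpm, q, constants, losses)
    if noise_sd_mmhg > 0:
        if seed is None:
            raise ValueError("a seed is required when noise_sd_mmhg > 0")
        rng = np.random.default_rng(seed)
        dp_mmhg = dp_mmhg + rng.normal(0.0, noise_sd_mmhg, size=dp_mmhg.shape)
    return PerformanceCurve(
        design_id=design.design_id,
        omega_rpm=float(omega_rpm),
        q_lpm=q,
        dp_mmhg=dp_mmhg,
        eta=eta,
    )


def zero_incidence_flow_lpm(
    design: BladeDesign,
    omega_rpm: float,
    constants: PumpConstants = PumpConstants(),
) -> float:
    """Flow at which the impeller incidence loss vanishes (c_x cot beta1 = U)."""
    w = units.rpm_to_rads(omega_rpm)
    u = w * constants.mid_radius_mm * units.MM_TO_M
    c_x = u / _cot(design.beta1)
    return units.m3s_to_lpm(c_x * constants.annulus_area_m2)
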