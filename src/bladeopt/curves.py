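"""Performance curves and similitude (affinity) scaling.

A pump running at fixed speed omega is characterised by its HQ curve
(pressure head dP vs flow Q) and its etaQ curve (efficiency vs flow). For
geometrically identical pumps the affinity laws say both collapse onto a
single dimensionless curve in the flow and head coefficients

    phi = Q / (omega D^3),    psi = dP / (rho omega^2 D^2),

so a curve measured at one speed can be rescaled exactly to any other:
Q ~ omega, dP ~ omega^2, eta invariant at matched phi.

To place a pump at a target operating point (Q1, dP1) the HQ curve at the
simulation speed omega2 is fitted with a quartic

    dP = c1 Q^4 + c2 Q^3 + c3 Q^2 + c4 Q + c5

and intersected with the affinity parabola dP = dP1 (Q/Q1)^2 through the
target; the intersection flow Q2 solves

    c1 Q2^4 + c2 Q2^3 + (c3 - dP1/Q1^2) Q2^2 + c4 Q2 + c5 = 0,

giving the required speed omega1 = omega2 * Q1/Q2.

Units at this interface are clinical: L/min, mmHg, rpm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import units
from .geometry import PumpConstants

__all__ = [
    "OperatingPoint",
    "PerformanceCurve",
    "QuarticFit",
    "ScalingResult",
    "NoIntersectionError",
    "fit_quartic",
    "phi_psi",
    "match_operating_point",
    "scaled_speed",
    "rescale_curve",
    "scale_to_operating_point",
    "efficiency_at",
    "pressure_at",
    "curve_rmse",
    "specific_speed",
    "reynolds_rotational",
    "curves_to_frame",
    "curves_from_frame",
]

CURVE_COLUMNS = ("design_id", "omega_rpm", "q_lpm", "dp_mmhg", "eta")


class NoIntersectionError(ValueError):
    """The affinity parabola through the target never meets the fitted curve."""

    def __init__(self, message: str, roots: Sequence[complex]):
        super().__init__(f"{message}; quartic root set: {list(roots)}")
        self.roots = list(roots)


@dataclass(frozen=True)
class OperatingPoint:
    """A (flow, pressure-head) target, e.g. 2 L/min at 70 mmHg."""

    q_lpm: float
    dp_mmhg: float
    label: str = ""

    def __post_init__(self):
        if self.q_lpm <= 0 or self.dp_mmhg <= 0:
            raise ValueError("operating point flow and head must be positive")


@dataclass(frozen=True)
class PerformanceCurve:
    """Sampled (Q, dP, eta) points at one rotational speed."""

    design_id: str
    omega_rpm: float
    q_lpm: np.ndarray
    dp_mmhg: np.ndarray
    eta: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q_lpm, dtype=float)
        dp = np.asarray(self.dp_mmhg, dtype=float)
        eta = np.asarray(self.eta, dtype=float)
        if not (len(q) == len(dp) == len(eta)):
            raise ValueError("q, dp and eta must have equal length")
        if np.any(np.diff(q) <= 0):
            raise ValueError("flow samples must be strictly increasing")
        if not np.all(np.isfinite(np.concatenate([q, dp, eta]))):
            raise ValueError("curve samples must be finite")
        object.__setattr__(self, "q_lpm", q)
        object.__setattr__(self, "dp_mmhg", dp)
        object.__setattr__(self, "eta", eta)
        if self.omega_rpm <= 0:
            raise ValueError("rotational speed must be positive")

    def flow_range(self) -> Tuple[float, float]:
        return float(self.q_lpm[0]), float(self.q_lpm[-1])


@dataclass(frozen=True)
class QuarticFit:
    """Least-squares quartic dP(Q), coefficients c1..c5 in descending powers."""

    coefficients: np.ndarray  # (5,) mmHg / (L/min)^k
    rmse_mmhg: float
    valid_range: Tuple[float, float]

    def __call__(self, q_lpm):
        return np.polyval(self.coefficients, q_lpm)


@dataclass(frozen=True)
class ScalingResult:
    """Outcome of scaling a curve through a target operating point."""

    omega_scaled_rpm: float
    q2_lpm: float
    dp2_mmhg: float
    scaled_curve: PerformanceCurve
    extrapolated: bool
    fit: QuarticFit
    target: OperatingPoint


def fit_quartic(curve: PerformanceCurve) -> QuarticFit:
    """Ordinary least-squares quartic of dP against Q.

    Requires at least five samples with distinct flows; returns the
    coefficients, the in-sample RMSE and the fitted flow range.
    """
    q, dp = curve.q_lpm, curve.dp_mmhg
    if len(q) < 5:
        raise ValueError("quartic fit needs at least 5 samples")
    if len(np.unique(q)) < len(q):
        raise ValueError("duplicate flow values make the quartic fit rank-deficient")
    coeffs = np.polyfit(q, dp, 4)
    resid = np.polyval(coeffs, q) - dp
    return QuarticFit(
        coefficients=coeffs,
        rmse_mmhg=float(np.sqrt(np.mean(resid**2))),
        valid_range=(float(q[0]), float(q[-1])),
    )


def phi_psi(
    q_lpm: float,
    dp_mmhg: float,
    omega_rpm: float,
    constants: PumpConstants = PumpConstants(),
) -> Tuple[float, float]:
    """Dimensionless flow and head coefficients phi = Q/(omega D^3), psi = dP/(rho omega^2 D^2)."""
    if omega_rpm <= 0:
        raise ValueError("omega must be positive")
    w = units.rpm_to_rads(omega_rpm)
    d = constants.diameter_mm * units.MM_TO_M
    phi = units.lpm_to_m3s(q_lpm) / (w * d**3)
    psi = units.mmhg_to_pa(dp_mmhg) / (constants.density_kgm3 * w**2 * d**2)
    return phi, psi


def _polish_root(poly: np.ndarray, q: float, n_iter: int = 3) -> float:
    """Newton-polish a real root of the given polynomial."""
    dpoly = np.polyder(poly)
    for _ in range(n_iter):
        f = np.polyval(poly, q)
        df = np.polyval(dpoly, q)
        if df == 0:
            break
        q = q - f / df
    return float(q)


def match_operating_point(
    fit: QuarticFit, target: OperatingPoint
) -> Tuple[float, float, bool]:
    """Find the point on the fitted curve that shares phi, psi with the target.

    Solves the quartic intersection equation and returns (Q2, dP2,
    extrapolated). Root policy: real positive roots only; roots inside the
    fit's valid range are preferred, the one nearest the target flow wins
    (with a warning when several are in range); when only out-of-range
    positive roots exist, the one nearest the range is taken and the
    extrapolated flag is set. No intersection at all raises
    ``NoIntersectionError`` with the full root set.
    """
    c = fit.coefficients.copy()
    q1, dp1 = target.q_lpm, target.dp_mmhg
    c[2] -= dp1 / q1**2
    roots = np.roots(c)
    real = roots[np.abs(roots.imag) < 1e-9 * np.maximum(1.0, np.abs(roots.real))].real
    positive = np.array(sorted(r for r in real if r > 0))
    if positive.size == 0:
        raise NoIntersectionError(
            f"no real positive intersection with target ({q1} L/min, {dp1} mmHg)", roots
        )
    positive = np.array([_polish_root(c, r) for r in positive])
    lo, hi = fit.valid_range
    in_range = positive[(positive >= lo) & (positive <= hi)]
    if in_range.size > 0:
        if in_range.size > 1:
            warnings.warn(
                f"multiple in-range intersections {in_range}; choosing nearest target flow",
                stacklevel=2,
            )
        q2 = float(in_range[np.argmin(np.abs(in_range - q1))])
        extrapolated = False
    else:
        dist = np.minimum(np.abs(positive - lo), np.abs(positive - hi))
        q2 = float(positive[np.argmin(dist)])
        extrapolated = True
        warnings.warn(
            f"intersection Q2={q2:.4g} L/min outside fitted range ({lo}, {hi}); extrapolating",
            stacklevel=2,
        )
    dp2 = float(fit(q2))
    return q2, dp2, extrapolated


def scaled_speed(omega2_rpm: float, q1_lpm: float, q2_lpm: float) -> float:
    """Speed omega1 = omega2 * Q1/Q2 that moves (Q2, dP2) onto (Q1, dP1) by affinity."""
    if q2_lpm <= 0:
        raise ValueError("Q2 must be positive")
    return omega2_rpm * q1_lpm / q2_lpm


def rescale_curve(curve: PerformanceCurve, omega_new_rpm: float) -> PerformanceCurve:
    """Affinity-rescale a curve to a new speed: Q ~ omega, dP ~ omega^2, eta fixed."""
    if omega_new_rpm <= 0:
        raise ValueError("new speed must be positive")
    r = omega_new_rpm / curve.omega_rpm
    return PerformanceCurve(
        design_id=curve.design_id,
        omega_rpm=omega_new_rpm,
        q_lpm=curve.q_lpm * r,
        dp_mmhg=curve.dp_mmhg * r**2,
        eta=curve.eta.copy(),
    )


def scale_to_operating_point(
    curve: PerformanceCurve, target: OperatingPoint
) -> ScalingResult:
    """Scale a curve so it passes through the target operating point.

    Fits the quartic, intersects it with the affinity parabola through the
    target, and rescales the whole curve to the implied speed.
    """
    fit = fit_quartic(curve)
    q2, dp2, extrapolated = match_operating_point(fit, target)
    omega1 = scaled_speed(curve.omega_rpm, target.q_lpm, q2)
    return ScalingResult(
        omega_scaled_rpm=omega1,
        q2_lpm=q2,
        dp2_mmhg=dp2,
        scaled_curve=rescale_curve(curve, omega1),
        extrapolated=extrapolated,
        fit=fit,
        target=target,
    )


def _interp_in_range(curve: PerformanceCurve, q_lpm: float, values: np.ndarray) -> float:
    lo, hi = curve.flow_range()
    if not (lo <= q_lpm <= hi):
        raise ValueError(
            f"flow {q_lpm} L/min outside sampled range ({lo}, {hi}); refusing to extrapolate"
        )
    return float(np.interp(q_lpm, curve.q_lpm, values))


def efficiency_at(curve: PerformanceCurve, q_lpm: float) -> float:
    """Piecewise-linear interpolation of eta at the given flow (no extrapolation)."""
    return _interp_in_range(curve, q_lpm, curve.eta)


def pressure_at(curve: PerformanceCurve, q_lpm: float) -> float:
    """Piecewise-linear interpolation of dP at the given flow (no extrapolation)."""
    return _interp_in_range(curve, q_lpm, curve.dp_mmhg)


def curve_rmse(a: PerformanceCurve, b: PerformanceCurve, which: str = "dp") -> float:
    """RMS difference of dP (mmHg) or eta between two curves.

    Curve ``b`` is linearly interpolated onto the part of ``a``'s flow grid
    that both curves cover; non-overlapping ranges raise.
    """
    if which not in ("dp", "eta"):
        raise ValueError("which must be 'dp' or 'eta'")
    lo = max(a.q_lpm[0], b.q_lpm[0])
    hi = min(a.q_lpm[-1], b.q_lpm[-1])
    if lo > hi:
        raise ValueError("curves have non-overlapping flow ranges")
    mask = (a.q_lpm >= lo) & (a.q_lpm <= hi)
    qa = a.q_lpm[mask]
    fa = (a.dp_mmhg if which == "dp" else a.eta)[mask]
    fb = np.interp(qa, b.q_lpm, b.dp_mmhg if which == "dp" else b.eta)
    return float(np.sqrt(np.mean((fa - fb) ** 2)))


def specific_speed(
    omega_rpm: float,
    op: OperatingPoint,
    constants: PumpConstants = PumpConstants(),
) -> float:
    """Dimensionless specific speed N_s = omega sqrt(Q) / (gH)^(3/4).

    With head H = dP/(rho g), the product gH equals dP/rho, so gravity
    cancels and N_s depends only on speed, flow, head and density.
    """
    if omega_rpm <= 0:
        raise ValueError("omega must be positive")
    w = units.rpm_to_rads(omega_rpm)
    q = units.lpm_to_m3s(op.q_lpm)
    gh = units.mmhg_to_pa(op.dp_mmhg) / constants.density_kgm3
    return w * math.sqrt(q) / gh**0.75


def reynolds_rotational(
    omega_rpm: float, constants: PumpConstants = PumpConstants()
) -> float:
    """Rotational Reynolds number omega D^2 rho / mu (omega in rad/s)."""
    if omega_rpm < 0:
        raise ValueError("omega must be non-negative")
    w = units.rpm_to_rads(omega_rpm)
    d = constants.diameter_mm * units.MM_TO_M
    return w * d**2 * constants.density_kgm3 / constants.viscosity_pas


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def curves_to_frame(curves: Sequence[PerformanceCurve]) -> pd.DataFrame:
    """Long-format frame with schema design_id,omega_rpm,q_lpm,dp_mmhg,eta."""
    parts = []
    for c in curves:
        parts.append(
            pd.DataFrame(
                {
                    "design_id": c.design_id,
                    "omega_rpm": c.omega_rpm,
                    "q_lpm": c.q_lpm,
                    "dp_mmhg": c.dp_mmhg,
                    "eta": c.eta,
                }
            )
        )
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=CURVE_COLUMNS)


def curves_from_frame(frame: pd.DataFrame) -> List[PerformanceCurve]:
    out = []
    for (design_id, omega), grp in frame.groupby(["design_id", "omega_rpm"], sort=False):
        grp = grp.sort_values("q_lpm")
        out.append(
            PerformanceCurve(
                design_id=str(design_id),
                omega_rpm=float(omega),
                q_lpm=grp["q_lpm"].to_numpy(float),
                dp_mmhg=grp["dp_mmhg"].to_numpy(float),
                eta=grp["eta"].to_numpy(float),
            )
        )
    return out
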