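"""Blade geometry: designs, circular-arc camber lines, factorial enumeration
and sequential constraint boxes.

An axial blood pump of the class modelled here has a two-blade impeller
followed by a three-blade diffuser inside a 7.7 mm shroud. The mid-span
section of every blade is a circular arc fully determined by its inlet
angle, outlet angle and chord length, with all angles measured from the
tangential direction. Five parameters govern a complete design: the
impeller inlet and outlet angles beta1 and beta2, the diffuser inlet angle
alpha2, and the impeller and diffuser chord lengths. The diffuser outlet
angle is fixed at 90 deg so the discharged flow is axial.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .units import MM_TO_M

__all__ = [
    "PumpConstants",
    "BladeDesign",
    "CamberArc",
    "ConstraintBox",
    "FactorialSet",
    "FeasibilityReport",
    "PARAM_NAMES",
    "camber_arc",
    "factorial_designs",
    "constraint_box",
    "validate_design",
    "designs_to_frame",
    "designs_from_frame",
]

#: canonical parameter ordering used everywhere (design vectors, CSV columns)
PARAM_NAMES: Tuple[str, ...] = ("beta1", "beta2", "alpha2", "cl_imp", "cl_diff")

#: CSV column names for the five parameters
PARAM_COLUMNS: Tuple[str, ...] = (
    "beta1_deg",
    "beta2_deg",
    "alpha2_deg",
    "cl_imp_mm",
    "cl_diff_mm",
)

#: number of boundary-constraint iterations supported (indices 0..4)
N_CONSTRAINT_ITERATIONS = 5

#: iteration-0 (low, high) extremes of the factorial study, per parameter
ITERATION0_BOUNDS: Dict[str, Tuple[float, float]] = {
    "beta1": (25.0, 40.0),
    "beta2": (75.0, 90.0),
    "alpha2": (25.0, 40.0),
    "cl_imp": (9.0, 14.0),
    "cl_diff": (9.0, 14.0),
}


@dataclass(frozen=True)
class PumpConstants:
    """Fixed pump dimensions and blood properties.

    Lengths in mm (tip gap in um), density in kg/m^3, viscosity in Pa*s.
    The reference diameter is the shroud diameter, 7.7 mm by default.
    """

    hub_radius_mm: float = 1.0
    shroud_radius_mm: float = 3.85
    tip_gap_um: float = 100.0
    blade_thickness_mm: float = 0.5
    n_impeller_blades: int = 2
    n_diffuser_blades: int = 3
    diffuser_outlet_angle_deg: float = 90.0
    density_kgm3: float = 1050.0
    viscosity_pas: float = 0.0035

    def __post_init__(self):
        if self.hub_radius_mm <= 0 or self.shroud_radius_mm <= 0:
            raise ValueError("radii must be positive")
        if self.hub_radius_mm >= self.shroud_radius_mm:
            raise ValueError("hub radius must be smaller than shroud radius")
        if self.tip_gap_um <= 0 or self.blade_thickness_mm <= 0:
            raise ValueError("tip gap and blade thickness must be positive")
        if self.diffuser_outlet_angle_deg != 90.0:
            raise ValueError("diffuser outlet angle is fixed at 90 deg from tangential")
        if self.density_kgm3 <= 0 or self.viscosity_pas <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def diameter_mm(self) -> float:
        """Reference diameter D = 2 x shroud radius."""
        return 2.0 * self.shroud_radius_mm

    @property
    def mid_radius_mm(self) -> float:
        """Mid-span radius (hub + shroud)/2, the plane of the camber lines."""
        return 0.5 * (self.hub_radius_mm + self.shroud_radius_mm)

    @property
    def annulus_area_m2(self) -> float:
        """Flow annulus area pi*(r_shroud^2 - r_hub^2) in m^2."""
        rs = self.shroud_radius_mm * MM_TO_M
        rh = self.hub_radius_mm * MM_TO_M
        return math.pi * (rs * rs - rh * rh)


@dataclass(frozen=True)
class BladeDesign:
    """The five geometry-governing parameters of one pump design.

    Angles in degrees from the tangential direction, chords in mm.
    The impeller outlet angle must exceed the inlet angle so that the
    blade is correctly oriented (it must turn the flow toward axial).
    """

    beta1: float
    beta2: float
    alpha2: float
    cl_imp: float
    cl_diff: float
    design_id: str = ""

    def __post_init__(self):
        for name in ("beta1", "beta2", "alpha2"):
            a = getattr(self, name)
            if not (0.0 < a <= 90.0):
                raise ValueError(f"{name}={a} outside (0, 90] deg")
        if self.beta2 <= self.beta1:
            raise ValueError(
                f"impeller outlet angle beta2={self.beta2} must exceed inlet angle beta1={self.beta1}"
            )
        for name in ("cl_imp", "cl_diff"):
            c = getattr(self, name)
            if c <= 0:
                raise ValueError(f"{name}={c} must be positive")

    def as_vector(self) -> np.ndarray:
        """Parameters in the canonical (beta1, beta2, alpha2, cl_imp, cl_diff) order."""
        return np.array([self.beta1, self.beta2, self.alpha2, self.cl_imp, self.cl_diff])

    @classmethod
    def from_vector(cls, x: Sequence[float], design_id: str = "") -> "BladeDesign":
        return cls(*(float(v) for v in x), design_id=design_id)

    def impeller_key(self) -> Tuple[float, float, float]:
        """Parameters that define the impeller alone."""
        return (self.beta1, self.beta2, self.cl_imp)

    def diffuser_key(self) -> Tuple[float, float]:
        """Parameters that define the diffuser alone."""
        return (self.alpha2, self.cl_diff)


@dataclass(frozen=True)
class CamberArc:
    """A circular-arc camber line in the unwrapped blade-to-blade plane.

    x is tangential, y is axial, units mm. The inlet endpoint sits at the
    origin; the chord runs along the stagger direction (the bisector of the
    inlet and outlet tangent angles). ``arc_radius_mm`` is ``math.inf`` for
    a straight (zero-camber) blade.
    """

    chord_mm: float
    inlet_angle_deg: float
    outlet_angle_deg: float
    turning_angle_deg: float
    arc_radius_mm: float
    points: np.ndarray  # (n, 2) array of (x, y) mm

    def sagitta_mm(self) -> float:
        """Maximum camber height above the chord, R*(1 - cos(theta/2))."""
        if math.isinf(self.arc_radius_mm):
            return 0.0
        half = math.radians(abs(self.turning_angle_deg)) / 2.0
        return self.arc_radius_mm * (1.0 - math.cos(half))

    def to_text(self) -> str:
        """Plain-text point list, one `x_mm y_mm` pair per line."""
        return "\n".join(f"{x:.9f} {y:.9f}" for x, y in self.points)


def camber_arc(
    inlet_angle_deg: float,
    outlet_angle_deg: float,
    chord_mm: float,
    n_points: int = 50,
) -> CamberArc:
    """Construct the circular-arc camber line for one blade section.

    The arc is the unique circle segment whose endpoint tangents match the
    inlet and outlet angles and whose endpoints are ``chord_mm`` apart:
    R = C / (2 sin(theta/2)) with turning angle theta = outlet - inlet.
    When theta = 0 the blade is straight and the radius is infinite.
    """
    if chord_mm <= 0:
        raise ValueError("chord must be positive")
    for name, a in (("inlet", inlet_angle_deg), ("outlet", outlet_angle_deg)):
        if not (0.0 < a <= 90.0):
            raise ValueError(f"{name} angle {a} outside (0, 90] deg")
    if n_points < 2:
        raise ValueError("need at least 2 sampled points")

    a_in = math.radians(inlet_angle_deg)
    a_out = math.radians(outlet_angle_deg)
    theta = a_out - a_in
    angles = np.linspace(a_in, a_out, n_points)

    if abs(theta) < 1e-12:
        # zero camber: straight segment along the common tangent direction
        t = np.linspace(0.0, chord_mm, n_points)
        pts = np.column_stack([t * math.cos(a_in), t * math.sin(a_in)])
        radius = math.inf
    else:
        # signed generating radius; |rho| is the geometric arc radius
        rho = chord_mm / (2.0 * math.sin(theta / 2.0))
        x = rho * (np.sin(angles) - math.sin(a_in))
        y = rho * (math.cos(a_in) - np.cos(angles))
        pts = np.column_stack([x, y])
        radius = abs(rho)

    return CamberArc(
        chord_mm=chord_mm,
        inlet_angle_deg=inlet_angle_deg,
        outlet_angle_deg=outlet_angle_deg,
        turning_angle_deg=outlet_angle_deg - inlet_angle_deg,
        arc_radius_mm=radius,
        points=pts,
    )


@dataclass(frozen=True)
class ConstraintBox:
    """Per-parameter (min, max) bounds for one boundary-constraint iteration."""

    iteration_index: int
    bounds: Dict[str, Tuple[float, float]]

    def __post_init__(self):
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            if lo >= hi:
                raise ValueError(f"{name}: min {lo} >= max {hi}")

    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in PARAM_NAMES])

    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in PARAM_NAMES])

    def contains(self, x: Sequence[float], atol: float = 1e-12) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower() - atol) and np.all(x <= self.upper() + atol))


def constraint_box(iteration_index: int) -> ConstraintBox:
    """Bounds for constraint iteration k (0 <= k <= 4).

    Iteration 0 uses the extremes of the original factorial study; each
    further iteration widens the angle bounds by 5 deg per side and the
    chord bounds by 1 mm per side, except that the impeller outlet angle
    is capped at 90 deg (measured from tangential, it cannot exceed axial).
    """
    k = iteration_index
    if not (0 <= k < N_CONSTRAINT_ITERATIONS) or int(k) != k:
        raise ValueError(f"iteration index must be an integer in 0..{N_CONSTRAINT_ITERATIONS - 1}")
    k = int(k)
    bounds = {
        "beta1": (25.0 - 5.0 * k, 40.0 + 5.0 * k),
        "beta2": (75.0 - 5.0 * k, 90.0),
        "alpha2": (25.0 - 5.0 * k, 40.0 + 5.0 * k),
        "cl_imp": (9.0 - 1.0 * k, 14.0 + 1.0 * k),
        "cl_diff": (9.0 - 1.0 * k, 14.0 + 1.0 * k),
    }
    return ConstraintBox(iteration_index=k, bounds=bounds)


@dataclass(frozen=True)
class FactorialSet:
    """Result of a two-level factorial enumeration.

    Behaves as a sequence of the feasible designs; parameter combinations
    that violate beta2 > beta1 are kept in ``infeasible`` (as parameter
    dictionaries) rather than silently dropped.
    """

    designs: Tuple[BladeDesign, ...]
    infeasible: Tuple[Dict[str, float], ...] = ()

    def __len__(self) -> int:
        return len(self.designs)

    def __iter__(self) -> Iterator[BladeDesign]:
        return iter(self.designs)

    def __getitem__(self, i):
        return self.designs[i]

    def unique_impellers(self) -> int:
        return len({d.impeller_key() for d in self.designs})

    def unique_diffusers(self) -> int:
        return len({d.diffuser_key() for d in self.designs})


def factorial_designs(
    low_high: Dict[str, Tuple[float, float]] | None = None,
) -> FactorialSet:
    """Enumerate the full two-level factorial over the five parameters.

    ``low_high`` maps each parameter name to its (low, high) levels;
    defaults to the iteration-0 extremes, which reproduce the original
    32-design study (8 unique impellers x 4 unique diffusers). Ordering is
    lexicographic over (beta1, beta2, alpha2, cl_imp, cl_diff) with low
    before high, so design IDs are stable. A collapsed factor (low == high)
    contributes a single level, halving the count. Combinations violating
    beta2 > beta1 are collected in the result's ``infeasible`` list.
    """
    low_high = dict(ITERATION0_BOUNDS if low_high is None else low_high)
    levels: List[Tuple[float, ...]] = []
    for name in PARAM_NAMES:
        lo, hi = low_high[name]
        if lo > hi:
            raise ValueError(f"{name}: low {lo} > high {hi}")
        levels.append((lo,) if lo == hi else (lo, hi))

    designs: List[BladeDesign] = []
    infeasible: List[Dict[str, float]] = []
    i = 0
    for combo in itertools.product(*levels):
        params = dict(zip(PARAM_NAMES, combo))
        if params["beta2"] <= params["beta1"]:
            infeasible.append(params)
            continue
        designs.append(BladeDesign(**params, design_id=f"d{i:02d}"))
        i += 1
    return FactorialSet(designs=tuple(designs), infeasible=tuple(infeasible))


@dataclass(frozen=True)
class FeasibilityReport:
    """Per-constraint satisfaction of one design against one box."""

    beta_ordering_ok: bool
    in_bounds: Dict[str, bool]

    @property
    def feasible(self) -> bool:
        return self.beta_ordering_ok and all(self.in_bounds.values())


def validate_design(
    design: "BladeDesign | Sequence[float]", box: ConstraintBox
) -> FeasibilityReport:
    """Report whether a design satisfies beta2 > beta1 and the box bounds.

    Accepts either a ``BladeDesign`` or a raw parameter vector in canonical
    order, so that candidates violating the beta ordering (which cannot be
    constructed as ``BladeDesign``) can still be reported on.
    """
    if isinstance(design, BladeDesign):
        x = design.as_vector()
    else:
        x = np.asarray(design, dtype=float)
        if x.shape != (5,):
            raise ValueError("expected 5 parameters (beta1, beta2, alpha2, cl_imp, cl_diff)")
    in_bounds = {}
    for name, v in zip(PARAM_NAMES, x):
        lo, hi = box.bounds[name]
        in_bounds[name] = bool(lo <= v <= hi)
    return FeasibilityReport(beta_ordering_ok=bool(x[1] > x[0]), in_bounds=in_bounds)


# ---------------------------------------------------------------------------
# I/O: designs as CSV / JSON-friendly frames
# ---------------------------------------------------------------------------

def designs_to_frame(designs: Sequence[BladeDesign]) -> pd.DataFrame:
    """Designs as a DataFrame with the canonical CSV schema."""
    rows = [
        {
            "design_id": d.design_id,
            "beta1_deg": d.beta1,
            "beta2_deg": d.beta2,
            "alpha2_deg": d.alpha2,
            "cl_imp_mm": d.cl_imp,
            "cl_diff_mm": d.cl_diff,
        }
        for d in designs
    ]
    return pd.DataFrame(rows, columns=["design_id", *PARAM_COLUMNS])


def designs_from_frame(frame: pd.DataFrame) -> List[BladeDesign]:
    return [
        BladeDesign(
            beta1=row["beta1_deg"],
            beta2=row["beta2_deg"],
            alpha2=row["alpha2_deg"],
            cl_imp=row["cl_imp_mm"],
            cl_diff=row["cl_diff_mm"],
            design_id=str(row["design_id"]),
        )
        for _, row in frame.iterrows()
    ]
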