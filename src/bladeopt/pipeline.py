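"""End-to-end inverse-design workflow.

Stages: enumerate the 32 factorial designs -> simulate each with the
virtual pump at the survey speed (20,000 rpm) -> affinity-scale every curve
through the target operating point (2 L/min at 70 mmHg by default) ->
assemble the surrogate training set -> per (surrogate x constraint
iteration): train, optimise with the GA (with a seeded repeatability
study), verify the optimum by a fresh simulation scaled to the target, and
record predicted vs verified efficiency -> retarget the winning design to
alternate operating points by rescaling its existing curve (no new
simulation).

Verified efficiencies always come from simulation, never from a surrogate;
efficiency gains are computed from verified values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .curves import (
    OperatingPoint,
    PerformanceCurve,
    ScalingResult,
    curves_to_frame,
    efficiency_at,
    scale_to_operating_point,
)
from .ga import GAConfig, RepeatabilityReport, repeatability_study
from .geometry import (
    BladeDesign,
    FactorialSet,
    PumpConstants,
    constraint_box,
    designs_to_frame,
    factorial_designs,
)
from .surrogates import DesignDataset, SurrogateModel, build_dataset, fit_brann, fit_gpr, fit_mlr
from .virtual_pump import DEFAULT_FLOW_GRID_LPM, LossCoefficients, simulate_curve

__all__ = [
    "PipelineConfig",
    "BaselineResult",
    "OptimisationRow",
    "RetargetResult",
    "derive_seed",
    "run_baseline",
    "train_surrogate",
    "run_optimisation",
    "retarget",
    "run_all",
    "write_report",
]

logger = logging.getLogger(__name__)

DEFAULT_TARGET = OperatingPoint(2.0, 70.0, label="OP_2L/min")
DEFAULT_ALTERNATES = (
    OperatingPoint(1.0, 60.0, label="OP_1L/min"),
    OperatingPoint(0.5, 50.0, label="OP_0.5L/min"),
)


def derive_seed(master_seed: int, tag: str) -> int:
    """Stable per-stage seed: mixes the master seed with a CRC of the tag."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PipelineConfig:
    target_op: OperatingPoint = DEFAULT_TARGET
    alternate_ops: Tuple[OperatingPoint, ...] = DEFAULT_ALTERNATES
    simulation_speed_rpm: float = 20000.0
    flow_grid_lpm: Tuple[float, ...] = DEFAULT_FLOW_GRID_LPM
    constraint_iterations: Tuple[int, ...] = (0, 1, 2, 3, 4)
    surrogate_kinds: Tuple[str, ...] = ("mlr", "gpr", "brann")
    ga: GAConfig = GAConfig()
    constants: PumpConstants = PumpConstants()
    losses: LossCoefficients = LossCoefficients()
    n_ga_repeats: int = 5
    min_surviving_designs: int = 20
    master_seed: int = 0

    def __post_init__(self):
        qmin, qmax = min(self.flow_grid_lpm), max(self.flow_grid_lpm)
        for op in (self.target_op, *self.alternate_ops):
            if not (qmin <= op.q_lpm <= qmax):
                raise ValueError(
                    f"flow grid ({qmin}, {qmax}) does not cover operating point {op.label or op.q_lpm}"
                )

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _to_jsonable(obj):
    if isinstance(obj, (PipelineConfig, GAConfig, PumpConstants, LossCoefficients, OperatingPoint)):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass(frozen=True)
class BaselineResult:
    """The factorial survey: raw and scaled curves, dataset and best design."""

    designs: FactorialSet
    raw_curves: Tuple[PerformanceCurve, ...]
    scalings: Dict[str, ScalingResult]  # by design_id; only designs that scaled
    dataset: DesignDataset
    best_design: BladeDesign
    best_eta: float
    failed: Tuple[Tuple[str, str], ...]  # (design_id, reason)


def run_baseline(config: PipelineConfig = PipelineConfig()) -> BaselineResult:
    """Simulate, scale and rank the factorial designs."""
    designs = factorial_designs()
    raw, scaled_ok, scalings, failed = [], [], {}, []
    kept_designs = []
    for d in designs:
        curve = simulate_curve(
            d,
            config.simulation_speed_rpm,
            config.flow_grid_lpm,
            config.constants,
            config.losses,
        )
        raw.append(curve)
        try:
            sc = scale_to_operating_point(curve, config.target_op)
        except ValueError as err:
            logger.warning("design %s failed scaling: %s", d.design_id, err)
            failed.append((d.design_id, str(err)))
            continue
        scalings[d.design_id] = sc
        scaled_ok.append(sc.scaled_curve)
        kept_designs.append(d)
    if len(kept_designs) < config.min_surviving_designs:
        raise RuntimeError(
            f"only {len(kept_designs)} designs scaled successfully "
            f"(need {config.min_surviving_designs}); aborting"
        )
    dataset = build_dataset(kept_designs, scaled_ok, config.target_op)
    ids = list(dataset.design_ids)
    best_i = int(np.argmax(dataset.y))
    best_id = ids[best_i]
    best_design = next(d for d in kept_designs if d.design_id == best_id)
    return BaselineResult(
        designs=designs,
        raw_curves=tuple(raw),
        scalings=scalings,
        dataset=dataset,
        best_design=best_design,
        best_eta=float(dataset.y[best_i]),
        failed=tuple(failed),
    )


def train_surrogate(
    dataset: DesignDataset, kind: str, seed: int
) -> SurrogateModel:
    if kind == "mlr":
        return fit_mlr(dataset)
    if kind == "gpr":
        return fit_gpr(dataset, seed=seed)
    if kind == "brann":
        return fit_brann(dataset, seed=seed)
    raise ValueError(f"unknown surrogate kind {kind!r}")


@dataclass(frozen=True)
class OptimisationRow:
    """One (surrogate x constraint iteration) result."""

    surrogate_kind: str
    iteration_index: int
    status: str  # 'ok' | 'failed'
    reason: str = ""
    design: Optional[BladeDesign] = None
    predicted_eta: float = float("nan")
    verified_eta: float = float("nan")
    rel_error_pct: float = float("nan")
    scaled_speed_rpm: float = float("nan")
    repeatability: Optional[RepeatabilityReport] = None
    ga_generations: int = 0
    surrogate_metrics: Dict[str, float] = field(default_factory=dict)


def verify_design(
    design: BladeDesign, config: PipelineConfig, target: Optional[OperatingPoint] = None
) -> Tuple[float, float, ScalingResult]:
    """Simulate a design afresh and measure its efficiency at the target.

    Returns (verified eta, scaled speed rpm, full scaling result).
    """
    target = target or config.target_op
    curve = simulate_curve(
        design,
        config.simulation_speed_rpm,
        config.flow_grid_lpm,
        config.constants,
        config.losses,
    )
    sc = scale_to_operating_point(curve, target)
    eta = efficiency_at(sc.scaled_curve, target.q_lpm)
    return eta, sc.omega_scaled_rpm, sc


def run_optimisation(
    config: PipelineConfig,
    dataset: DesignDataset,
    surrogate_kind: str,
    iteration_index: int,
) -> OptimisationRow:
    """Train a surrogate, optimise under one constraint box, verify by simulation."""
    box = constraint_box(iteration_index)
    try:
        model = train_surrogate(
            dataset,
            surrogate_kind,
            seed=derive_seed(config.master_seed, f"surrogate/{surrogate_kind}"),
        )
    except Exception as err:  # noqa: BLE001 - row-level containment by contract
        logger.warning("surrogate %s failed: %s", surrogate_kind, err)
        return OptimisationRow(
            surrogate_kind=surrogate_kind,
            iteration_index=iteration_index,
            status="failed",
            reason=f"surrogate training failed: {err}",
        )

    def objective(x: np.ndarray) -> np.ndarray:
        return -model.predict_eta(x)

    seeds = [
        derive_seed(config.master_seed, f"ga/{surrogate_kind}/{iteration_index}/{i}")
        for i in range(config.n_ga_repeats)
    ]
    rep = repeatability_study(
        objective, box, config.ga, n_repeats=config.n_ga_repeats, seeds=seeds
    )
    best_x = rep.solutions[rep.best_index]
    design = BladeDesign.from_vector(
        best_x, design_id=f"opt_{surrogate_kind}_it{iteration_index}"
    )
    predicted = float(model.predict_eta(best_x.reshape(1, -1))[0])
    try:
        verified, omega1, _ = verify_design(design, config)
    except ValueError as err:
        return OptimisationRow(
            surrogate_kind=surrogate_kind,
            iteration_index=iteration_index,
            status="failed",
            reason=f"verification scaling failed: {err}",
            design=design,
            predicted_eta=predicted,
            repeatability=rep,
        )
    rel_err = 100.0 * abs(predicted - verified) / abs(verified)
    return OptimisationRow(
        surrogate_kind=surrogate_kind,
        iteration_index=iteration_index,
        status="ok",
        design=design,
        predicted_eta=predicted,
        verified_eta=verified,
        rel_error_pct=rel_err,
        scaled_speed_rpm=omega1,
        repeatability=rep,
        ga_generations=int(rep.generations.max()),
        surrogate_metrics={k: v for k, v in model.metrics.items() if np.isscalar(v)},
    )


@dataclass(frozen=True)
class RetargetResult:
    op: OperatingPoint
    eta: float
    omega_rpm: float
    scaling: ScalingResult


def retarget(curve: PerformanceCurve, op: OperatingPoint) -> RetargetResult:
    """Evaluate an existing survey-speed curve at another operating point.

    Rescales the curve through the new point and interpolates its
    efficiency there; no new simulation is performed.
    """
    sc = scale_to_operating_point(curve, op)
    return RetargetResult(
        op=op,
        eta=efficiency_at(sc.scaled_curve, op.q_lpm),
        omega_rpm=sc.omega_scaled_rpm,
        scaling=sc,
    )


@dataclass(frozen=True)
class PipelineReport:
    config: PipelineConfig
    baseline: BaselineResult
    rows: Tuple[OptimisationRow, ...]
    winner: Optional[OptimisationRow]
    retargets: Tuple[RetargetResult, ...]
    gain_points: float = float("nan")  # verified gain in percentage points of eta
    gain_relative_pct: float = float("nan")


def _select_winner(
    rows: Sequence[OptimisationRow], kind: str = "gpr", max_error_pct: float = 15.0
) -> Optional[OptimisationRow]:
    """Widest constraint iteration of the given surrogate with acceptable error."""
    ok = [
        r
        for r in rows
        if r.surrogate_kind == kind and r.status == "ok" and r.rel_error_pct < max_error_pct
    ]
    return max(ok, key=lambda r: r.iteration_index) if ok else None


def run_all(config: PipelineConfig = PipelineConfig()) -> PipelineReport:
    """Execute the full workflow and assemble the report."""
    baseline = run_baseline(config)
    rows: List[OptimisationRow] = []
    for kind in config.surrogate_kinds:
        for it in config.constraint_iterations:
            rows.append(run_optimisation(config, baseline.dataset, kind, it))
    winner = _select_winner(rows)
    retargets: List[RetargetResult] = []
    gain_pts = float("nan")
    gain_rel = float("nan")
    if winner is not None:
        curve = simulate_curve(
            winner.design,
            config.simulation_speed_rpm,
            config.flow_grid_lpm,
            config.constants,
            config.losses,
        )
        for op in config.alternate_ops:
            try:
                retargets.append(retarget(curve, op))
            except ValueError as err:
                logger.warning("retarget to %s failed: %s", op.label, err)
        gain_pts = 100.0 * (winner.verified_eta - baseline.best_eta)
        gain_rel = 100.0 * (winner.verified_eta - baseline.best_eta) / baseline.best_eta
    return PipelineReport(
        config=config,
        baseline=baseline,
        rows=tuple(rows),
        winner=winner,
        retargets=tuple(retargets),
        gain_points=gain_pts,
        gain_relative_pct=gain_rel,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _rows_frame(rows: Sequence[OptimisationRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        rec = {
            "surrogate": r.surrogate_kind,
            "iteration": r.iteration_index,
            "status": r.status,
            "reason": r.reason,
            "predicted_eta": r.predicted_eta,
            "verified_eta": r.verified_eta,
            "rel_error_pct": r.rel_error_pct,
            "scaled_speed_rpm": r.scaled_speed_rpm,
            "max_param_spread_pct": (
                r.repeatability.max_spread_pct if r.repeatability else float("nan")
            ),
        }
        if r.design is not None:
            for name, v in zip(
                ("beta1_deg", "beta2_deg", "alpha2_deg", "cl_imp_mm", "cl_diff_mm"),
                r.design.as_vector(),
            ):
                rec[name] = v
        recs.append(rec)
    return pd.DataFrame(recs)


def write_report(report: PipelineReport, outdir: str | Path) -> Dict[str, Path]:
    """Write JSON summary, CSV tables, curve CSVs and a Markdown summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    probe.write_text("ok")
    probe.unlink()

    import bladeopt

    files: Dict[str, Path] = {}
    summary = {
        "software_version": bladeopt.__version__,
        "config_hash": report.config.config_hash(),
        "master_seed": report.config.master_seed,
        "config": _to_jsonable(report.config),
        "baseline": {
            "best_design_id": report.baseline.best_design.design_id,
            "best_eta": report.baseline.best_eta,
            "n_designs": len(report.baseline.dataset),
            "failed": list(report.baseline.failed),
        },
        "rows": _rows_frame(report.rows).to_dict(orient="records"),
        "winner": None,
        "retargets": [
            {"label": r.op.label, "q_lpm": r.op.q_lpm, "dp_mmhg": r.op.dp_mmhg,
             "eta": r.eta, "omega_rpm": r.omega_rpm}
            for r in report.retargets
        ],
        "gain_points": report.gain_points,
        "gain_relative_pct": report.gain_relative_pct,
    }
    if report.winner is not None:
        summary["winner"] = {
            "surrogate": report.winner.surrogate_kind,
            "iteration": report.winner.iteration_index,
            "verified_eta": report.winner.verified_eta,
            "design": dict(zip(
                ("beta1_deg", "beta2_deg", "alpha2_deg", "cl_imp_mm", "cl_diff_mm"),
                report.winner.design.as_vector().tolist(),
            )),
        }
    files["summary_json"] = outdir / "summary.json"
    files["summary_json"].write_text(json.dumps(summary, indent=2, default=float))

    files["rows_csv"] = outdir / "optimisation_rows.csv"
    _rows_frame(report.rows).to_csv(files["rows_csv"], index=False)

    files["designs_csv"] = outdir / "designs.csv"
    designs_to_frame(list(report.baseline.designs)).to_csv(files["designs_csv"], index=False)

    files["raw_curves_csv"] = outdir / "curves_raw.csv"
    curves_to_frame(report.baseline.raw_curves).to_csv(files["raw_curves_csv"], index=False)

    files["scaled_curves_csv"] = outdir / "curves_scaled.csv"
    scaled = [sc.scaled_curve for sc in report.baseline.scalings.values()]
    curves_to_frame(scaled).to_csv(files["scaled_curves_csv"], index=False)

    md = ["# Optimisation summary", "",
          f"Baseline best eta: {report.baseline.best_eta:.4f} "
          f"({report.baseline.best_design.design_id})", "",
          "| surrogate | iteration | predicted eta | verified eta | error % |",
          "|---|---|---|---|---|"]
    for r in report.rows:
        md.append(
            f"| {r.surrogate_kind} | {r.iteration_index} | {r.predicted_eta:.4f} | "
            f"{r.verified_eta:.4f} | {r.rel_error_pct:.2f} |"
        )
    if report.winner is not None:
        md += ["",
               f"Winner: {report.winner.surrogate_kind} at iteration "
               f"{report.winner.iteration_index}, verified eta "
               f"{report.winner.verified_eta:.4f} "
               f"(+{report.gain_points:.2f} points, {report.gain_relative_pct:.1f}% relative)"]
    files["summary_md"] = outdir / "summary.md"
    files["summary_md"].write_text("\n".join(md) + "\n")
    return files
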