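"""Surrogate models of design-point efficiency.

Each surrogate maps the five blade parameters, min-max normalised to
[-1, 1], to the hydraulic efficiency interpolated at the target operating
point on the design's affinity-scaled etaQ curve. Because every curve has
been scaled through the same operating point, the rotational speed is
implied by the geometry and is not an input; the surrogate has five inputs
and one output.

Three model families are provided:

* ``fit_mlr``  - ordinary least-squares multi-linear regression (the
  benchmark); trained and evaluated on all data.
* ``fit_gpr``  - Gaussian-process regression (scikit-learn) with a choice
  of Matern 5/2 (default), squared-exponential, exponential or rational
  quadratic kernel; 5-fold cross-validation supplies the validation RMSE
  and the returned model is refitted on all data.
* ``fit_brann`` - Bayesian-regularised single-hidden-layer network (five
  tanh units) trained by Levenberg-Marquardt with evidence-framework
  hyperparameters; validated on a random holdout (5 of 32 designs at the
  default fraction).

All reported RMSEs are on the natural efficiency scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    Matern,
    RationalQuadratic,
)
from sklearn.model_selection import KFold

from .brann import BRANNTrainer, BRANNWeights
from .curves import OperatingPoint, PerformanceCurve, efficiency_at
from .geometry import BladeDesign

__all__ = [
    "DesignDataset",
    "SurrogateModel",
    "Prediction",
    "GPR_KERNELS",
    "build_dataset",
    "fit_mlr",
    "fit_gpr",
    "fit_brann",
    "predict",
    "compare_kernels",
]

logger = logging.getLogger(__name__)

GPR_KERNELS = ("matern52", "sqexp", "exp", "rationalquadratic")


@dataclass(frozen=True)
class MinMaxScaler1:
    """Affine map of each column onto [-1, 1] using training min/max.

    A zero-span column maps identically to 0 (and back to its constant).
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "MinMaxScaler1":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return cls(mins=x.min(axis=0), maxs=x.max(axis=0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        span = self.maxs - self.mins
        safe = np.where(span == 0, 1.0, span)
        out = 2.0 * (x - self.mins) / safe - 1.0
        return np.where(span == 0, 0.0, out)

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        span = self.maxs - self.mins
        return np.where(span == 0, self.mins, (z + 1.0) * span / 2.0 + self.mins)

    @property
    def halfspan(self) -> np.ndarray:
        return (self.maxs - self.mins) / 2.0


@dataclass(frozen=True)
class DesignDataset:
    """Designs, design-point efficiencies and the normalisation maps."""

    x: np.ndarray  # (n, 5) raw parameters, canonical order
    y: np.ndarray  # (n,) efficiency at the target operating point
    design_ids: Tuple[str, ...]
    target_op: OperatingPoint
    x_scaler: MinMaxScaler1
    y_scaler: MinMaxScaler1
    excluded: Tuple[Tuple[str, str], ...] = ()  # (design_id, reason)

    def __len__(self) -> int:
        return len(self.y)

    def xn(self) -> np.ndarray:
        """Normalised features in [-1, 1]."""
        return self.x_scaler.transform(self.x)

    def yn(self) -> np.ndarray:
        """Normalised targets in [-1, 1]."""
        return self.y_scaler.transform(self.y.reshape(-1, 1)).ravel()

    def normalise_designs(self, x_raw: np.ndarray) -> np.ndarray:
        return self.x_scaler.transform(np.atleast_2d(x_raw))

    def denormalise_eta(self, yn: np.ndarray) -> np.ndarray:
        return self.y_scaler.inverse(np.asarray(yn).reshape(-1, 1)).ravel()


def build_dataset(
    designs: Sequence[BladeDesign],
    scaled_curves: Sequence[PerformanceCurve],
    target_op: OperatingPoint,
) -> DesignDataset:
    """Assemble the training set from designs and their scaled curves.

    The target for each design is the linearly interpolated efficiency of
    its scaled etaQ curve at the target flow. Designs whose scaled curve
    does not cover the target flow are excluded with a logged warning and
    recorded in ``excluded``.
    """
    if len(designs) != len(scaled_curves):
        raise ValueError("one scaled curve per design required")
    rows, targets, ids, excluded = [], [], [], []
    for d, c in zip(designs, scaled_curves):
        try:
            eta = efficiency_at(c, target_op.q_lpm)
        except ValueError as err:
            logger.warning("design %s excluded from dataset: %s", d.design_id, err)
            excluded.append((d.design_id, str(err)))
            continue
        rows.append(d.as_vector())
        targets.append(eta)
        ids.append(d.design_id)
    if not rows:
        raise ValueError("no design's scaled curve covers the target flow")
    x = np.array(rows)
    y = np.array(targets)
    return DesignDataset(
        x=x,
        y=y,
        design_ids=tuple(ids),
        target_op=target_op,
        x_scaler=MinMaxScaler1.fit(x),
        y_scaler=MinMaxScaler1.fit(y.reshape(-1, 1)),
        excluded=tuple(excluded),
    )


@dataclass(frozen=True)
class Prediction:
    eta: float
    extrapolating: bool


@dataclass
class SurrogateModel:
    """A fitted surrogate with its validation metrics.

    ``metrics`` holds RMSEs on the natural efficiency scale:
    ``rmse_train``, ``rmse_validation`` (CV mean or holdout, model
    dependent) and ``rmse_all`` (resubstitution on all data).
    """

    kind: str  # 'mlr' | 'gpr' | 'brann'
    dataset: DesignDataset
    metrics: Dict[str, float]
    seed: Optional[int] = None
    # model internals (exactly one populated set, by kind)
    mlr_coef: Optional[np.ndarray] = None  # (6,) intercept + 5 slopes, normalised space
    gpr: Optional[GaussianProcessRegressor] = None
    gpr_kernel_name: Optional[str] = None
    brann: Optional[BRANNTrainer] = None
    holdout_ids: Tuple[str, ...] = ()
    warning: Optional[str] = None

    def predict_eta(self, x_raw: np.ndarray) -> np.ndarray:
        """Efficiency predictions (natural scale) for raw parameter rows."""
        xn = self.dataset.normalise_designs(x_raw)
        if self.kind == "mlr":
            if self.mlr_coef is None:
                raise RuntimeError("model not fitted")
            yn = self.mlr_coef[0] + xn @ self.mlr_coef[1:]
        elif self.kind == "gpr":
            if self.gpr is None:
                raise RuntimeError("model not fitted")
            yn = self.gpr.predict(xn)
        elif self.kind == "brann":
            if self.brann is None:
                raise RuntimeError("model not fitted")
            yn = self.brann.predict(xn)
        else:
            raise ValueError(f"unknown surrogate kind {self.kind!r}")
        return self.dataset.denormalise_eta(np.asarray(yn))

    def is_extrapolating(self, x_raw: np.ndarray) -> np.ndarray:
        """True for rows outside the training bounding box."""
        xn = self.dataset.normalise_designs(x_raw)
        return np.any((xn < -1.0 - 1e-12) | (xn > 1.0 + 1e-12), axis=1)

    def to_json(self) -> str:
        """Serialise coefficients/weights, normalisation and metrics."""
        d: Dict = {
            "kind": self.kind,
            "metrics": self.metrics,
            "seed": self.seed,
            "target_op": {
                "q_lpm": self.dataset.target_op.q_lpm,
                "dp_mmhg": self.dataset.target_op.dp_mmhg,
                "label": self.dataset.target_op.label,
            },
            "normalisation": {
                "x_min": self.dataset.x_scaler.mins.tolist(),
                "x_max": self.dataset.x_scaler.maxs.tolist(),
                "y_min": self.dataset.y_scaler.mins.tolist(),
                "y_max": self.dataset.y_scaler.maxs.tolist(),
            },
            "training_data": {
                "design_ids": list(self.dataset.design_ids),
                "x": self.dataset.x.tolist(),
                "y": self.dataset.y.tolist(),
            },
            "holdout_ids": list(self.holdout_ids),
            "warning": self.warning,
        }
        if self.kind == "mlr":
            d["mlr_coef"] = self.mlr_coef.tolist()
        elif self.kind == "gpr":
            d["gpr_kernel_name"] = self.gpr_kernel_name
            d["gpr_kernel_params"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.gpr.kernel_.get_params().items()
                if isinstance(v, (int, float, np.ndarray))
            }
            d["gpr_alpha_jitter"] = float(self.gpr.alpha)
        elif self.kind == "brann":
            w = self.brann.weights
            d["brann"] = {
                "w1": w.w1.tolist(),
                "b1": w.b1.tolist(),
                "w2": w.w2.tolist(),
                "b2": w.b2,
                "alpha": self.brann.alpha,
                "beta": self.brann.beta,
                "gamma": self.brann.gamma,
                "n_hidden": self.brann.n_hidden,
            }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SurrogateModel":
        d = json.loads(text)
        op = OperatingPoint(**d["target_op"])
        norm = d["normalisation"]
        x = np.array(d["training_data"]["x"])
        y = np.array(d["training_data"]["y"])
        dataset = DesignDataset(
            x=x,
            y=y,
            design_ids=tuple(d["training_data"]["design_ids"]),
            target_op=op,
            x_scaler=MinMaxScaler1(np.array(norm["x_min"]), np.array(norm["x_max"])),
            y_scaler=MinMaxScaler1(np.array(norm["y_min"]), np.array(norm["y_max"])),
        )
        model = cls(
            kind=d["kind"],
            dataset=dataset,
            metrics=d["metrics"],
            seed=d["seed"],
            holdout_ids=tuple(d["holdout_ids"]),
            warning=d.get("warning"),
        )
        if d["kind"] == "mlr":
            model.mlr_coef = np.array(d["mlr_coef"])
        elif d["kind"] == "gpr":
            refit = fit_gpr(
                dataset,
                kernel=d["gpr_kernel_name"],
                seed=d["seed"] if d["seed"] is not None else 0,
            )
            model.gpr = refit.gpr
            model.gpr_kernel_name = refit.gpr_kernel_name
        elif d["kind"] == "brann":
            b = d["brann"]
            trainer = BRANNTrainer(n_hidden=b["n_hidden"])
            trainer.weights = BRANNWeights(
                w1=np.array(b["w1"]),
                b1=np.array(b["b1"]),
                w2=np.array(b["w2"]),
                b2=b["b2"],
            )
            trainer.alpha, trainer.beta, trainer.gamma = b["alpha"], b["beta"], b["gamma"]
            model.brann = trainer
        return model


def predict(model: SurrogateModel, design: BladeDesign) -> Prediction:
    """Predict design-point efficiency for one design, with extrapolation flag."""
    x = design.as_vector().reshape(1, -1)
    return Prediction(
        eta=float(model.predict_eta(x)[0]),
        extrapolating=bool(model.is_extrapolating(x)[0]),
    )


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def fit_mlr(data: DesignDataset) -> SurrogateModel:
    """Ordinary least squares with intercept on the five normalised features."""
    n = len(data)
    if n <= 6:
        raise ValueError("multi-linear regression needs more samples than parameters")
    xn, yn = data.xn(), data.yn()
    a = np.column_stack([np.ones(n), xn])
    coef, _, rank, _ = np.linalg.lstsq(a, yn, rcond=None)
    if rank < a.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear features)")
    model = SurrogateModel(kind="mlr", dataset=data, metrics={}, mlr_coef=coef)
    rmse_all = _rmse(model.predict_eta(data.x), data.y)
    model.metrics = {"rmse_train": rmse_all, "rmse_validation": rmse_all, "rmse_all": rmse_all}
    return model


def _make_kernel(name: str, n_features: int):
    ls = np.ones(n_features)
    if name == "matern52":
        base = Matern(length_scale=ls, nu=2.5)
    elif name == "sqexp":
        base = RBF(length_scale=ls)
    elif name == "exp":
        base = Matern(length_scale=ls, nu=0.5)
    elif name == "rationalquadratic":
        base = RationalQuadratic(length_scale=1.0, alpha=1.0)
    else:
        raise ValueError(f"unknown kernel {name!r}; choose from {GPR_KERNELS}")
    return ConstantKernel(1.0) * base


def _fit_gpr_once(xn, yn, kernel_name, seed, jitter=1e-10):
    """Fit one GPR, escalating jitter x10 up to 1e-6 on Cholesky failure."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    while True:
        gpr = GaussianProcessRegressor(
            kernel=_make_kernel(kernel_name, xn.shape[1]),
            alpha=jitter,
            normalize_y=True,
            n_restarts_optimizer=2,
            random_state=seed,
        )
        try:
            with warnings.catch_warnings():
                # near-noiseless data leaves the marginal likelihood flat at
                # its optimum; lbfgs line-search failures there are benign
                warnings.simplefilter("ignore", ConvergenceWarning)
                gpr.fit(xn, yn)
            return gpr
        except np.linalg.LinAlgError:
            jitter *= 10.0
            if jitter > 1e-6:
                raise


def fit_gpr(
    data: DesignDataset,
    kernel: str = "matern52",
    n_folds: int = 5,
    seed: int = 0,
) -> SurrogateModel:
    """Gaussian-process regression with k-fold cross-validated reporting.

    Hyperparameters are fitted per fold by maximising the marginal
    likelihood; the mean held-out RMSE is the validation metric. The
    returned model is refitted on all data.
    """
    n = len(data)
    if n < n_folds:
        raise ValueError("need at least as many samples as folds")
    xn, yn = data.xn(), data.yn()
    fold_rmse = []
    if n_folds >= 2:
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for tr, te in kf.split(xn):
            g = _fit_gpr_once(xn[tr], yn[tr], kernel, seed)
            pred = data.denormalise_eta(g.predict(xn[te]))
            fold_rmse.append(_rmse(pred, data.y[te]))
    final = _fit_gpr_once(xn, yn, kernel, seed)
    model = SurrogateModel(
        kind="gpr", dataset=data, metrics={}, seed=seed, gpr=final, gpr_kernel_name=kernel
    )
    rmse_all = _rmse(model.predict_eta(data.x), data.y)
    model.metrics = {
        "rmse_train": rmse_all,
        "rmse_validation": float(np.mean(fold_rmse)) if fold_rmse else rmse_all,
        "rmse_all": rmse_all,
        "fold_rmse": [float(v) for v in fold_rmse],
    }
    return model


def compare_kernels(
    data: DesignDataset,
    kernels: Sequence[str] = GPR_KERNELS,
    n_folds: int = 5,
    seed: int = 0,
) -> List[Dict]:
    """Cross-validated comparison of GPR kernels, best (lowest CV RMSE) first."""
    report = []
    for k in kernels:
        m = fit_gpr(data, kernel=k, n_folds=n_folds, seed=seed)
        report.append(
            {
                "kernel": k,
                "rmse_validation": m.metrics["rmse_validation"],
                "rmse_all": m.metrics["rmse_all"],
            }
        )
    return sorted(report, key=lambda r: r["rmse_validation"])


def fit_brann(
    data: DesignDataset,
    n_hidden: int = 5,
    holdout_fraction: float = 0.15,
    seed: int = 0,
) -> SurrogateModel:
    """Bayesian-regularised network with a random holdout validation set.

    The holdout rows (5 of 32 at the default fraction) are chosen without
    replacement under the supplied seed and never seen during training;
    Bayesian regularisation makes a separate early-stopping set unnecessary.
    """
    n = len(data)
    n_hold = int(round(holdout_fraction * n))
    if n_hold < 1 or n - n_hold < 2:
        raise ValueError("holdout must leave at least one test row and two training rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    hold, train = perm[:n_hold], perm[n_hold:]
    xn, yn = data.xn(), data.yn()
    trainer = BRANNTrainer(n_hidden=n_hidden).fit(xn[train], yn[train], seed=seed)
    model = SurrogateModel(
        kind="brann",
        dataset=data,
        metrics={},
        seed=seed,
        brann=trainer,
        holdout_ids=tuple(data.design_ids[i] for i in hold),
        warning=None if trainer.converged else "LM training stopped before convergence",
    )
    pred_all = model.predict_eta(data.x)
    model.metrics = {
        "rmse_train": _rmse(pred_all[train], data.y[train]),
        "rmse_validation": _rmse(pred_all[hold], data.y[hold]),
        "rmse_all": _rmse(pred_all, data.y),
        "gamma": trainer.gamma,
        "n_weights": trainer.weights.n_weights,
    }
    return model
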