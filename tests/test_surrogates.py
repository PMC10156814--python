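import numpy as np
import pytest

from bladeopt.curves import OperatingPoint, PerformanceCurve
from bladeopt.geometry import BladeDesign, constraint_box, factorial_designs
from bladeopt.surrogates import (
    DesignDataset,
    MinMaxScaler1,
    SurrogateModel,
    build_dataset,
    compare_kernels,
    fit_brann,
    fit_gpr,
    fit_mlr,
    predict,
)


def linear_dataset(n=30, seed=0, coefs=(0.02, -0.015, 0.01, 0.005, -0.008), intercept=0.28):
    """Targets exactly linear in the five raw parameters."""
    rng = np.random.default_rng(seed)
    box = constraint_box(0)
    lo, hi = box.lower(), box.upper()
    x = lo + rng.random((n, 5)) * (hi - lo)
    x[:, 1] = np.maximum(x[:, 1], x[:, 0] + 1.0)
    y = intercept + x @ np.array(coefs) / 100.0
    return DesignDataset(
        x=x,
        y=y,
        design_ids=tuple(f"s{i}" for i in range(n)),
        target_op=OperatingPoint(2.0, 70.0),
        x_scaler=MinMaxScaler1.fit(x),
        y_scaler=MinMaxScaler1.fit(y.reshape(-1, 1)),
    )


class TestDataset:
    def test_build_dataset_shapes_and_normalisation(self, baseline):
        data = baseline.dataset
        assert len(data) == 32
        assert data.x.shape == (32, 5)
        xn = data.xn()
        assert np.all(xn >= -1.0 - 1e-12) and np.all(xn <= 1.0 + 1e-12)
        yn = data.yn()
        assert yn.min() == pytest.approx(-1.0) and yn.max() == pytest.approx(1.0)

    def test_normalisation_round_trip(self, baseline):
        data = baseline.dataset
        back = data.x_scaler.inverse(data.xn())
        assert np.allclose(back, data.x, atol=1e-12)
        assert np.allclose(data.denormalise_eta(data.yn()), data.y, atol=1e-12)

    def test_zero_span_targets_normalise_to_zero(self):
        y = np.full((4, 1), 0.3)
        sc = MinMaxScaler1.fit(y)
        assert np.all(sc.transform(y) == 0.0)
        assert np.allclose(sc.inverse(sc.transform(y)), y)

    def test_design_not_covering_target_flow_is_excluded(self, target_op):
        designs = [
            BladeDesign(25, 90, 25, 9, 9, design_id="ok"),
            BladeDesign(30, 90, 30, 10, 10, design_id="short"),
        ]
        q_ok = np.arange(0.5, 4.01, 0.5)
        q_short = np.arange(2.5, 4.51, 0.5)  # does not cover Q = 2
        curves = [
            PerformanceCurve("ok", 15000, q_ok, 100 - 10 * q_ok, np.linspace(0.1, 0.3, q_ok.size)),
            PerformanceCurve("short", 15000, q_short, 100 - 10 * q_short,
                             np.linspace(0.1, 0.3, q_short.size)),
        ]
        data = build_dataset(designs, curves, target_op)
        assert data.design_ids == ("ok",)
        assert data.excluded[0][0] == "short"


class TestMLR:
    def test_exact_linear_recovery_against_normal_equations(self):
        data = linear_dataset()
        model = fit_mlr(data)
        assert model.metrics["rmse_all"] < 1e-10
        # oracle: normal equations in the normalised space
        a = np.column_stack([np.ones(len(data)), data.xn()])
        oracle = np.linalg.solve(a.T @ a, a.T @ data.yn())
        assert np.allclose(model.mlr_coef, oracle, atol=1e-8)
        assert model.mlr_coef.shape == (6,)

    def test_prediction_equals_hand_recomputation(self, baseline):
        model = fit_mlr(baseline.dataset)
        d = BladeDesign(30.0, 85.0, 30.0, 10.0, 12.0)
        xn = baseline.dataset.normalise_designs(d.as_vector().reshape(1, -1))
        by_hand = model.mlr_coef[0] + xn[0] @ model.mlr_coef[1:]
        eta_hand = baseline.dataset.denormalise_eta(np.array([by_hand]))[0]
        assert predict(model, d).eta == pytest.approx(eta_hand, rel=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_mlr(linear_dataset(n=6))


class TestGPR:
    def test_interpolates_training_points(self, baseline):
        model = fit_gpr(baseline.dataset, seed=0)
        pred = model.predict_eta(baseline.dataset.x)
        assert np.allclose(pred, baseline.dataset.y, atol=1e-6)

    def test_cross_validation_protocol(self, baseline):
        model = fit_gpr(baseline.dataset, n_folds=5, seed=0)
        assert len(model.metrics["fold_rmse"]) == 5
        assert model.metrics["rmse_validation"] == pytest.approx(
            np.mean(model.metrics["fold_rmse"])
        )
        # resubstitution error of the interpolating fit is far below CV error
        assert model.metrics["rmse_all"] < model.metrics["rmse_validation"]

    def test_beats_nearest_neighbour_baseline_inside_the_box(self):
        # smooth 5-D function sampled at the 32 factorial corners
        f = lambda x: 0.25 + 0.001 * x[:, 0] - 0.0005 * x[:, 1] + 0.0008 * x[:, 2] \
            - 0.0004 * x[:, 3] + 0.0002 * x[:, 4] + 1e-5 * x[:, 0] * x[:, 2]
        x = np.array([d.as_vector() for d in factorial_designs()])
        y = f(x)
        data = DesignDataset(
            x=x, y=y, design_ids=tuple(f"c{i}" for i in range(32)),
            target_op=OperatingPoint(2.0, 70.0),
            x_scaler=MinMaxScaler1.fit(x), y_scaler=MinMaxScaler1.fit(y.reshape(-1, 1)),
        )
        model = fit_gpr(data, seed=0)
        rng = np.random.default_rng(1)
        box = constraint_box(0)
        lo, hi = box.lower(), box.upper()
        queries = lo + rng.random((20, 5)) * (hi - lo)
        truth = f(queries)
        gpr_err = np.abs(model.predict_eta(queries) - truth).mean()
        # brute-force nearest-neighbour on the same normalised samples
        xn, qn = data.xn(), data.normalise_designs(queries)
        nn = np.array([y[np.argmin(np.sum((xn - q) ** 2, axis=1))] for q in qn])
        nn_err = np.abs(nn - truth).mean()
        assert gpr_err < nn_err

    def test_kernel_comparison_returns_full_ranking(self, baseline):
        report = compare_kernels(baseline.dataset, seed=0)
        assert {r["kernel"] for r in report} == {"matern52", "sqexp", "exp", "rationalquadratic"}
        vals = [r["rmse_validation"] for r in report]
        assert vals == sorted(vals)


class TestBRANN:
    def test_holdout_is_5_of_32(self, baseline):
        model = fit_brann(baseline.dataset, holdout_fraction=0.15, seed=0)
        assert len(model.holdout_ids) == 5

    def test_linear_targets_fit_with_small_effective_parameter_count(self):
        data = linear_dataset()
        model = fit_brann(data, seed=1)
        assert model.metrics["rmse_train"] < 1e-5
        # evidence framework bounds gamma by the number of training samples,
        # itself below the raw weight count
        n_train = len(data) - len(model.holdout_ids)
        assert model.metrics["gamma"] <= n_train + 1e-6
        assert model.metrics["gamma"] < model.metrics["n_weights"]

    def test_seeded_reruns_are_bit_identical(self, baseline):
        a = fit_brann(baseline.dataset, seed=3)
        b = fit_brann(baseline.dataset, seed=3)
        assert np.array_equal(a.brann.weights.to_vector(), b.brann.weights.to_vector())
        assert a.metrics == b.metrics

    def test_stronger_weight_decay_shrinks_weights(self):
        from bladeopt.brann import BRANNTrainer

        data = linear_dataset()
        norms = []
        for alpha in (0.01, 0.1, 1.0, 10.0):
            tr = BRANNTrainer(update_evidence=False, alpha0=alpha, beta0=100.0).fit(
                data.xn(), data.yn(), seed=3
            )
            norms.append(np.linalg.norm(tr.weights.to_vector()))
        assert all(np.diff(norms) < 0)


class TestPredictInterface:
    def test_extrapolation_flag(self, baseline):
        model = fit_mlr(baseline.dataset)
        inside = BladeDesign(30.0, 85.0, 30.0, 10.0, 10.0)
        outside = BladeDesign(10.0, 90.0, 10.0, 6.0, 6.0)
        assert not predict(model, inside).extrapolating
        assert predict(model, outside).extrapolating

    def test_unfitted_model_rejected(self, baseline):
        broken = SurrogateModel(kind="mlr", dataset=baseline.dataset, metrics={})
        with pytest.raises(RuntimeError):
            broken.predict_eta(baseline.dataset.x[:1])

    @pytest.mark.parametrize("kind", ["mlr", "gpr", "brann"])
    def test_json_round_trip_preserves_predictions(self, baseline, kind):
        from bladeopt.pipeline import train_surrogate

        model = train_surrogate(baseline.dataset, kind, seed=0)
        restored = SurrogateModel.from_json(model.to_json())
        x = baseline.dataset.x[:5]
        assert np.allclose(restored.predict_eta(x), model.predict_eta(x), atol=1e-9)


class TestAllModelsHaveSignal:
    @pytest.mark.parametrize("kind", ["mlr", "gpr", "brann"])
    def test_beats_mean_predictor_on_virtual_data(self, baseline, kind):
        from bladeopt.pipeline import train_surrogate

        model = train_surrogate(baseline.dataset, kind, seed=0)
        assert model.metrics["rmse_all"] < baseline.dataset.y.std()
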