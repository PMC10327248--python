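"""Feature engineering, the feed-forward network and its training loop."""

import numpy as np
import pytest

from afmfit.dnn_rmsd import (
    MLPConfig,
    RmsdEstimator,
    RnaMeta,
    apply_scaler,
    build_mlp,
    count_parameters,
    featurize,
    fit_scaler,
    huber,
    load_model,
    mse,
    predict_rmsd,
    save_model,
    train,
)
from afmfit.energy_model import ThetaConfig
from afmfit.synthetic_fixtures import PlantedTrajectorySpec, planted_trajectory

from .conftest import make_records

META = RnaMeta(n_nucleotides=20, n_stacks=19, n_pairs=8)


class TestFeaturize:
    def test_engineered_feature_limits(self):
        recs = make_records({"e_total": [40.0, 40.0], "cc_afm": [1.0, 0.0]})
        X = featurize(recs, META)
        # cc = 1 -> engineered equals normalized e_total; cc = 0 -> 0
        assert X[0, 9] == pytest.approx(X[0, 0])
        assert X[1, 9] == 0.0

    def test_normalizations(self):
        theta = ThetaConfig()
        recs = make_records({"e_total": [40.0], "e_stacking": [90.0],
                             "e_pairing": [45.0], "e_local": [100.0],
                             "v_afm": [50.0], "cc_afm": [0.5]})
        X = featurize(recs, META, theta)
        assert X[0, 0] == pytest.approx(40.0 / 20)
        assert X[0, 1] == pytest.approx(100.0 / 20 / 5)          # theta_c
        assert X[0, 4] == pytest.approx(90.0 / 19 / 9)           # stacks, theta
        assert X[0, 5] == pytest.approx(45.0 / 8 / 9)            # pairs, theta
        assert X[0, 7] == pytest.approx(50.0 / 20 / theta.theta_afm)

    def test_default_power_is_seven(self):
        import inspect
        assert inspect.signature(featurize).parameters["N"].default == 7

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            RnaMeta(n_nucleotides=0, n_stacks=1, n_pairs=1)


class TestScaler:
    def test_self_transform_standardized(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, (200, 10))
        sc = fit_scaler(X)
        Z = apply_scaler(X, sc)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_named(self):
        X = np.random.default_rng(1).normal(size=(50, 10))
        X[:, 3] = 2.0
        with pytest.raises(ValueError, match="e_repulsive"):
            fit_scaler(X)

    def test_foreign_scaler_not_refit(self):
        rng = np.random.default_rng(2)
        A = rng.normal(0, 1, (100, 10))
        B = rng.normal(5, 1, (100, 10))         # shifted set
        sc = fit_scaler(A)
        ZB = apply_scaler(B, sc)
        assert abs(ZB.mean()) > 1.0             # B keeps its shift under A's scaler

    def test_round_trip_bitwise(self, tmp_path):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(64, 10))
        model = build_mlp(MLPConfig(max_epochs=1), seed=0)
        model.scaler = fit_scaler(X)
        p = tmp_path / "m.npz"
        save_model(model, p)
        back = load_model(p)
        np.testing.assert_array_equal(back.scaler.mean, model.scaler.mean)
        np.testing.assert_array_equal(back.scaler.sigma, model.scaler.sigma)
        np.testing.assert_array_equal(
            apply_scaler(X, back.scaler), apply_scaler(X, model.scaler))


class TestArchitecture:
    def test_default_parameter_count(self):
        # 10->128->64->16->1: 1408 + 8256 + 1040 + 17 = 10721 (~11k)
        assert count_parameters((128, 64, 16)) == 10_721

    def test_count_matches_hand_count_arbitrary(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            hidden = tuple(int(h) for h in rng.integers(1, 40, rng.integers(1, 5)))
            model = build_mlp(MLPConfig(hidden_sizes=hidden), input_dim=10)
            direct = sum(w.size + b.size
                         for w, b in zip(model.weights, model.biases))
            assert direct == count_parameters(hidden)

    def test_tiny_network_count(self):
        assert count_parameters((1,)) == 13

    def test_empty_hidden_rejected(self):
        with pytest.raises(ValueError):
            MLPConfig(hidden_sizes=())


class TestLosses:
    def test_zero_at_equality(self):
        y = np.array([1.0, 2.0, 3.0])
        assert huber(y, y) == 0.0
        assert mse(y, y) == 0.0

    def test_huber_boundary_continuity(self):
        assert huber(np.array([1.0]), np.array([0.0]), delta=1.0) == \
            pytest.approx(0.5)

    def test_huber_linear_branch(self):
        # single error 3 with delta 1: 1 * (3 - 0.5) = 2.5
        assert huber(np.array([3.0]), np.array([0.0]), delta=1.0) == \
            pytest.approx(2.5)

    def test_huber_quadratic_regime_matches_half_mse(self):
        rng = np.random.default_rng(5)
        pred = rng.normal(0, 0.01, 1000)
        true = np.zeros(1000)
        assert huber(pred, true, delta=1.0) == pytest.approx(
            mse(pred, true) / 2, rel=0.01)

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            huber(np.array([1.0]), np.array([0.0]), delta=0.0)


class TestTraining:
    def test_learns_linear_toy(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (600, 10))
        y = 2.0 + 3.0 * X[:, 0]
        # a larger step size than the full-scale default: only ~4 mini
        # batches per epoch here, so Adam takes far fewer updates per epoch
        cfg = MLPConfig(hidden_sizes=(16, 8), dropout=0.0, max_epochs=200,
                        patience=50, val_rmsd_cap=1e9, learning_rate=0.01)
        model = build_mlp(cfg, seed=1)
        train(model, (X[:480], y[:480]), (X[480:], y[480:]), seed=2)
        assert min(model.history["val_loss"]) < 0.01

    def test_patience_zero_stops_after_first_stall(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(128, 10))
        y = rng.normal(size=128)
        cfg = MLPConfig(max_epochs=100, patience=0, val_rmsd_cap=1e9)
        model = build_mlp(cfg, seed=3)
        train(model, (X, y), (X, y), seed=4)
        n_epochs = len(model.history["val_loss"])
        assert n_epochs <= 100
        # ended exactly one epoch after the best one, or at the cap
        assert n_epochs == model.best_epoch + 2 or n_epochs == 100

    def test_validation_mask_requires_small_rmsd_examples(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(64, 10))
        y = np.full(64, 25.0)            # all above the 10-A cap
        model = build_mlp(MLPConfig(), seed=5)
        with pytest.raises(ValueError, match="10"):
            train(model, (X, y), (X, y), seed=6)

    def test_estimator_default_split_is_80_20(self):
        assert RmsdEstimator().val_fraction == 0.2

    def test_inference_deterministic(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(256, 10))
        y = np.abs(X[:, 0] * 3 + 5)
        est = RmsdEstimator(max_epochs=20, random_state=0).fit(X, y)
        p1 = est.predict(X[:32])
        p2 = est.predict(X[:32])
        np.testing.assert_array_equal(p1, p2)

    def test_planted_holdout_pearson(self):
        # parameter-recovery: energies/CC encode RMSD; the network must
        # rank held-out frames correctly
        recs, labels = planted_trajectory(
            PlantedTrajectorySpec(n_frames=6000, seed=10))
        X = featurize(recs, META)
        n_train = 5000
        est = RmsdEstimator(max_epochs=150, patience=20, random_state=1)
        est.fit(X[:n_train], labels[:n_train])
        pred = est.predict(X[n_train:])
        r = np.corrcoef(pred, labels[n_train:])[0, 1]
        assert r >= 0.9

    def test_predict_rmsd_uses_stored_scaler(self, tmp_path):
        recs, labels = planted_trajectory(
            PlantedTrajectorySpec(n_frames=800, seed=11))
        X = featurize(recs, META)
        est = RmsdEstimator(max_epochs=10, random_state=2).fit(X, labels)
        p = tmp_path / "model.npz"
        save_model(est.model_, p)
        back = load_model(p)
        direct = predict_rmsd(back, recs[:50], META)
        np.testing.assert_allclose(direct, est.predict(X[:50]), atol=1e-10)


class TestSpearmanRanking:
    def test_heldout_rank_correlation(self):
        from scipy.stats import spearmanr

        recs, labels = planted_trajectory(
            PlantedTrajectorySpec(n_frames=4100, seed=12))
        X = featurize(recs, META)
        est = RmsdEstimator(max_epochs=120, patience=15, random_state=3)
        est.fit(X[:4000], labels[:4000])
        pred = est.predict(X[4000:])
        rho = spearmanr(pred, labels[4000:]).statistic
        assert rho >= 0.8
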