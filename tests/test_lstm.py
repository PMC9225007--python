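"""Recurrent model: cell-equation oracles, backprop exactness, scaling,
teacher forcing semantics and training capacity."""

import numpy as np
import pytest

import micos
from micos.nn import init_lstm, lstm_backward, lstm_cell_step, lstm_forward
from micos.scaling import FeatureScaler
from micos.model import (TrainingConfig, attach_metabolite_head, build_joint_model,
                         fit_scaler, train_endpoint_model, train_joint_model,
                         train_teacher_forcing)


def zero_weights(D, H):
    return {k: np.zeros_like(v) for k, v in init_lstm(D, H, seed=0).items()}


class TestCellStep:
    def test_all_zero_weights_and_state(self):
        W = zero_weights(3, 4)
        h, c, o = lstm_cell_step(np.zeros(3), np.zeros(4), np.zeros(4), W)
        assert np.allclose(o, 0.5)       # sigmoid(0)
        assert np.allclose(c, 0.0)       # f*0 + i*tanh(0)
        assert np.allclose(h, 0.0)

    def test_zero_weights_nonzero_cell_state(self):
        W = zero_weights(3, 4)
        h, c, o = lstm_cell_step(np.zeros(3), np.zeros(4), np.full(4, 2.0), W)
        assert np.allclose(c, 1.0)                       # 0.5 * 2
        assert np.allclose(h, 0.5 * np.tanh(1.0))        # ~0.380797
        assert h[0] == pytest.approx(0.380797, abs=1e-6)

    def test_scalar_hand_oracle_to_1e12(self):
        # 1-D unit: all weight matrices 1, biases 0, x=1, h=c=0
        W = zero_weights(1, 1)
        for gate in "ifgo":
            W[f"W_i{gate}"][:] = 1.0
            W[f"W_h{gate}"][:] = 1.0
        h, c, o = lstm_cell_step(np.array([1.0]), np.zeros(1), np.zeros(1), W)
        sig = 1 / (1 + np.exp(-1.0))
        c_hand = sig * np.tanh(1.0)
        h_hand = sig * np.tanh(c_hand)
        assert abs(c[0] - c_hand) < 1e-12
        assert abs(h[0] - h_hand) < 1e-12
        assert abs(o[0] - sig) < 1e-12

    def test_shape_mismatch_rejected(self):
        W = init_lstm(3, 4, seed=0)
        with pytest.raises(ValueError, match="input dim"):
            lstm_cell_step(np.zeros(5), np.zeros(4), np.zeros(4), W)


class TestBackprop:
    def test_weight_and_input_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        D, H, B, T = 3, 5, 4, 4
        W = init_lstm(D, H, seed=1)
        X = rng.standard_normal((B, T, D))
        Y = rng.standard_normal((B, T, D))
        mask = rng.random((B, T)) < 0.5
        mask[:, 0] = False

        def loss(Wv, Xv):
            ys, _ = lstm_forward(Wv, Xv, mask)
            return np.mean((ys - Y) ** 2)

        ys, cache = lstm_forward(W, X, mask)
        grads, dX = lstm_backward(W, cache, 2 * (ys - Y) / ys.size)
        h = 1e-6
        for name in ("W_ii", "W_hf", "b_ig", "W_yo", "b_yo", "W_ho"):
            idx = tuple(rng.integers(0, s) for s in W[name].shape)
            orig = W[name][idx]
            W[name][idx] = orig + h
            lp = loss(W, X)
            W[name][idx] = orig - h
            lm = loss(W, X)
            W[name][idx] = orig
            fd = (lp - lm) / (2 * h)
            assert grads[name][idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)
        # input gradient at time 0 (the sensitivity path)
        for d in range(D):
            X2 = X.copy()
            X2[0, 0, d] += h
            lp = loss(W, X2)
            X2[0, 0, d] -= 2 * h
            lm = loss(W, X2)
            fd = (lp - lm) / (2 * h)
            assert dX[0, 0, d] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_full_teacher_forcing_equals_one_step_ahead_chain(self):
        # with the true state fed at every step, the rollout must reproduce
        # an explicitly coded chain of one-step-ahead cell evaluations whose
        # inputs are always the observations (no prediction feedback)
        rng = np.random.default_rng(1)
        D, H, B, T = 2, 3, 3, 3
        W = init_lstm(D, H, seed=2)
        X = rng.standard_normal((B, T, D))
        mask_full = np.ones((B, T), dtype=bool)
        mask_full[:, 0] = False
        ys, _ = lstm_forward(W, X, mask_full)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        for t in range(T):
            h, c, o = lstm_cell_step(X[:, t], h, c, W)
            y_ref = o @ W["W_yo"].T + W["b_yo"]
            assert np.allclose(ys[:, t], y_ref, atol=1e-12)

    def test_free_running_ignores_intermediate_observations(self):
        # teacher_forcing_prob = 0: only the initial state matters
        rng = np.random.default_rng(2)
        D, H, B, T = 2, 3, 3, 4
        W = init_lstm(D, H, seed=3)
        X = rng.standard_normal((B, T, D))
        ys1, _ = lstm_forward(W, X, teacher_mask=None)
        X2 = X.copy()
        X2[:, 1:] = rng.standard_normal((B, T - 1, D))
        ys2, _ = lstm_forward(W, X2, teacher_mask=None)
        assert np.allclose(ys1, ys2, atol=1e-12)


class TestScaler:
    def test_population_convention_hand_values(self):
        data = np.array([[[1.0]], [[2.0]], [[3.0]]])  # 3 samples, 1 time, 1 feat
        sc = FeatureScaler().fit(data)
        assert sc.mu[0, 0] == pytest.approx(2.0)
        assert sc.sigma[0, 0] == pytest.approx(np.sqrt(2.0 / 3.0))
        z = sc.transform(data)[:, 0, 0]
        assert np.allclose(z, [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((7, 4, 6))
        sc = FeatureScaler().fit(data)
        assert np.allclose(sc.inverse_transform(sc.transform(data)), data,
                           atol=1e-12)

    def test_constant_feature_floored_and_maps_to_zero(self):
        data = np.full((5, 2, 1), 3.3)
        sc = FeatureScaler().fit(data)
        assert np.all(sc.sigma == sc.eps)
        assert np.allclose(sc.transform(data), 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            FeatureScaler().fit(np.zeros((0, 3, 2)))

    def test_training_only_statistics_by_default(self, tables5):
        sc_train = fit_scaler(tables5[:20])
        sc_all = fit_scaler(tables5[:20], extra_tables=tables5[20:],
                            normalize_all=True)
        assert not np.allclose(sc_train.mu, sc_all.mu)


class TestTrainingAndRollout:
    def test_rollout_zero_steps_returns_input(self, trained_model5):
        x0 = np.array([0.01, 0.0, 0.02, 0.0, 0.01])
        out = trained_model5.rollout(x0, n_steps=0)
        assert np.array_equal(out[0], x0)

    def test_rollout_requires_scaler(self):
        model = build_joint_model(n_species=3, n_metabolites=4,
                                  config=TrainingConfig(hidden_dim=8))
        with pytest.raises(RuntimeError):
            model.rollout(np.zeros(7), n_steps=1)

    def test_loss_history_bitwise_deterministic(self, tables5):
        cfg = TrainingConfig(hidden_dim=16, epochs=10, batch_size=10, seed=3)
        m1 = train_teacher_forcing(tables5[:15], cfg)
        m2 = train_teacher_forcing(tables5[:15], cfg)
        assert m1.loss_history == m2.loss_history
        for k in m1.weights:
            assert np.array_equal(m1.weights[k], m2.weights[k])

    def test_holdout_accuracy_on_pairwise_glv_data(self, tables5, trained_model5):
        test = tables5[24:]
        true = np.stack([tb.X[-1] for tb in test])
        pred = np.stack([trained_model5.rollout(tb.X[0])[-1] for tb in test])
        assert micos.pearson_r2(pred.ravel(), true.ravel()) >= 0.8

    def test_inconsistent_grids_rejected(self, tables5, truth5):
        odd = micos.simulate_glv(truth5, tables5[0].design,
                                 times=np.arange(0, 25, 8.0), sample_id="odd")
        with pytest.raises(ValueError, match="time grid"):
            train_teacher_forcing(tables5[:3] + [odd],
                                  TrainingConfig(hidden_dim=8, epochs=1))

    def test_teacher_forcing_probability_validated(self):
        with pytest.raises(ValueError):
            TrainingConfig(teacher_forcing_prob=1.5)


class TestMetaboliteHead:
    def test_head_input_dimension_checked(self, trained_model5):
        with pytest.raises(ValueError, match="head input dim"):
            attach_metabolite_head(trained_model5, [7, 4])

    def test_endpoint_linkage_recovery(self, linked_tables5):
        cfg = TrainingConfig(hidden_dim=64, epochs=300, batch_size=10, seed=0)
        m = train_endpoint_model(linked_tables5[:24], cfg)
        test = linked_tables5[24:]
        pred = np.stack([m.predict_endpoint(tb.X[0])[1] for tb in test])
        true = np.stack([tb.C[-1] for tb in test])
        assert micos.pearson_r2(pred.ravel(), true.ravel()) >= 0.9

    def test_metabolite_loss_gradient_reaches_lstm_weights(self, linked_tables5):
        # two short trainings differing only in metabolite targets must move
        # the recurrent weights differently: the end-to-end path is live
        cfg = TrainingConfig(hidden_dim=16, epochs=3, batch_size=10, seed=1)
        m1 = train_endpoint_model(linked_tables5[:20], cfg)
        shuffled = []
        rng = np.random.default_rng(0)
        perm = rng.permutation(20)
        for tb, j in zip(linked_tables5[:20], perm):
            shuffled.append(micos.TrajectoryTable(
                sample_id=tb.sample_id, design=tb.design, times=tb.times,
                X=tb.X, C=linked_tables5[int(j)].C))
        m2 = train_endpoint_model(shuffled, cfg)
        diff = max(np.abs(m1.weights[k] - m2.weights[k]).max()
                   for k in m1.weights)
        assert diff > 1e-6

    def test_missing_metabolites_rejected(self, tables5):
        with pytest.raises(ValueError, match="metabolite"):
            train_endpoint_model(tables5[:5],
                                 TrainingConfig(hidden_dim=8, epochs=1))


class TestJointModel:
    def test_joint_state_dimension_is_species_plus_metabolites(self):
        model = build_joint_model(n_species=25, n_metabolites=4,
                                  config=TrainingConfig(hidden_dim=8))
        assert model.n_features == 29
        assert model.weights["W_ii"].shape[1] == 29
        assert model.weights["W_yo"].shape[0] == 29

    def test_joint_model_requires_metabolite_columns(self, tables5):
        with pytest.raises(ValueError, match="metabolite"):
            train_joint_model(tables5[:5], TrainingConfig(hidden_dim=8, epochs=1))

    def test_joint_recovery_of_metabolite_trajectories(self, truth5):
        from micos.glv import design_test_communities, metabolites_from_abundances
        rng = np.random.default_rng(3)
        W = np.abs(rng.normal(1.5, 1.0, (4, 5)))
        designs = design_test_communities(5, n=31, min_richness=1, seed=1)
        times = np.arange(0.0, 49.0, 16.0)
        tables = [metabolites_from_abundances(
            micos.simulate_glv(truth5, d, times=times, sample_id=f"j{i}"),
            W, mode="cumulative") for i, d in enumerate(designs)]
        cfg = TrainingConfig(hidden_dim=64, epochs=200, batch_size=5, seed=0)
        m = train_joint_model(tables[:24], cfg)
        test = tables[24:]
        for t in range(1, len(times)):
            pred = np.stack([m.rollout(np.concatenate([tb.X[0], tb.C[0]]))[t]
                             for tb in test])
            true = np.stack([tb.C[t] for tb in test])
            assert micos.pearson_r2(pred[:, 5:].ravel(), true.ravel()) >= 0.8


def test_model_save_load_round_trip(tmp_path, trained_model5):
    trained_model5.save(tmp_path / "model")
    loaded = micos.LSTMModel.load(tmp_path / "model")
    x0 = np.array([0.01, 0.02, 0.0, 0.01, 0.0])
    assert np.allclose(loaded.rollout(x0), trained_model5.rollout(x0), atol=1e-12)
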