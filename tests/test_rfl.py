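"""The transfer-feature core: LSTM cell, RF probabilities, concatenation,
out-of-fold extraction and the leakage demonstration."""

import numpy as np
import pytest

from rflkit.classifiers import ClassifierSpec, predict, train_classifier
from rflkit.dataio import FeatureTable
from rflkit.evaluation import kfold_cv
from rflkit.rfl import (
    LSTMFeatureExtractor,
    LSTMParams,
    RFLConfig,
    RFLTransformer,
    RFProbabilityExtractor,
    _build_windows,
    lstm_cell_step,
    rfl_transform,
    transfer_feature_names,
)
from rflkit.simdata import generate_dataset, reference_sim_spec


def _zero_params(hidden, inputs, n_classes=2):
    hd = hidden + inputs
    z = np.zeros
    return LSTMParams(
        W_f=z((hidden, hd)), W_i=z((hidden, hd)), W_C=z((hidden, hd)),
        W_o=z((hidden, hd)), b_f=z(hidden), b_i=z(hidden), b_C=z(hidden),
        b_o=z(hidden), W_y=z((n_classes, hidden)), b_y=z(n_classes),
    )


class TestLSTMCell:
    def test_zero_parameter_fixed_point(self):
        # all weights/biases zero, c_prev = 0: every gate sits at
        # sigmoid(0) = 0.5, the candidate is tanh(0) = 0, so c_t = 0 and
        # h_t = 0.5 * tanh(0) = 0
        params = _zero_params(4, 9)
        h, c = lstm_cell_step(np.ones(9), np.zeros(4), np.zeros(4), params)
        np.testing.assert_array_equal(c, np.zeros(4))
        np.testing.assert_array_equal(h, np.zeros(4))

    def test_saturation_limit_reaches_tanh_of_one(self):
        # forget gate shut (b_f → −inf), input/output gates open and the
        # candidate saturated (+inf): c_t → 1, h_t → tanh(1) ≈ 0.7616,
        # regardless of the previous cell state; checked at magnitude 50
        params = _zero_params(3, 9)
        params.b_f[:] = -50.0
        params.b_i[:] = 50.0
        params.b_o[:] = 50.0
        params.b_C[:] = 50.0
        for c_prev in (np.zeros(3), np.full(3, -7.0), np.full(3, 4.0)):
            h, c = lstm_cell_step(np.zeros(9), np.zeros(3), c_prev, params)
            np.testing.assert_allclose(c, 1.0, atol=1e-12)
            np.testing.assert_allclose(h, np.tanh(1.0), atol=1e-12)
            assert abs(h[0] - 0.7616) < 1e-4

    def test_matches_hand_coded_scalar_oracle(self):
        # H = 1, D = 1: compare against an independently written scalar
        # transcription of the gate equations over 1,000 random draws
        import math

        def scalar_oracle(x, h_prev, c_prev, wf, wi, wc, wo, bf, bi, bc, bo):
            def sig(v):
                return 1.0 / (1.0 + math.exp(-v))
            zf = wf[0] * h_prev + wf[1] * x + bf
            zi = wi[0] * h_prev + wi[1] * x + bi
            zc = wc[0] * h_prev + wc[1] * x + bc
            zo = wo[0] * h_prev + wo[1] * x + bo
            c = sig(zf) * c_prev + sig(zi) * math.tanh(zc)
            h = sig(zo) * math.tanh(c)
            return h, c

        rng = np.random.default_rng(12)
        for _ in range(1000):
            wf, wi, wc, wo = rng.normal(0, 2, (4, 2))
            bf, bi, bc, bo = rng.normal(0, 2, 4)
            x, h_prev, c_prev = rng.normal(0, 2, 3)
            params = LSTMParams(
                W_f=wf.reshape(1, 2), W_i=wi.reshape(1, 2),
                W_C=wc.reshape(1, 2), W_o=wo.reshape(1, 2),
                b_f=np.array([bf]), b_i=np.array([bi]),
                b_C=np.array([bc]), b_o=np.array([bo]),
            )
            h, c = lstm_cell_step(np.array([x]), np.array([h_prev]),
                                  np.array([c_prev]), params)
            h_ref, c_ref = scalar_oracle(x, h_prev, c_prev, wf, wi, wc, wo,
                                         bf, bi, bc, bo)
            assert abs(h[0] - h_ref) < 1e-12
            assert abs(c[0] - c_ref) < 1e-12

    def test_shape_mismatch_raises(self):
        params = _zero_params(4, 9)
        with pytest.raises(ValueError):
            lstm_cell_step(np.ones(5), np.zeros(4), np.zeros(4), params)
        with pytest.raises(ValueError):
            lstm_cell_step(np.ones(9), np.zeros(3), np.zeros(4), params)


class TestLSTMExtractor:
    def test_window_one_features_equal_single_cell_step(self):
        # with window_len=1 each row's feature vector must equal one cell
        # application from the zero state
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (20, 9))
        y = rng.integers(0, 2, 20)
        ex = LSTMFeatureExtractor(hidden_size=6, window_len=1, epochs=0,
                                  random_state=1).fit(X, y)
        feats = ex.transform(X)
        for r in range(20):
            h, _ = lstm_cell_step(X[r], np.zeros(6), np.zeros(6), ex.params_)
            np.testing.assert_allclose(feats[r], h, atol=1e-12)

    def test_longer_window_matches_manual_recurrence(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (15, 9))
        y = rng.integers(0, 2, 15)
        W = 4
        ex = LSTMFeatureExtractor(hidden_size=5, window_len=W, epochs=0,
                                  random_state=2).fit(X, y)
        feats = ex.transform(X)
        for r in (0, 1, 7, 14):
            idx = np.clip(np.arange(r - W + 1, r + 1), 0, None)
            h = np.zeros(5)
            c = np.zeros(5)
            for i in idx:
                h, c = lstm_cell_step(X[i], h, c, ex.params_)
            np.testing.assert_allclose(feats[r], h, atol=1e-12)

    def test_edge_windows_repeat_first_row(self):
        X = np.arange(30.0).reshape(10, 3)
        w = _build_windows(X, 4)
        np.testing.assert_array_equal(w[0], np.tile(X[0], (4, 1)))
        np.testing.assert_array_equal(w[1][:3], np.tile(X[0], (3, 1)))
        np.testing.assert_array_equal(w[9], X[6:10])

    def test_zero_parameters_give_zero_features(self):
        X = np.random.default_rng(0).normal(size=(8, 9))
        ex = LSTMFeatureExtractor(hidden_size=3, epochs=0, random_state=0)
        ex.fit(X, np.array([0, 1] * 4))
        ex.params_ = _zero_params(3, 9)
        np.testing.assert_array_equal(ex.transform(X), np.zeros((8, 3)))

    def test_untrained_extractor_is_well_defined(self):
        X = np.random.default_rng(1).normal(size=(12, 9))
        ex = LSTMFeatureExtractor(hidden_size=4, epochs=0, random_state=3)
        ex.fit(X, np.array([0, 1] * 6))
        feats = ex.transform(X)
        assert feats.shape == (12, 4)
        assert np.all(np.isfinite(feats))

    def test_duplicate_rows_get_identical_features(self):
        X = np.tile(np.arange(9.0), (6, 1))
        ex = LSTMFeatureExtractor(hidden_size=4, epochs=0, random_state=0)
        ex.fit(X, np.array([0, 1] * 3))
        feats = ex.transform(X)
        assert np.all(feats == feats[0])

    def test_training_separates_two_classes(self, two_class_blobs):
        X, y = two_class_blobs
        ex = LSTMFeatureExtractor(hidden_size=8, epochs=5,
                                  random_state=0).fit(X, y)
        assert ex.head_accuracy(X, y) > 0.9

    def test_training_is_seed_deterministic(self, two_class_blobs):
        X, y = two_class_blobs
        a = LSTMFeatureExtractor(hidden_size=4, epochs=2, random_state=7).fit(X, y)
        b = LSTMFeatureExtractor(hidden_size=4, epochs=2, random_state=7).fit(X, y)
        np.testing.assert_array_equal(a.params_.W_f, b.params_.W_f)
        np.testing.assert_array_equal(a.params_.W_y, b.params_.W_y)

    def test_window_longer_than_data_raises(self):
        X = np.zeros((3, 9))
        with pytest.raises(ValueError, match="window_len"):
            LSTMFeatureExtractor(window_len=5).fit(X, np.array([0, 1, 0]))

    def test_bptt_gradients_match_finite_differences(self):
        # numerical check of the backward pass on a tiny problem
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (6, 3))
        y = rng.integers(0, 2, 6)
        ex = LSTMFeatureExtractor(hidden_size=2, window_len=3, epochs=0,
                                  random_state=0).fit(X, y)
        params = ex.params_
        windows = _build_windows(X, 3)
        y_idx = np.searchsorted(ex.classes_, y)

        def loss():
            h_T, _ = ex._forward(windows, params)
            logits = h_T @ params.W_y.T + params.b_y
            logits = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            return -np.mean(np.log(p[np.arange(len(y)), y_idx]))

        h_T, tape = ex._forward(windows, params)
        logits = h_T @ params.W_y.T + params.b_y
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        onehot = np.zeros_like(p)
        onehot[np.arange(len(y)), y_idx] = 1.0
        dlogits = (p - onehot) / len(y)
        grads = ex._backward(dlogits @ params.W_y, tape, params)

        eps = 1e-6
        for name in ("W_f", "W_i", "W_C", "W_o", "b_f", "b_C"):
            arr = getattr(params, name)
            flat = arr.reshape(-1)
            for j in (0, flat.size // 2, flat.size - 1):
                orig = flat[j]
                flat[j] = orig + eps
                up = loss()
                flat[j] = orig - eps
                down = loss()
                flat[j] = orig
                num = (up - down) / (2 * eps)
                assert abs(num - grads[name].reshape(-1)[j]) < 1e-5


class TestRFExtractor:
    def test_table_defaults(self, separable_table):
        ex = RFProbabilityExtractor().fit(separable_table.features,
                                          separable_table.labels)
        assert ex.n_estimators == 10
        assert ex.max_depth == 10
        assert ex.criterion == "entropy"
        assert len(ex.forest_.estimators_) == 10

    def test_pure_stump_gives_one_hot_rows(self):
        # one tree, perfectly separable 2-class toy: leaves are pure, so
        # every probability row is a one-hot vector
        X = np.vstack([np.zeros((5, 9)), np.ones((5, 9))])
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        ex = RFProbabilityExtractor(n_estimators=1, max_depth=1,
                                    random_state=0).fit(X, y)
        probs = ex.transform(X)
        assert set(np.unique(probs)) <= {0.0, 1.0}
        np.testing.assert_array_equal(probs.sum(axis=1), np.ones(10))

    def test_probabilities_are_per_tree_averages(self, separable_table):
        # Eq.-style dual route: forest output must equal the brute-force
        # mean of per-tree class distributions
        ex = RFProbabilityExtractor(random_state=3).fit(
            separable_table.features, separable_table.labels)
        X = separable_table.features[:100]
        manual = np.mean([t.predict_proba(X) for t in ex.forest_.estimators_],
                         axis=0)
        np.testing.assert_allclose(ex.transform(X), manual, atol=1e-12)

    def test_rows_sum_to_one(self, separable_table):
        ex = RFProbabilityExtractor().fit(separable_table.features,
                                          separable_table.labels)
        rng = np.random.default_rng(0)
        probe = rng.normal(0, 5, (100, 9))
        sums = ex.transform(probe).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_seeded_determinism(self, separable_table):
        probe = separable_table.features[:50]
        a = RFProbabilityExtractor(random_state=5).fit(
            separable_table.features, separable_table.labels).transform(probe)
        b = RFProbabilityExtractor(random_state=5).fit(
            separable_table.features, separable_table.labels).transform(probe)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            RFProbabilityExtractor().fit(np.zeros((5, 9)), np.zeros(5, int))

    def test_dimension_mismatch_rejected(self, separable_table):
        ex = RFProbabilityExtractor().fit(separable_table.features,
                                          separable_table.labels)
        with pytest.raises(ValueError):
            ex.transform(np.zeros((3, 5)))


class TestRFLTransformer:
    def test_output_width_is_classes_plus_hidden(self, separable_table):
        est = RFLTransformer(hidden_size=32, epochs=0, mode="in_sample",
                             random_state=0)
        out = est.fit_transform(separable_table.features,
                                separable_table.labels)
        assert out.shape == (len(separable_table), 8 + 32)
        assert transfer_feature_names(8, 32)[:2] == ["rf_p0", "rf_p1"]
        assert transfer_feature_names(8, 32)[8] == "lstm_h0"

    def test_probability_block_always_normalized(self, separable_table):
        for mode in ("in_sample", "out_of_fold"):
            est = RFLTransformer(hidden_size=4, epochs=0, mode=mode,
                                 oof_folds=3, random_state=0)
            out = est.fit_transform(separable_table.features,
                                    separable_table.labels)
            np.testing.assert_allclose(out[:, :8].sum(axis=1), 1.0, atol=1e-9)
            assert np.all(np.isfinite(out))

    def test_zero_hidden_size_degenerates_to_rf_probabilities(self, separable_table):
        est = RFLTransformer(hidden_size=0, mode="in_sample", random_state=0)
        out = est.fit_transform(separable_table.features,
                                separable_table.labels)
        ref = RFProbabilityExtractor(random_state=0).fit(
            separable_table.features,
            separable_table.labels).transform(separable_table.features)
        np.testing.assert_array_equal(out, ref)

    def test_oof_equals_brute_force_refit_on_two_folds(self):
        # label is a deterministic function of feature 1; OOF rows must
        # equal probabilities from extractors refitted manually on the
        # complementary fold
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (40, 9))
        y = (X[:, 0] > 0).astype(int)
        est = RFLTransformer(hidden_size=0, mode="out_of_fold", oof_folds=2,
                             random_state=11)
        out = est.fit_transform(X, y)
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=11)
        for fit_idx, held_idx in skf.split(X, y):
            ref = RFProbabilityExtractor(random_state=11).fit(
                X[fit_idx], y[fit_idx]).transform(X[held_idx])
            np.testing.assert_allclose(out[held_idx], ref, atol=1e-12)

    def test_oof_on_foreign_matrix_is_rejected(self, separable_table):
        other = FeatureTable(features=separable_table.features[:10] + 1.0,
                             labels=separable_table.labels[:10])
        with pytest.raises(ValueError, match="out_of_fold"):
            rfl_transform(separable_table, other,
                          RFLConfig(hidden_size=0), mode="out_of_fold")

    def test_in_sample_training_accuracy_dominates_oof_cv(self):
        # the leakage demonstration: reusing in-sample probabilities of
        # the rows the forest was trained on inflates downstream accuracy
        spec = reference_sim_spec(baseline_gap=0.6, noise_sd=1.2, seed=3)
        table = generate_dataset(spec, 2000, seed=3)
        cfg = RFLConfig(hidden_size=16, epochs=3, seed=0)
        tf_in = rfl_transform(table, table, cfg, mode="in_sample")
        model = train_classifier(ClassifierSpec("rf"), tf_in.matrix,
                                 table.labels)
        acc_in = np.mean(predict(model, tf_in.matrix) == table.labels)
        cv = kfold_cv(ClassifierSpec("rf"), table, k=5, seed=0,
                      use_rfl=True, rfl_config=cfg)
        assert acc_in > cv.mean

    def test_transform_of_test_partition_needs_no_labels(self, separable_table):
        # the held-out path goes through transform(X) which has no label
        # argument at all — the audit that test labels cannot leak
        est = RFLTransformer(hidden_size=4, epochs=1, random_state=0)
        est.fit(separable_table.features, separable_table.labels)
        import inspect
        assert list(inspect.signature(est.transform).parameters) == ["X"]
        out = est.transform(separable_table.features[:17])
        assert out.shape == (17, 12)

    def test_unknown_mode_rejected(self, separable_table):
        est = RFLTransformer(mode="bogus")
        with pytest.raises(ValueError):
            est.fit(separable_table.features, separable_table.labels)
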