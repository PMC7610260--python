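import numpy as np
import pytest

import fingerdx as fx
from fingerdx.networks import (ArchitectureError, TrainingError,
                               _LocallyConnected1D, arch_for_width)


def toy_separable(n=200, seed=0):
    """2-bin toy: cases shifted +5 sd on bin 0."""
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    X = rng.normal(size=(n, 2))
    X[:, 0] += 5.0 * y
    return X, y


class TestArchitectureSpec:
    def test_default_has_four_locally_connected_blocks(self):
        arch = fx.default_arch(881)
        assert len(arch.lc_layers) == 4

    def test_kernel_wider_than_input_rejected(self):
        with pytest.raises(ArchitectureError, match="kernel_width"):
            fx.ArchitectureSpec(input_width=5, lc_layers=(fx.LCBlock(9, 3, 4),))

    def test_kernel_wider_than_intermediate_width_rejected(self):
        # 20 -> 4 positions after the first block; a 9-wide kernel cannot follow
        with pytest.raises(ArchitectureError):
            fx.ArchitectureSpec(input_width=20,
                                lc_layers=(fx.LCBlock(9, 3, 4), fx.LCBlock(9, 3, 4)))

    def test_arch_for_width_adapts_depth(self):
        assert len(arch_for_width(881).lc_layers) == 4
        assert len(arch_for_width(20).lc_layers) == 1
        assert arch_for_width(5).lc_layers == ()

    def test_locally_connected_parameter_count(self):
        """Parameters = out_positions * (k*c_in + 1) * c, by enumeration."""
        rng = np.random.default_rng(0)
        for w, k, s, c, c_in in [(40, 5, 2, 3, 1), (881, 9, 3, 8, 1), (30, 4, 4, 2, 5)]:
            layer = _LocallyConnected1D(w, c_in, fx.LCBlock(k, s, c), rng)
            out_positions = (w - k) // s + 1
            expected = out_positions * (k * c_in + 1) * c
            assert layer.n_parameters == expected
            # explicit enumeration of the weight tensors
            assert layer.W.shape == (out_positions, c, c_in, k)
            assert layer.b.shape == (out_positions, c)
            assert layer.W.size + layer.b.size == expected


class TestForwardPass:
    def test_softmax_outputs_sum_to_one_untrained(self, rng):
        model = fx.build_model(fx.ArchitectureSpec(
            input_width=30, lc_layers=(fx.LCBlock(5, 2, 3),), fc_layers=(8,)))
        X = rng.normal(size=(7, 30))
        logits, _ = model._forward(X, None)
        from fingerdx.networks import _softmax

        probs = _softmax(logits)
        assert probs.shape == (7, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs > 0) & (probs < 1))

    def test_locally_connected_weights_are_unshared(self, rng):
        """Perturbing one position's weights changes only outputs at that position."""
        layer = _LocallyConnected1D(20, 1, fx.LCBlock(4, 4, 2), rng)
        x = rng.normal(size=(3, 1, 20))
        before, _ = layer.forward(x)
        layer.W[2] += 1.0
        after, _ = layer.forward(x)
        changed = np.any(before != after, axis=(0, 1))
        assert changed[2] and not changed[[0, 1, 3, 4]].any()


class TestTraining:
    def test_separable_toy_reaches_high_accuracy(self):
        X, y = toy_separable()
        model = fx.build_model(fx.ArchitectureSpec(
            input_width=2, lc_layers=(), fc_layers=(8,), dropout_rate=0.1,
            input_dropout_rate=0.0))
        model.fit(X, y, cfg=fx.TrainConfig(seed=0))
        acc = np.mean((model.predict_scores(X) > 0.5) == y)
        assert acc >= 0.95
        assert fx.auc(model.predict_scores(X), y) >= 0.95

    def test_refit_same_seed_is_bitwise_identical(self, small_cohort):
        X = fx.tic_normalize_matrix(small_cohort.fingerprints.values)
        y = small_cohort.labels
        arch = fx.ArchitectureSpec(input_width=40, lc_layers=(fx.LCBlock(5, 2, 4),),
                                   fc_layers=(8,))
        cfg = fx.TrainConfig(seed=3, max_epochs=10, early_stop_patience=10)
        m1 = fx.build_model(arch).fit(X, y, cfg=cfg)
        m2 = fx.build_model(arch).fit(X, y, cfg=cfg)
        np.testing.assert_array_equal(m1.predict_scores(X), m2.predict_scores(X))
        for p1, p2 in zip(m1._params(), m2._params()):
            np.testing.assert_array_equal(p1, p2)

    def test_full_schedule_records_every_epoch(self):
        X, y = toy_separable(n=60)
        model = fx.build_model(fx.ArchitectureSpec(input_width=2, lc_layers=(),
                                                   fc_layers=(4,)))
        model.fit(X, y, cfg=fx.TrainConfig(max_epochs=80, early_stop_patience=80,
                                           seed=1))
        assert len(model.history) == 80
        assert [e["epoch"] for e in model.history] == list(range(80))

    def test_early_stop_halts_before_cap(self):
        # pure-noise labels: the holdout monitor cannot keep improving
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 2))
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        model = fx.build_model(fx.ArchitectureSpec(input_width=2, lc_layers=(),
                                                   fc_layers=(4,)))
        model.fit(X, y, cfg=fx.TrainConfig(max_epochs=80, early_stop_patience=3,
                                           seed=1))
        assert len(model.history) < 80

    def test_single_class_labels_rejected(self):
        X = np.ones((10, 2))
        model = fx.build_model(fx.ArchitectureSpec(input_width=2, lc_layers=(),
                                                   fc_layers=(4,)))
        with pytest.raises(TrainingError, match="single class"):
            model.fit(X, np.ones(10, int), cfg=fx.TrainConfig(seed=0))

    def test_misaligned_rows_rejected(self):
        X, y = toy_separable(n=20)
        model = fx.build_model(fx.ArchitectureSpec(input_width=2, lc_layers=(),
                                                   fc_layers=(4,)))
        with pytest.raises(TrainingError):
            model.fit(X, y[:-1], cfg=fx.TrainConfig(seed=0))


class TestPrediction:
    def test_scores_in_unit_interval_and_pure(self, small_trained_sn):
        model, X, y = small_trained_sn
        s1 = model.predict_scores(X)
        s2 = model.predict_scores(X)
        assert np.all((s1 >= 0) & (s1 <= 1))
        np.testing.assert_array_equal(s1, s2)  # bitwise-stable, dropout off

    def test_sample_order_equivariance(self, small_trained_sn, rng):
        model, X, y = small_trained_sn
        perm = rng.permutation(X.shape[0])
        np.testing.assert_allclose(model.predict_scores(X[perm]),
                                   model.predict_scores(X)[perm], atol=1e-12)

    def test_width_mismatch_raises(self, small_trained_sn):
        model, X, _ = small_trained_sn
        with pytest.raises(TrainingError, match="width"):
            model.predict_scores(X[:, :-1])


class TestCSN:
    def _cohort(self, seed=0, n=60, bins=30, signal=0.2):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        X = rng.normal(size=(n, bins)) + signal * y[:, None]
        return X, y

    def _arch(self, clinical_width):
        return fx.ArchitectureSpec(input_width=30,
                                   lc_layers=(fx.LCBlock(5, 2, 3),),
                                   fc_layers=(8,), clinical_width=clinical_width,
                                   input_dropout_rate=0.0, dropout_rate=0.2)

    def test_builder_dispatch(self):
        with pytest.raises(ArchitectureError):
            fx.build_model(self._arch(2))
        with pytest.raises(ArchitectureError):
            fx.build_csn(self._arch(0))

    def test_label_leak_in_clinical_column_gives_near_perfect_auc(self):
        X, y = self._cohort()
        clin = np.c_[y.astype(float), np.ones(60)]
        model = fx.build_csn(self._arch(2))
        model.fit(X, y, clinical=clin, cfg=fx.TrainConfig(seed=0, max_epochs=40,
                                                          early_stop_patience=40))
        assert fx.auc(model.predict_scores(X, clin), y) >= 0.99

    def test_constant_clinical_block_matches_sn(self):
        """All-constant clinical columns add no signal: CSN ~ SN over seeds."""
        diffs = []
        for seed in range(10):
            X, y = self._cohort(seed=seed, n=200, signal=0.4)
            Xtest, ytest = self._cohort(seed=100 + seed, n=400, signal=0.4)
            clin = np.ones((200, 2))
            cfg = fx.TrainConfig(seed=seed, max_epochs=40, early_stop_patience=40)
            a0 = self._arch(0)
            a2 = self._arch(2)
            import dataclasses

            a0 = dataclasses.replace(a0, dropout_rate=0.1)
            a2 = dataclasses.replace(a2, dropout_rate=0.1)
            sn = fx.build_model(a0).fit(X, y, cfg=cfg)
            csn = fx.build_csn(a2).fit(X, y, clinical=clin, cfg=cfg)
            diffs.append(fx.auc(csn.predict_scores(Xtest, np.ones((400, 2))), ytest)
                         - fx.auc(sn.predict_scores(Xtest), ytest))
        assert abs(np.mean(diffs)) <= 0.05

    def test_rejects_missing_clinical_block(self):
        X, y = self._cohort()
        model = fx.build_csn(self._arch(2))
        model.fit(X, y, clinical=np.ones((60, 2)),
                  cfg=fx.TrainConfig(seed=0, max_epochs=5, early_stop_patience=5))
        with pytest.raises(TrainingError, match="clinical"):
            model.predict_scores(X)


class TestPersistence:
    def test_save_load_roundtrip(self, small_trained_sn, tmp_path):
        model, X, _ = small_trained_sn
        path = tmp_path / "model.json"
        model.save(path)
        back = fx.SNClassifier.load(path)
        np.testing.assert_array_equal(back.predict_scores(X), model.predict_scores(X))
        assert back.arch == model.arch
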