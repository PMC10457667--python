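"""Networks, two-stream sampling, training loop and results object."""

import numpy as np
import pandas as pd
import pytest

from nclabel import (
    CrossModalLabelTransfer,
    LabelTransferResults,
    LossWeights,
    ModelConfig,
    TrainConfig,
    epoch_minibatches,
)
from nclabel.autodiff import Tensor
from nclabel.losses import ce_loss_from_logits, fa_loss, ncl_loss, pr_loss, total_loss
from nclabel.model import Adam, SGD, classify, encode, init_parameters


class TestInit:
    def test_linear_parameter_shapes(self):
        cfg = ModelConfig(input_dim=100, n_classes=3, embed_dim=8, encoder_hidden=[])
        params = init_parameters(cfg, seed=0)
        shapes = [p.value.shape for p in params["encoder"]]
        assert shapes == [(100, 8), (8,)]
        assert [p.value.shape for p in params["classifier"]] == [(8, 3), (3,)]

    def test_hidden_layer_shapes(self):
        cfg = ModelConfig(input_dim=20, n_classes=2, embed_dim=4, encoder_hidden=[16])
        shapes = [p.value.shape for p in init_parameters(cfg, 1)["encoder"]]
        assert shapes == [(20, 16), (16,), (16, 4), (4,)]

    def test_seeded_init_is_bitwise_identical(self):
        cfg = ModelConfig(input_dim=30, n_classes=2, embed_dim=4)
        a = init_parameters(cfg, seed=7)
        b = init_parameters(cfg, seed=7)
        for pa, pb in zip(a["encoder"] + a["classifier"], b["encoder"] + b["classifier"]):
            assert np.array_equal(pa.value, pb.value)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ModelConfig(input_dim=10, n_classes=3, embed_dim=1)
        with pytest.raises(ValueError):
            ModelConfig(input_dim=10, n_classes=1)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=1)


class TestMinibatches:
    def test_cycling_counts(self):
        rng = np.random.default_rng(0)
        batches = epoch_minibatches(n_ref=10, n_target=20, batch_size=5, rng=rng)
        assert len(batches) == 4
        ref_indices = np.concatenate([b[0] for b in batches])
        # two full shuffled passes over the 10 reference cells
        counts = np.bincount(ref_indices, minlength=10)
        np.testing.assert_array_equal(counts, 2)
        tgt_indices = np.concatenate([b[1] for b in batches])
        np.testing.assert_array_equal(np.bincount(tgt_indices, minlength=20), 1)

    def test_equal_sizes_single_batch(self):
        batches = epoch_minibatches(5, 5, 5, np.random.default_rng(0))
        assert len(batches) == 1
        assert set(batches[0][0]) == set(range(5))

    def test_deterministic_under_seed(self):
        a = epoch_minibatches(13, 29, 7, np.random.default_rng(3))
        b = epoch_minibatches(13, 29, 7, np.random.default_rng(3))
        for (r1, t1), (r2, t2) in zip(a, b):
            np.testing.assert_array_equal(r1, r2)
            np.testing.assert_array_equal(t1, t2)

    def test_cycling_disabled_errors(self):
        with pytest.raises(ValueError, match="cycling"):
            epoch_minibatches(4, 20, 5, np.random.default_rng(0), cycle=False)


def _small_model(bench, **tc_kwargs):
    defaults = dict(epochs=3, batch_size=64, k0=10, seed=0)
    defaults.update(tc_kwargs)
    tc = TrainConfig(**defaults)
    return CrossModalLabelTransfer(bench["reference"], bench["target"], bench["rep"],
                                   train_config=tc)


class TestFit:
    def test_loss_decreases_on_benchmark(self, tiny_benchmark):
        res = _small_model(tiny_benchmark, epochs=25).fit()
        eh = res.epoch_history
        assert eh["total"].iloc[-1] < eh["total"].iloc[0]
        assert len(eh) == 25

    def test_two_runs_identical(self, tiny_benchmark):
        res1 = _small_model(tiny_benchmark).fit()
        res2 = _small_model(tiny_benchmark).fit()
        pd.testing.assert_frame_equal(res1.history, res2.history)
        for p1, p2 in zip(res1.params["encoder"], res2.params["encoder"]):
            assert np.array_equal(p1.value, p2.value)

    def test_inputs_not_mutated(self, tiny_benchmark):
        ref_before = tiny_benchmark["reference"].to_dense().copy()
        tgt_before = tiny_benchmark["target"].to_dense().copy()
        _small_model(tiny_benchmark).fit()
        np.testing.assert_array_equal(tiny_benchmark["reference"].to_dense(), ref_before)
        np.testing.assert_array_equal(tiny_benchmark["target"].to_dense(), tgt_before)

    def test_reference_without_labels_rejected(self, tiny_benchmark):
        from nclabel import ExpressionDataset

        ref = tiny_benchmark["reference"]
        unlabeled = ExpressionDataset(ref.matrix, ref.cell_ids, ref.gene_names)
        with pytest.raises(ValueError, match="labels"):
            CrossModalLabelTransfer(unlabeled, tiny_benchmark["target"],
                                    tiny_benchmark["rep"])

    def test_misaligned_rep_rejected(self, tiny_benchmark):
        from nclabel import LowDimRep

        rep = tiny_benchmark["rep"]
        shuffled = LowDimRep(rep.coords, list(reversed(rep.cell_ids)))
        with pytest.raises(Exception, match="cell ids"):
            CrossModalLabelTransfer(tiny_benchmark["reference"],
                                    tiny_benchmark["target"], shuffled)


class TestTrainStepSemantics:
    def test_zero_learning_rate_keeps_parameters(self, tiny_benchmark):
        model = _small_model(tiny_benchmark, epochs=1)
        cfg = ModelConfig(input_dim=model.reference.n_genes,
                          n_classes=model.vocab.n_classes, embed_dim=8,
                          encoder_hidden=[])
        model.model_config = cfg
        before = [p.value.copy() for p in init_parameters(cfg, 0)["encoder"]]
        # lr=0 must leave parameters exactly at their init
        model.train_config = TrainConfig(epochs=1, batch_size=64, k0=10, seed=0,
                                         optimizer="sgd", learning_rate=0.0)
        res = model.fit()
        for p, b in zip(res.params["encoder"], before):
            np.testing.assert_array_equal(p.value, b)
        assert len(res.history) >= 1 and np.isfinite(res.history["total"]).all()

    def test_regularizers_leave_classifier_untouched(self, rng):
        """PR/FA/NCL gradients must not reach classifier parameters."""
        cfg = ModelConfig(input_dim=12, n_classes=3, embed_dim=4, encoder_hidden=[])
        params = init_parameters(cfg, 0)
        x_rna = rng.standard_normal((6, 12))
        x_atac = rng.standard_normal((6, 12))
        h_rna, h_atac = encode(params, x_rna), encode(params, x_atac)
        h_partner = encode(params, x_atac + 0.01 * rng.standard_normal((6, 12)))
        reg = pr_loss(h_rna, h_atac) + fa_loss(h_atac, h_rna, 0.8) \
            + ncl_loss(h_atac, h_partner, 0.5)
        reg.backward()
        assert all(p.grad is None for p in params["classifier"])
        assert all(p.grad is not None for p in params["encoder"])

    def test_supervised_reduction(self, rng):
        """With all regularizer weights at zero the update equals a plain
        supervised cross-entropy step on the reference stream."""
        cfg = ModelConfig(input_dim=10, n_classes=3, embed_dim=4, encoder_hidden=[])
        x = rng.standard_normal((8, 10))
        y = rng.integers(0, 3, size=8)

        def ce_only_step():
            params = init_parameters(cfg, 0)
            allp = params["encoder"] + params["classifier"]
            opt = SGD(allp, lr=0.05, momentum=0.0)
            loss = ce_loss_from_logits(classify(params, encode(params, x)), y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            return [p.value.copy() for p in allp]

        def combined_step():
            params = init_parameters(cfg, 0)
            allp = params["encoder"] + params["classifier"]
            opt = SGD(allp, lr=0.05, momentum=0.0)
            w = LossWeights(pr_weight=0.0, lambda1=0.0, lambda2=0.0)
            h_rna = encode(params, x)
            h_atac = encode(params, x[::-1].copy())
            ce = ce_loss_from_logits(classify(params, h_rna), y)
            obj = total_loss(ce, pr_loss(h_rna, h_atac),
                             fa_loss(h_atac, h_rna, 0.8),
                             ncl_loss(h_atac, h_atac + 0.0, 0.5), w)
            opt.zero_grad()
            obj.backward()
            opt.step()
            return [p.value.copy() for p in allp]

        for a, b in zip(ce_only_step(), combined_step()):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_objective_gradient_matches_finite_differences(self, rng):
        """Numerical check of the full combined objective on a tiny model."""
        cfg = ModelConfig(input_dim=20, n_classes=3, embed_dim=4, encoder_hidden=[])
        params = init_parameters(cfg, 0)
        x_rna = rng.standard_normal((4, 20))
        x_atac = rng.standard_normal((4, 20))
        x_part = x_atac + 0.1 * rng.standard_normal((4, 20))
        y = np.array([0, 1, 2, 0])
        w = LossWeights(tau=0.5)

        def objective(params):
            h_rna = encode(params, x_rna)
            h_atac = encode(params, x_atac)
            h_part = encode(params, x_part)
            return total_loss(
                ce_loss_from_logits(classify(params, h_rna), y),
                pr_loss(h_rna, h_atac),
                fa_loss(h_atac, h_rna, w.top_p),
                ncl_loss(h_atac, h_part, w.tau),
                w,
            )

        obj = objective(params)
        obj.backward()
        weight = params["encoder"][0]
        rng_idx = np.random.default_rng(0)
        for _ in range(12):
            i, j = rng_idx.integers(0, 20), rng_idx.integers(0, 4)
            eps = 1e-6
            orig = weight.value[i, j]
            weight.value[i, j] = orig + eps
            up = float(objective(params).value)
            weight.value[i, j] = orig - eps
            down = float(objective(params).value)
            weight.value[i, j] = orig
            numeric = (up - down) / (2 * eps)
            assert weight.grad[i, j] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestResults:
    def test_predict_probabilities_and_ties(self, tiny_benchmark):
        res = _small_model(tiny_benchmark).fit()
        pred = res.predict()
        np.testing.assert_allclose(pred.probabilities.sum(axis=1), 1.0, atol=1e-9)
        assert pred.n_cells == tiny_benchmark["target"].n_cells
        assert pred.embedding.shape == (pred.n_cells, res.model_config.embed_dim)
        np.testing.assert_allclose(pred.novel_confidence, 1.0 - pred.confidence)

    def test_checkpoint_round_trip(self, tiny_benchmark, tmp_path):
        res = _small_model(tiny_benchmark).fit()
        pred = res.predict()
        res.save(tmp_path / "ckpt.npz")
        loaded = LabelTransferResults.load(tmp_path / "ckpt.npz")
        assert loaded.vocab.classes == res.vocab.classes
        assert loaded.gene_names == res.gene_names
        pred2 = loaded.predict(tiny_benchmark["target"])
        np.testing.assert_allclose(pred2.probabilities, pred.probabilities, atol=1e-12)

    def test_predict_rejects_gene_mismatch(self, tiny_benchmark):
        from nclabel import ExpressionDataset

        res = _small_model(tiny_benchmark).fit()
        bad = ExpressionDataset(np.ones((2, 3)), ["a", "b"], ["g1", "g2", "g3"])
        with pytest.raises(ValueError, match="lacks"):
            res.predict(bad)

    def test_summary_mentions_key_settings(self, tiny_benchmark):
        res = _small_model(tiny_benchmark).fit()
        text = res.summary()
        assert "embedding dim" in text and "k0" in text and "final-epoch loss" in text


class TestOptimizers:
    def test_sgd_momentum_accumulates(self):
        p = Tensor(np.array([1.0]), requires_grad=True)
        opt = SGD([p], lr=0.1, momentum=0.5)
        for _ in range(2):
            p.grad = np.array([1.0])
            opt.step()
        # v1 = 1, p -= 0.1; v2 = 1.5, p -= 0.15
        np.testing.assert_allclose(p.value, [0.75])

    def test_adam_first_step_size(self):
        p = Tensor(np.array([0.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        p.grad = np.array([123.0])
        opt.step()
        # bias-corrected first step is ~lr regardless of gradient scale
        np.testing.assert_allclose(p.value, [-0.1], rtol=1e-6)
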