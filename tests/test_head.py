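"""The 1D-conv regression head: architecture, gradients, training recipe."""

import numpy as np
import pytest

from hist2rna import AlignmentError, ConfigurationError, InvalidInputError, StateError
from hist2rna.expression import ExpressionMatrix
from hist2rna.features import AggregatedFeature, FeatureTensor, aggregate
from hist2rna.experiments import desk_scale_train_config
from hist2rna.head import (
    HeadConfig,
    TrainConfig,
    _Model,
    build_head,
    predict,
    predict_matrix,
    train_head,
    train_on_matrix,
)
from hist2rna.synthetic import make_cohort


class TestBuildHead:
    def test_forward_returns_panel_sized_vector(self):
        m = build_head(HeadConfig(output_dim=138), input_dim=64, seed=0)
        out = m.forward(np.random.default_rng(0).standard_normal((3, 64)))
        assert out.shape == (3, 138)
        assert np.all(np.isfinite(out))

    def test_zero_input_with_zero_biases_outputs_output_bias(self):
        m = build_head(HeadConfig(output_dim=7), input_dim=16, seed=1)
        out = m.forward(np.zeros((2, 16)))
        np.testing.assert_allclose(out, np.tile(m.out_b, (2, 1)), atol=1e-12)

    def test_parameter_count_matches_closed_form(self):
        cfg = HeadConfig()  # (256, 512, 512) channels, kernels (5, 1, 1), 138 out
        m = build_head(cfg, input_dim=64)
        expected = (
            (1 * 5 * 256 + 256)        # C1
            + (256 * 1 * 512 + 512)    # C2
            + (512 * 1 * 512 + 512)    # C3
            + (512 * 138 + 138)        # dense output after pooling
        )
        assert m.n_parameters() == expected

    def test_input_smaller_than_first_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            build_head(HeadConfig(), input_dim=4)

    @pytest.mark.parametrize("variant", ["pool_then_dense", "conv_out_then_pool"])
    def test_gradients_match_finite_differences(self, variant):
        cfg = HeadConfig(conv_channels=(4, 6, 5), kernel_sizes=(3, 1, 2),
                         output_dim=3, ordering_variant=variant)
        rng = np.random.default_rng(1)
        m = _Model(cfg, 10, rng, dtype=np.float64)
        # nonzero biases keep pre-activations away from the ReLU kink at 0
        for b in (*m.conv_b, m.out_b):
            b += rng.standard_normal(b.shape) * 0.3
        X = rng.standard_normal((4, 10))
        Y = rng.standard_normal((4, 3))
        cache = []
        pred = m.forward(X, cache)
        grads = m.backward(cache, 2.0 / pred.size * (pred - Y))
        eps = 1e-6
        for p, g in zip(m.parameters(), grads):
            flat, gflat = p.ravel(), g.ravel()
            idx = rng.choice(flat.size, size=min(12, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp = np.mean((m.forward(X) - Y) ** 2)
                flat[i] = orig - eps
                lm = np.mean((m.forward(X) - Y) ** 2)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(gflat[i], rel=1e-4, abs=1e-7)

    def test_variant_orderings_differ_but_share_conv_stack(self):
        a = build_head(HeadConfig(output_dim=5), 32, seed=2)
        b = build_head(HeadConfig(output_dim=5, ordering_variant="conv_out_then_pool"),
                       32, seed=2)
        x = np.random.default_rng(0).standard_normal((1, 32))
        assert a.forward(x).shape == b.forward(x).shape == (1, 5)


def _train_inputs(n=20, f=16, g=6, seed=0, noise=0.0):
    cohort = make_cohort(n, 4, f, g, noise, seed=seed)
    aggs = [aggregate(FeatureTensor(p, cohort.features[p], "synthetic"))
            for p in cohort.patient_ids]
    return aggs, cohort.expression


class TestTrainHead:
    def test_raw_scale_targets_rejected(self):
        aggs, expr = _train_inputs()
        raw = ExpressionMatrix(expr.patient_ids, expr.gene_symbols, expr.values,
                               scale="raw")
        with pytest.raises(StateError):
            train_head(aggs, raw)

    def test_misaligned_patients_listed(self):
        aggs, expr = _train_inputs()
        with pytest.raises(AlignmentError, match="P0001"):
            train_head(aggs[1:], expr)

    def test_fewer_patients_than_batch_warns_and_trains(self):
        aggs, expr = _train_inputs(n=8)
        with pytest.warns(UserWarning, match="full-batch"):
            trained = train_head(aggs, expr,
                                 TrainConfig(seed=0, max_epochs=3, monitor="train",
                                             validation_fraction=0.0),
                                 HeadConfig(output_dim=expr.n_genes))
        assert len(trained.history["train_loss"]) == 3

    def test_constant_monitored_loss_halts_after_patience(self):
        aggs, expr = _train_inputs()
        cfg = TrainConfig(seed=0, learning_rate=0.0, early_stop_patience=4,
                          max_epochs=50, monitor="train", validation_fraction=0.0)
        trained = train_head(aggs, expr, cfg, HeadConfig(output_dim=expr.n_genes))
        # epoch 1 sets the best; 4 further epochs with no improvement, then stop
        assert len(trained.history["train_loss"]) == 5
        assert trained.best_epoch == 1

    def test_best_epoch_is_argmin_of_monitored_series(self):
        aggs, expr = _train_inputs(n=24, noise=0.3)
        cfg = TrainConfig(seed=1, max_epochs=12, monitor="train",
                          validation_fraction=0.0)
        trained = train_head(aggs, expr, cfg, HeadConfig(output_dim=expr.n_genes))
        monitored = trained.monitored_history
        assert monitored[trained.best_epoch - 1] == min(monitored)

    def test_same_seed_reproduces_history_exactly(self):
        aggs, expr = _train_inputs(n=16)
        cfg = TrainConfig(seed=5, max_epochs=4, monitor="train", validation_fraction=0.0)
        a = train_head(aggs, expr, cfg, HeadConfig(output_dim=expr.n_genes))
        b = train_head(aggs, expr, cfg, HeadConfig(output_dim=expr.n_genes))
        assert a.history == b.history

    def test_aggregation_trainer_touches_each_patient_once_per_epoch(self):
        aggs, expr = _train_inputs(n=18)
        cfg = TrainConfig(seed=0, max_epochs=3, monitor="train", validation_fraction=0.0)
        trained = train_head(aggs, expr, cfg, HeadConfig(output_dim=expr.n_genes))
        assert trained.samples_seen_per_epoch == [18, 18, 18]

    def test_noiseless_cohort_is_fit_to_low_training_error(self):
        # the generating map is linear in the aggregated features, so the head
        # should drive training MSE well below the target variance (~5 here)
        cohort = make_cohort(80, 20, 32, 20, noise_sd=0.0, seed=1)
        X = np.stack([cohort.features[p].mean(axis=0) for p in cohort.patient_ids])
        cfg = desk_scale_train_config(seed=1, max_epochs=350, patience=50)
        trained = train_on_matrix(X, cohort.expression.values, cfg,
                                  HeadConfig(output_dim=20))
        assert min(trained.history["train_loss"]) < 1e-2

    def test_heldout_accuracy_degrades_as_noise_grows(self):
        from hist2rna.evaluation import evaluate_across_patients

        medians = []
        for noise in (0.0, 0.5, 2.0):
            per_seed = []
            for seed in range(1, 6):
                cohort = make_cohort(60, 10, 16, 10, noise, seed=seed)
                X = np.stack([cohort.features[p].mean(axis=0)
                              for p in cohort.patient_ids])
                Y = cohort.expression.values
                cfg = desk_scale_train_config(seed=seed, max_epochs=60)
                trained = train_on_matrix(X[:40], Y[:40], cfg,
                                          HeadConfig(output_dim=10))
                ids = cohort.patient_ids[40:]
                pred = ExpressionMatrix(ids, cohort.expression.gene_symbols,
                                        predict_matrix(trained, X[40:]),
                                        scale="log2p1")
                truth = ExpressionMatrix(ids, cohort.expression.gene_symbols,
                                         Y[40:], scale="log2p1")
                per_seed.append(evaluate_across_patients(pred, truth)["rho"].median())
            medians.append(float(np.median(per_seed)))
        assert medians[0] > medians[1] > medians[2]


class TestPredict:
    def test_same_input_twice_identical(self):
        aggs, expr = _train_inputs()
        cfg = TrainConfig(seed=0, max_epochs=2, monitor="train", validation_fraction=0.0)
        trained = train_head(aggs, expr, cfg, HeadConfig(output_dim=expr.n_genes))
        a = predict(trained, aggs[0])
        b = predict(trained, aggs[0])
        np.testing.assert_array_equal(a, b)
        assert a.shape == (expr.n_genes,)

    def test_dimension_mismatch_rejected(self):
        aggs, expr = _train_inputs()
        cfg = TrainConfig(seed=0, max_epochs=1, monitor="train", validation_fraction=0.0)
        trained = train_head(aggs, expr, cfg, HeadConfig(output_dim=expr.n_genes))
        with pytest.raises(InvalidInputError):
            predict(trained, AggregatedFeature("x", np.zeros(5), 1))
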