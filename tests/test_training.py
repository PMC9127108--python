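"""Split arithmetic, plateau schedule, ablation variants, training, evaluation."""

import numpy as np
import pandas as pd
import pytest

from lungseg.network import ModelConfig, assemble_model
from lungseg.phantom import ImageSample
from lungseg.training import (
    ABLATION_VARIANTS,
    Adam,
    ReduceLROnPlateau,
    TrainConfig,
    TrainingDivergedError,
    build_variant,
    evaluate,
    split_dataset,
    train,
)
from lungseg.nn.autograd import Tensor


def _dummy_samples(n, size=8):
    rng = np.random.default_rng(0)
    return [
        ImageSample(
            image=rng.random((size, size, 3)),
            mask=rng.random((size, size)) > 0.5,
            sample_id=f"s{i}",
        )
        for i in range(n)
    ]


class TestSplitDataset:
    def test_stated_fractions_at_n300(self):
        tr, va, te = split_dataset(_dummy_samples(300), TrainConfig(seed=0))
        assert (len(tr), len(va), len(te)) == (160, 40, 100)

    def test_same_seed_identical_partition(self):
        samples = _dummy_samples(50)
        a = split_dataset(samples, TrainConfig(seed=3))
        b = split_dataset(samples, TrainConfig(seed=3))
        for pa, pb in zip(a, b):
            assert [s.sample_id for s in pa] == [s.sample_id for s in pb]

    def test_different_seed_differs(self):
        samples = _dummy_samples(50)
        a, _, _ = split_dataset(samples, TrainConfig(seed=3))
        b, _, _ = split_dataset(samples, TrainConfig(seed=4))
        assert [s.sample_id for s in a] != [s.sample_id for s in b]

    @pytest.mark.parametrize("n", [5, 7, 13, 100, 301])
    def test_disjoint_exhaustive_and_near_exact(self, n):
        samples = _dummy_samples(n)
        tr, va, te = split_dataset(samples, TrainConfig(seed=1))
        ids = [s.sample_id for part in (tr, va, te) for s in part]
        assert sorted(ids) == sorted(s.sample_id for s in samples)
        assert len(set(ids)) == n
        assert abs(len(te) - n / 3) <= 1
        assert abs(len(va) - 0.2 * (n - len(te))) <= 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            split_dataset(_dummy_samples(4), TrainConfig())


class TestReduceLROnPlateau:
    def test_halves_after_ten_flat_epochs(self):
        sched = ReduceLROnPlateau(2e-4, factor=0.5, patience=10)
        sched.step(1.0)  # first value becomes the best
        for _ in range(9):
            assert sched.step(1.0) == pytest.approx(2e-4)
        assert sched.step(1.0) == pytest.approx(1e-4)

    def test_improvement_resets_patience(self):
        sched = ReduceLROnPlateau(2e-4, patience=3)
        for v in [1.0, 0.9, 1.0, 1.0, 0.8, 1.0, 1.0]:
            sched.step(v)
        assert sched.lr == pytest.approx(2e-4)

    def test_sequence_is_powers_of_factor(self):
        sched = ReduceLROnPlateau(2e-4, factor=0.5, patience=2)
        lrs = [sched.step(1.0) for _ in range(13)]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        for lr in lrs:
            m = np.log(lr / 2e-4) / np.log(0.5)
            assert abs(m - round(m)) < 1e-12 and round(m) >= 0


class TestBuildVariant:
    @pytest.mark.parametrize(
        "method_id,activation,n_res",
        [(1, "relu", 0), (2, "leaky_relu", 0), (3, "relu", 1),
         (4, "leaky_relu", 1), (5, "leaky_relu", 2), (6, "leaky_relu", 3)],
    )
    def test_mapping(self, method_id, activation, n_res):
        cfg = build_variant(method_id, ModelConfig(encoder="tiny_test", input_size=64))
        assert cfg.activation == activation
        assert cfg.residual_blocks_per_decoder == n_res

    def test_variant_networks_have_declared_block_counts(self):
        for method_id, (_, n_res) in ABLATION_VARIANTS.items():
            cfg = build_variant(method_id, ModelConfig(encoder="tiny_test", input_size=32))
            net = assemble_model(cfg)
            assert all(len(b.residual_blocks) == n_res for b in net.decoder_blocks)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1..6"):
            build_variant(7, ModelConfig(encoder="tiny_test"))


class TestAdam:
    def test_minimizes_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            loss = (p * p).sum()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-3


@pytest.fixture(scope="module")
def trained(phantom_dataset):
    cfg = ModelConfig(encoder="tiny_test", input_size=64, dropout_rate=0.0)
    net = assemble_model(cfg, seed=3)
    tc = TrainConfig(initial_lr=1e-3, batch_size=8, max_epochs=5, seed=3)
    return train(net, phantom_dataset[:8], phantom_dataset[8:10], tc)


class TestTrain:
    def test_history_schema_and_lr_column(self, trained):
        _, hist = trained
        assert list(hist.columns) == ["epoch", "train_loss", "val_loss", "lr"]
        assert len(hist) == 5
        assert (hist["lr"] <= 1e-3).all()

    def test_loss_decreases(self, trained):
        _, hist = trained
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_training_is_deterministic(self, phantom_dataset):
        losses = []
        for _ in range(2):
            cfg = ModelConfig(encoder="tiny_test", input_size=64, dropout_rate=0.2)
            net = assemble_model(cfg, seed=7)
            tc = TrainConfig(initial_lr=1e-3, batch_size=4, max_epochs=2, seed=7)
            _, hist = train(net, phantom_dataset[:6], phantom_dataset[6:8], tc)
            losses.append(hist["val_loss"].tolist())
        assert losses[0] == losses[1]

    def test_batch_size_auto_reduced(self, phantom_dataset, caplog):
        import logging

        cfg = ModelConfig(encoder="tiny_test", input_size=64, dropout_rate=0.0)
        net = assemble_model(cfg, seed=0)
        tc = TrainConfig(batch_size=64, max_epochs=1, seed=0)
        with caplog.at_level(logging.INFO, logger="lungseg.training"):
            train(net, phantom_dataset[:6], phantom_dataset[6:8], tc)
        assert any("reduced" in r.message for r in caplog.records)

    def test_divergence_detected(self, phantom_dataset):
        cfg = ModelConfig(encoder="tiny_test", input_size=64, dropout_rate=0.0)
        net = assemble_model(cfg, seed=0)
        net.parameters()[0].data[:] = np.nan
        tc = TrainConfig(max_epochs=1, seed=0)
        with pytest.raises(TrainingDivergedError):
            train(net, phantom_dataset[:6], phantom_dataset[6:8], tc)


class TestEvaluate:
    def test_oracle_predictor_scores_one_everywhere(self, phantom_dataset):
        result = evaluate(lambda s: s.mask, phantom_dataset[:5], repair_enabled=True)
        for rep in (result.raw, result.repaired):
            for agg in rep.aggregate.values():
                assert agg["mean"] == 1.0 and agg["std"] == 0.0

    def test_all_background_predictor(self, phantom_dataset):
        result = evaluate(
            lambda s: np.zeros_like(s.mask), phantom_dataset[:5], repair_enabled=False
        )
        assert result.raw.aggregate["specificity"]["mean"] == 1.0
        assert result.raw.aggregate["sensitivity"]["mean"] == 0.0
        assert result.repaired is None

    def test_repair_improves_speckled_holey_predictions(self, phantom_dataset):
        def corrupt(s):
            pred = s.mask.copy()
            rng = np.random.default_rng(hash(s.sample_id) % 2**31)
            rows, cols = np.nonzero(pred)
            for _ in range(3):  # enclosed holes
                i = rng.integers(0, rows.size)
                if 2 < rows[i] < 61 and 2 < cols[i] < 61:
                    pred[rows[i], cols[i]] = False
            bg_rows, bg_cols = np.nonzero(~pred)
            for _ in range(3):  # speckles
                i = rng.integers(0, bg_rows.size)
                if bg_rows[i] in (0, 63) or bg_cols[i] in (0, 63):
                    pred[bg_rows[i], bg_cols[i]] = True
            return pred

        result = evaluate(corrupt, phantom_dataset, repair_enabled=True)
        assert (
            result.repaired.aggregate["dice"]["mean"]
            >= result.raw.aggregate["dice"]["mean"]
        )

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            evaluate(lambda s: s.mask, [])
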