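"""Split bookkeeping, the training loop contract, and cross-validation."""

import numpy as np
import pytest

from ecgnet import EcgNetConfig, TrainConfig, build_ecgnet, crossvalidate, \
    split_dataset, train_model
from ecgnet.io_formats import BeatDataset, LabelTaxonomy
from ecgnet.training import PAPER_LEARNING_RATE


def _toy_separable(n=200, seed=0):
    """Two classes distinguished by a mean offset in a lead band; verified
    linearly separable by an independent linear classifier."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 0.3, (n, 651, 12)).astype(np.float32)
    y = rng.integers(0, 2, n)
    X[y == 1, 200:400, 3:6] += 0.8
    from sklearn.linear_model import LogisticRegression

    feats = X[:, 200:400, 3:6].mean(axis=(1, 2)).reshape(-1, 1)
    order = rng.permutation(n)
    half = n // 2
    oracle = LogisticRegression().fit(feats[order[:half]], y[order[:half]])
    assert oracle.score(feats[order[half:]], y[order[half:]]) >= 0.99
    return BeatDataset(X, y, LabelTaxonomy(("neg", "pos")))


class TestSplitDataset:
    def test_single_class_1000_beats_splits_595_255_150(self, random_beats):
        ds = random_beats(1000)
        tr, va, te = split_dataset(ds, TrainConfig(seed=1))
        assert abs(len(tr) - 595) <= 1
        assert abs(len(va) - 255) <= 1
        assert abs(len(te) - 150) <= 1
        assert len(tr) + len(va) + len(te) == 1000

    def test_same_seed_gives_identical_assignments(self, random_beats):
        ds = random_beats(300, n_classes=3, seed=5)
        a = split_dataset(ds, TrainConfig(seed=9))
        b = split_dataset(ds, TrainConfig(seed=9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.meta["split_indices"],
                                          y.meta["split_indices"])

    def test_eleven_class_stratification_within_one_beat(self, random_beats):
        rng = np.random.default_rng(0)
        n_per = 40
        X = rng.standard_normal((11 * n_per, 651, 12)).astype(np.float32)
        y = np.repeat(np.arange(11), n_per)
        ds = BeatDataset(X, y, LabelTaxonomy([f"c{i}" for i in range(11)]))
        _, _, te = split_dataset(ds, TrainConfig(seed=2))
        for c in range(11):
            assert abs(int((te.y == c).sum()) - round(0.15 * n_per)) <= 1

    def test_class_smaller_than_fold_count_is_named(self, random_beats):
        ds = random_beats(20, n_classes=2, seed=1)
        ds.y[:] = 0
        ds.y[:3] = 1
        with pytest.raises(ValueError, match="C1"):
            split_dataset(ds, TrainConfig(seed=0))

    def test_partitions_are_disjoint(self, four_class_small):
        tr, va, te = split_dataset(four_class_small, TrainConfig(seed=3))
        sets = [set(s.meta["split_indices"]) for s in (tr, va, te)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
            and not (sets[1] & sets[2])


class TestTrainModel:
    def test_published_protocol_constants(self):
        cfg = TrainConfig.paper_protocol()
        assert cfg.learning_rate == PAPER_LEARNING_RATE == 8e-7
        assert cfg.batch_size == 64
        assert cfg.early_stop_patience == 5
        assert TrainConfig().batch_size == 64

    def test_separable_toy_reaches_high_validation_accuracy(self):
        ds = _toy_separable()
        cfg = TrainConfig(seed=0, learning_rate=1e-2, batch_size=16,
                          max_epochs=30)
        tr, va, _ = split_dataset(ds, cfg)
        model = build_ecgnet(EcgNetConfig(n_classes=2, base_filters=4,
                                          block2_repeats=1), rng=0)
        result = train_model(model, tr, va, cfg)
        assert max(result.history["val_acc"]) >= 0.98
        assert len(result.history["val_acc"]) <= 30

    def test_checkpoint_has_lowest_monitored_loss(self):
        ds = _toy_separable(n=80, seed=2)
        cfg = TrainConfig(seed=1, learning_rate=1e-2, batch_size=16,
                          max_epochs=6)
        tr, va, _ = split_dataset(ds, cfg)
        model = build_ecgnet(EcgNetConfig(n_classes=2, base_filters=4,
                                          block2_repeats=1), rng=1)
        result = train_model(model, tr, va, cfg)
        losses = result.history["val_loss"]
        assert result.best_monitored_loss == pytest.approx(min(losses))
        assert losses[result.best_epoch] == pytest.approx(min(losses))

    def test_divergent_loss_aborts_with_diagnostic(self):
        ds = _toy_separable(n=60, seed=3)
        cfg = TrainConfig(seed=1, learning_rate=1e12, batch_size=16,
                          max_epochs=3)
        tr, va, _ = split_dataset(ds, cfg)
        model = build_ecgnet(EcgNetConfig(n_classes=2, base_filters=4,
                                          block2_repeats=1), rng=1)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(FloatingPointError, match="learning rate"):
                train_model(model, tr, va, cfg)

    def test_label_exceeding_model_classes_rejected(self, four_class_small):
        cfg = TrainConfig(seed=0, max_epochs=1)
        tr, va, _ = split_dataset(four_class_small, cfg)
        model = build_ecgnet(EcgNetConfig(n_classes=2, base_filters=4,
                                          block2_repeats=1), rng=0)
        with pytest.raises(ValueError, match="n_classes"):
            train_model(model, tr, va, cfg)


@pytest.fixture(scope="module")
def cv_run(four_class_small):
    cfg = TrainConfig(seed=4, learning_rate=1e-2, batch_size=16, max_epochs=1)
    mcfg = EcgNetConfig(n_classes=4, base_filters=4, block2_repeats=1)
    return crossvalidate(four_class_small, mcfg, cfg), four_class_small


class TestCrossValidation:
    def test_fold_test_sets_partition_the_dataset(self, cv_run):
        (folds, _), ds = cv_run
        total = sum(f.test_confusion.total for f in folds)
        assert total == len(ds)
        # per-fold supports sum to the class counts, so no beat repeats
        per_class = np.zeros(4, dtype=int)
        for f in folds:
            per_class += f.test_confusion.counts.sum(axis=1)
        np.testing.assert_array_equal(per_class,
                                      np.bincount(ds.y, minlength=4))

    def test_averaged_report_is_mean_of_folds(self, cv_run):
        (folds, avg), _ = cv_run
        accs = [f.test_report.overall_accuracy for f in folds]
        assert avg.overall_accuracy == pytest.approx(float(np.mean(accs)))

    def test_rerun_with_same_seed_reproduces_confusions(self, four_class_small):
        cfg = TrainConfig(seed=6, learning_rate=1e-2, batch_size=16,
                          max_epochs=1)
        mcfg = EcgNetConfig(n_classes=4, base_filters=4, block2_repeats=1)
        folds1, _ = crossvalidate(four_class_small, mcfg, cfg)
        folds2, _ = crossvalidate(four_class_small, mcfg, cfg)
        for a, b in zip(folds1, folds2):
            np.testing.assert_array_equal(a.test_confusion.counts,
                                          b.test_confusion.counts)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"test_fraction": 0.0},
        {"test_fraction": 1.0},
        {"validation_fraction_of_train": 0.0},
        {"early_stop_patience": 0},
        {"batch_size": 0},
        {"monitor": "test_loss"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)
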