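import numpy as np
import pytest

from octnss.enhance import enhance_image
from octnss.harness import (
    BatchStream,
    EarlyStopping,
    ReduceLROnPlateau,
    TrainedModel,
    build_plan,
    evaluate,
    prepare_batches,
    train,
)
from octnss.io import read_gray
from octnss import nn
from octnss.nn import TinyCNNBackbone

SMALL = {
    "input_size": [32, 32, 3],
    "stage1": {"epochs": 1},
    "stage2": {"epochs": 1},
    "seed": 11,
}


class TestBuildPlan:
    def test_default_schedule_constants(self):
        plan = build_plan()
        assert plan.input_size == (224, 224, 3)
        assert plan.n_classes == 8
        assert plan.batch_size == 32
        assert plan.loss == "categorical_crossentropy"
        assert plan.stage1.lr == 1e-3 and plan.stage1.epochs == 10
        assert plan.stage1.frozen_base is True
        assert plan.stage2.lr == 1e-4 and plan.stage2.epochs == 20
        assert plan.stage2.unfreeze_last_n_layers == 50
        assert plan.dropout == 0.5
        assert plan.reduce_lr_min_lr == 1e-6

    def test_override_epochs_keeps_other_defaults(self):
        plan = build_plan({"stage1": {"epochs": 2}, "stage2": {"epochs": 2}})
        assert plan.stage1.epochs == 2 and plan.stage2.epochs == 2
        assert plan.stage1.lr == 1e-3 and plan.stage2.lr == 1e-4

    def test_stage2_lr_must_be_below_stage1(self):
        with pytest.raises(ValueError):
            build_plan({"stage2": {"lr": 1e-2}})

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError):
            build_plan({"momentum": 0.9})

    def test_yaml_file_config(self, tmp_path):
        cfg = tmp_path / "plan.yaml"
        cfg.write_text("batch_size: 16\nstage1:\n  epochs: 3\n")
        plan = build_plan(cfg)
        assert plan.batch_size == 16 and plan.stage1.epochs == 3


class TestBatchStream:
    def test_batch_count_is_ceiling_division(self, phantom_dataset):
        plan = build_plan(SMALL)
        stream = prepare_batches(phantom_dataset["train"], plan)
        assert stream.n_batches == 6  # 184 images / batch 32 -> 6, last partial
        batches = list(stream.batches())
        assert len(batches) == 6
        assert sum(len(x) for x, _ in batches) == 184

    def test_val_stream_is_bit_identical_across_iterations(self, phantom_dataset):
        plan = build_plan(SMALL)
        stream = prepare_batches(phantom_dataset["val"], plan)
        a = np.concatenate([x for x, _ in stream.batches()])
        b = np.concatenate([x for x, _ in stream.batches()])
        assert np.array_equal(a, b)

    def test_train_stream_reproducible_across_instances(self, phantom_dataset):
        plan = build_plan(SMALL)
        s1 = prepare_batches(phantom_dataset["train"], plan)
        s2 = prepare_batches(phantom_dataset["train"], plan)
        x1, _ = next(iter(s1.batches(epoch=1)))
        x2, _ = next(iter(s2.batches(epoch=1)))
        assert np.array_equal(x1, x2)

    def test_augmentation_changes_between_epochs(self, phantom_dataset):
        plan = build_plan(SMALL)
        stream = prepare_batches(phantom_dataset["train"], plan)
        x1, _ = next(iter(stream.batches(epoch=1)))
        x2, _ = next(iter(stream.batches(epoch=2)))
        assert not np.array_equal(x1, x2)

    def test_enhancement_plumbing_equals_enhance_then_prepare(self, phantom_dataset):
        plan = build_plan(SMALL)
        index = phantom_dataset["val"]
        enhanced_stream = prepare_batches(index, plan, enhance=True)
        enhanced_stream._load()
        for i, (path, _) in enumerate(index.entries[:4]):
            expected = BatchStream._prepare(
                enhance_image(read_gray(path)).enhanced, (32, 32)
            )
            assert np.allclose(enhanced_stream._images[i], expected, atol=1e-6)

    def test_class_count_mismatch_rejected(self, phantom_dataset):
        plan = build_plan({**SMALL, "n_classes": 5})
        with pytest.raises(ValueError):
            prepare_batches(phantom_dataset["train"], plan)


class TestCallbacks:
    def test_early_stopping_on_contrived_rising_loss(self):
        stopper = EarlyStopping(patience=1)
        assert stopper.update(1, 0.5) is False
        assert stopper.update(2, 0.6) is True
        assert stopper.best_epoch == 1

    def test_early_stopping_waits_out_patience(self):
        stopper = EarlyStopping(patience=2)
        assert stopper.update(1, 0.5) is False
        assert stopper.update(2, 0.6) is False
        assert stopper.update(3, 0.4) is False  # improvement resets the wait
        assert stopper.update(4, 0.5) is False
        assert stopper.update(5, 0.5) is True
        assert stopper.best_epoch == 3

    def test_plateau_halves_lr_down_to_floor(self):
        plateau = ReduceLROnPlateau(factor=0.5, patience=2, min_lr=3e-4)
        lr = 1e-3
        lr = plateau.update(0.5, lr)  # improvement
        assert lr == 1e-3
        lr = plateau.update(0.6, lr)
        lr = plateau.update(0.6, lr)  # second stale epoch triggers decay
        assert lr == 5e-4
        lr = plateau.update(0.6, lr)
        lr = plateau.update(0.6, lr)
        assert lr == 3e-4  # clamped at the floor


class TestTrain:
    def test_frozen_backbone_is_untouched_when_never_unfrozen(self, phantom_dataset):
        plan = build_plan({**SMALL, "stage2": {"epochs": 1, "unfreeze_last_n_layers": 0}})
        backbone = TinyCNNBackbone(seed=0)
        before = [p.value.copy() for p in backbone.params()]
        train(
            plan,
            backbone,
            prepare_batches(phantom_dataset["train"], plan),
            prepare_batches(phantom_dataset["val"], plan),
        )
        after = [p.value for p in backbone.params()]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_stage_two_updates_unfrozen_backbone_layers(self, phantom_dataset):
        plan = build_plan(SMALL)
        backbone = TinyCNNBackbone(seed=0)
        before = [p.value.copy() for p in backbone.params()]
        plan_no_restore = build_plan({**SMALL, "early_stopping_restore_best": False})
        train(
            plan_no_restore,
            backbone,
            prepare_batches(phantom_dataset["train"], plan),
            prepare_batches(phantom_dataset["val"], plan),
        )
        after = [p.value for p in backbone.params()]
        assert any(not np.array_equal(a, b) for a, b in zip(before, after))

    def test_history_and_reproducibility(self, phantom_dataset):
        plan = build_plan(SMALL)

        def run():
            backbone = TinyCNNBackbone(seed=plan.seed)
            return train(
                plan,
                backbone,
                prepare_batches(phantom_dataset["train"], plan),
                prepare_batches(phantom_dataset["val"], plan),
            )[1]

        h1, h2 = run(), run()
        assert len(h1.stage1["train_loss"]) == 1
        assert len(h1.stage2["train_loss"]) == 1
        assert h1.stage1 == h2.stage1
        assert h1.stage2 == h2.stage2
        assert h1.best_epoch == h2.best_epoch
        assert 1 <= h1.best_epoch <= 2


class TestEvaluate:
    def test_constant_predictor_scores_chance_on_balanced_split(self, phantom_dataset):
        plan = build_plan(SMALL)
        backbone = TinyCNNBackbone(seed=0)
        head = nn.Sequential([nn.Dense(backbone.feature_dim, plan.n_classes)])
        for p in head.params():  # zero weights -> uniform softmax -> argmax class 0
            p.value[...] = 0.0
        model = TrainedModel(backbone, head, phantom_dataset["test"].class_names)
        report = evaluate(model, prepare_batches(phantom_dataset["test"], plan))
        assert report.accuracy == pytest.approx(1 / 8)

    def test_perfect_oracle_model_scores_one(self, phantom_dataset):
        plan = build_plan(SMALL)
        stream = prepare_batches(phantom_dataset["test"], plan)
        _, y_idx = stream.all_arrays()

        class Oracle:
            class_names = stream.class_names

            def predict_proba(self, x, batch_size=32):
                probs = np.full((len(x), 8), 1e-4)
                probs[np.arange(len(x)), y_idx[: len(x)]] = 1 - 7e-4
                return probs

        report = evaluate(Oracle(), stream)
        assert report.accuracy == 1.0
        assert all(a == 1.0 for a in report.auc_ovr)
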