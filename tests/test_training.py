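import numpy as np
import pytest

from labelrefine import (
    CANONICAL_SCHEME,
    TrainConfig,
    build_model,
    finetune,
    freeze_encoder,
    parameter_checksum,
    pretrain,
    replace_weak_labels,
    run_pipeline,
)


class TestTrainConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(pretrain_epochs=-1),
        dict(finetune_epochs=-2),
        dict(replace_interval=0),
        dict(batch_size=0),
        dict(learning_rate=0.0),
        dict(confidence_branch="neither"),
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)


class TestPretrain:
    def test_zero_epochs_is_noop(self, tiny_model, weak_set):
        before = parameter_checksum(tiny_model)
        pretrain(tiny_model, weak_set, TrainConfig(pretrain_epochs=0))
        assert parameter_checksum(tiny_model) == before

    def test_training_changes_parameters(self, tiny_model, weak_set, tiny_config):
        before = parameter_checksum(tiny_model)
        pretrain(tiny_model, weak_set, tiny_config)
        assert parameter_checksum(tiny_model) != before

    def test_frozen_encoder_rejected(self, tiny_model, weak_set, tiny_config):
        freeze_encoder(tiny_model)
        with pytest.raises(ValueError):
            pretrain(tiny_model, weak_set, tiny_config)

    def test_loss_descends(self, weak_set):
        model = build_model(width=4, depth=2, seed=1)
        cfg = TrainConfig(pretrain_epochs=12, finetune_epochs=0, batch_size=2, seed=1)
        run = run_pipeline(weak_set, weak_set, cfg, model=model)
        pre = run.history[run.history.phase == "pretrain"]
        first = pre.sup_weak.iloc[:3].mean()
        last = pre.sup_weak.iloc[-3:].mean()
        assert last < first


class TestFinetune:
    def test_run_outputs(self, tiny_model, phantom_set, weak_set, tiny_config):
        run = finetune(tiny_model, phantom_set[:2], weak_set, tiny_config,
                       truth=phantom_set)
        assert len(run.weak_set) == len(weak_set)
        assert run.metrics is not None
        assert set(run.history.phase) == {"finetune"}
        assert len(run.history) == tiny_config.finetune_epochs

    def test_replacement_schedule(self, tiny_model, phantom_set, weak_set):
        cfg = TrainConfig(pretrain_epochs=0, finetune_epochs=4, replace_interval=2,
                          batch_size=2)
        run = finetune(tiny_model, phantom_set[:2], weak_set, cfg)
        assert list(run.history.replaced) == [False, True, False, True]

    def test_weak_labels_match_strong_decoder_argmax(self, tiny_model, phantom_set,
                                                     weak_set, tiny_config):
        run = finetune(tiny_model, phantom_set[:2], weak_set, tiny_config)
        # after the last epoch's replacement the weak labels must equal the
        # strong decoder's argmax on each weak image
        for s in run.weak_set:
            strong_probs, _ = run.model.forward(s.image)
            assert np.array_equal(s.labels, np.argmax(strong_probs, axis=-1))

    def test_initial_weak_preserved(self, tiny_model, phantom_set, weak_set,
                                    tiny_config):
        before = [s.labels.copy() for s in weak_set]
        run = finetune(tiny_model, phantom_set[:2], weak_set, tiny_config)
        assert all(np.array_equal(a.labels, b)
                   for a, b in zip(run.initial_weak, before))

    def test_strong_samples_untouched(self, tiny_model, phantom_set, weak_set,
                                      tiny_config):
        strong = phantom_set[:2]
        before = [s.labels.copy() for s in strong]
        run = finetune(tiny_model, strong, weak_set, tiny_config)
        assert all(np.array_equal(a.labels, b) for a, b in zip(run.strong_set, before))

    def test_weak_revisions_valid(self, tiny_model, phantom_set, weak_set, tiny_config):
        run = finetune(tiny_model, phantom_set[:2], weak_set, tiny_config)
        for s in run.weak_set:
            assert s.provenance == "weak"
            CANONICAL_SCHEME.validate_labels(s.labels)


class TestReplaceWeakLabels:
    def test_idempotent(self, tiny_model, weak_set):
        once = replace_weak_labels(tiny_model, weak_set)
        twice = replace_weak_labels(tiny_model, once)
        assert all(np.array_equal(a.labels, b.labels) for a, b in zip(once, twice))

    def test_input_not_mutated(self, tiny_model, weak_set):
        before = [s.labels.copy() for s in weak_set]
        replace_weak_labels(tiny_model, weak_set)
        assert all(np.array_equal(s.labels, b) for s, b in zip(weak_set, before))


class TestRunPipeline:
    def test_history_concatenates_phases(self, phantom_set, weak_set):
        model = build_model(width=4, depth=2, seed=2)
        cfg = TrainConfig(pretrain_epochs=2, finetune_epochs=3, batch_size=2, seed=2)
        run = run_pipeline(weak_set, phantom_set[:2], cfg, model=model,
                          truth=phantom_set)
        assert list(run.history.phase) == ["pretrain"] * 2 + ["finetune"] * 3
        assert "dsc_muscle" in run.history.columns

    def test_pretrain_zero_smoke(self, phantom_set, weak_set):
        model = build_model(width=4, depth=2, seed=2)
        cfg = TrainConfig(pretrain_epochs=0, finetune_epochs=2, batch_size=2, seed=2)
        run = run_pipeline(weak_set, phantom_set[:2], cfg, model=model)
        assert len(run.history) == 2

    def test_empty_sets_rejected(self, phantom_set, tiny_config):
        with pytest.raises(ValueError):
            run_pipeline([], phantom_set[:2], tiny_config)
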