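"""Fusion, joint objective, splitting, sampling and training-loop tests."""

import dataclasses
import math

import numpy as np
import pytest

from lnmfusion.clinical import fit_normalizer, clinical_matrix
from lnmfusion.cohort import Cohort, SyntheticParams, generate_cohort
from lnmfusion.contrastive import ContrastiveConfig, info_nce
from lnmfusion.nn import Linear, Tensor
from lnmfusion.training import (Checkpoint, TrainConfig, classify,
                                evaluate_checkpoint, fuse, load_checkpoint,
                                predict_scores, sampler_weights,
                                save_checkpoint, split_cohort, total_loss,
                                train)


# ------------------------------------------------------------------- fusion

def test_fuse_width_and_column_order(rng):
    h = [Tensor(rng.normal(size=(4, 512))) for _ in range(3)]
    fused = fuse(h)
    assert fused.data.shape == (4, 1536)
    np.testing.assert_array_equal(fused.data[:, :512], h[0].data)
    np.testing.assert_array_equal(fused.data[:, 512:1024], h[1].data)


def test_fuse_zero_block_stays_zero(rng):
    h = [Tensor(rng.normal(size=(4, 512))), Tensor(np.zeros((4, 512))),
         Tensor(rng.normal(size=(4, 512)))]
    np.testing.assert_array_equal(fuse(h).data[:, 512:1024], 0.0)


def test_fuse_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        fuse([Tensor(rng.normal(size=(4, 512))),
              Tensor(rng.normal(size=(5, 512)))])
    with pytest.raises(ValueError):
        fuse([Tensor(rng.normal(size=(4, 512))),
              Tensor(rng.normal(size=(4, 256)))])


def test_classify_matches_affine_oracle(rng):
    clf = Linear(6, 2, rng)
    x = rng.normal(size=(2, 6)).astype(np.float32)
    scores = classify(Tensor(x), clf).data
    expected = x @ clf.weight.data + clf.bias.data
    np.testing.assert_allclose(scores, expected, rtol=1e-6)
    with pytest.raises(ValueError):
        classify(Tensor(rng.normal(size=(2, 5))), clf)


# ------------------------------------------------------------------- losses

def test_uniform_scores_give_log2_ce():
    scores = Tensor(np.zeros((6, 2)))
    labels = np.array([0, 1, 0, 1, 1, 0])
    _, breakdown = total_loss(scores, labels, None)
    assert breakdown.ce == pytest.approx(math.log(2), rel=1e-6)
    assert breakdown.total == breakdown.ce


def test_confident_correct_scores_drive_ce_to_zero():
    scores = np.zeros((4, 2))
    labels = np.array([0, 1, 1, 0])
    scores[np.arange(4), labels] = 30.0
    _, breakdown = total_loss(Tensor(scores), labels, None)
    assert breakdown.ce < 1e-6


def test_total_decomposes_exactly(rng):
    from lnmfusion.contrastive import ProjectionBundle, combined_contrastive
    scores = Tensor(rng.normal(size=(5, 2)))
    labels = rng.integers(0, 2, size=5)
    proj = ProjectionBundle(z_ct=Tensor(rng.normal(size=(5, 16))),
                            z_us=Tensor(rng.normal(size=(5, 16))),
                            z_clin=Tensor(rng.normal(size=(5, 16))))
    con = combined_contrastive(proj)
    _, b = total_loss(scores, labels, con)
    assert b.total == pytest.approx(b.ce + b.contrastive, abs=1e-7)
    assert b.contrastive == pytest.approx(np.mean(list(b.pair_losses.values())),
                                          abs=1e-6)


def test_nonbinary_labels_rejected(rng):
    with pytest.raises(ValueError):
        total_loss(Tensor(rng.normal(size=(3, 2))), np.array([0, 1, 2]), None)


# -------------------------------------------------------------------- split

def test_split_127_gives_documented_sizes():
    cohort = generate_cohort(SyntheticParams(seed=7, n_patients=127,
                                             n_positive=16, image_size=8))
    split = split_cohort(cohort, seed=0)
    sizes = (len(split.train_ids), len(split.val_ids), len(split.test_ids))
    assert sizes == (102, 12, 13)


def test_split_is_deterministic_and_a_partition():
    cohort = generate_cohort(SyntheticParams(seed=9, n_patients=63,
                                             n_positive=9, image_size=8))
    s1 = split_cohort(cohort, seed=4)
    s2 = split_cohort(cohort, seed=4)
    assert (s1.train_ids, s1.val_ids, s1.test_ids) == \
           (s2.train_ids, s2.val_ids, s2.test_ids)
    all_ids = s1.train_ids + s1.val_ids + s1.test_ids
    assert sorted(all_ids) == list(range(63))


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_stratified_split_places_positives_everywhere(seed):
    cohort = generate_cohort(SyntheticParams(seed=seed, n_patients=127,
                                             n_positive=16, image_size=8))
    split = split_cohort(cohort, seed=seed)
    labels = cohort.labels
    for ids in (split.train_ids, split.val_ids, split.test_ids):
        assert labels[ids].sum() >= 1


def test_stratified_split_needs_three_positives():
    cohort = generate_cohort(SyntheticParams(seed=0, n_patients=40,
                                             n_positive=2, image_size=8))
    with pytest.raises(ValueError, match="positives"):
        split_cohort(cohort, seed=0)
    # unstratified mode has no such requirement
    split_cohort(cohort, seed=0, stratified=False)


def test_single_class_cohort_rejected():
    cohort = generate_cohort(SyntheticParams(seed=0, n_patients=20,
                                             n_positive=0, image_size=8))
    with pytest.raises(ValueError, match="both classes"):
        split_cohort(cohort, seed=0)


# ------------------------------------------------------------------ sampler

def test_inverse_frequency_weights_worked_example():
    labels = np.array([1] * 16 + [0] * 86)
    w = sampler_weights(labels)
    assert w.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(w[:16], (1 / 16) / 2)
    np.testing.assert_allclose(w[16:], (1 / 86) / 2)


def test_balanced_classes_give_uniform_weights():
    w = sampler_weights(np.array([0, 1] * 10))
    np.testing.assert_allclose(w, 1 / 20)


def test_single_class_sampler_rejected():
    with pytest.raises(ValueError):
        sampler_weights(np.ones(10, dtype=int))


def test_weighted_batches_balanced_in_expectation():
    labels = np.array([1] * 16 + [0] * 86)
    w = sampler_weights(labels)
    rng = np.random.default_rng(0)
    draws = rng.choice(len(labels), size=(10_000, 8), replace=True, p=w)
    frac = labels[draws].mean()
    assert abs(frac - 0.5) < 0.02


# ----------------------------------------------------------------- training

def test_one_epoch_smoke_run(small_cohort, smoke_checkpoint):
    ckpt, split = smoke_checkpoint
    assert ckpt.best_epoch in (0, 1)
    assert len(ckpt.history) == 2
    for entry in ckpt.history:
        assert entry["total"] == pytest.approx(
            entry["ce"] + entry["contrastive"], abs=1e-5)
        assert entry["contrastive"] == pytest.approx(
            np.mean(list(entry["pair_losses"].values())), abs=1e-5)
    test_records = [small_cohort.records[i] for i in split.test_ids]
    metrics = evaluate_checkpoint(ckpt, test_records)
    assert set(metrics) == {"ACC", "SE", "SP", "AUC"}


def test_checkpoint_comes_from_best_val_epoch(smoke_checkpoint):
    """Reported weights belong to the epoch maximizing validation
    accuracy, earliest on ties — never simply the last epoch."""
    ckpt, _ = smoke_checkpoint
    accs = [h["val_acc"] for h in ckpt.history]
    assert ckpt.best_epoch == int(np.argmax(accs))


def test_training_reproducible_and_bounds_from_train_only(
        small_cohort, test_encoder_config):
    split = split_cohort(small_cohort, seed=1)
    cfg = TrainConfig(epochs=1, seed=5)
    c1 = train(small_cohort, split, cfg, test_encoder_config,
               ContrastiveConfig())
    c2 = train(small_cohort, split, cfg, test_encoder_config,
               ContrastiveConfig())
    assert [h["val_acc"] for h in c1.history] == \
           [h["val_acc"] for h in c2.history]
    for k in c1.state:
        np.testing.assert_array_equal(c1.state[k], c2.state[k])
    train_records = [small_cohort.records[i] for i in split.train_ids]
    np.testing.assert_array_equal(
        c1.bounds, fit_normalizer(clinical_matrix(train_records,
                                                  c1.feature_names)))


def test_single_modality_and_no_contrastive_modes(small_cohort,
                                                  test_encoder_config):
    split = split_cohort(small_cohort, seed=2)
    ckpt = train(small_cohort, split, TrainConfig(epochs=1, seed=0),
                 test_encoder_config, ContrastiveConfig(),
                 modalities=("clinical",), use_contrastive=False)
    assert ckpt.state["classifier.weight"].shape == (512, 2)
    assert all(h["contrastive"] == 0.0 for h in ckpt.history)
    with pytest.raises(ValueError, match=">= 2 modalities"):
        train(small_cohort, split, TrainConfig(epochs=1),
              test_encoder_config, ContrastiveConfig(),
              modalities=("ct",), use_contrastive=True)


def test_checkpoint_round_trip(tmp_path, small_cohort, smoke_checkpoint):
    ckpt, split = smoke_checkpoint
    path = save_checkpoint(ckpt, tmp_path / "ckpt.npz")
    loaded = load_checkpoint(path)
    records = [small_cohort.records[i] for i in split.test_ids]
    np.testing.assert_allclose(predict_scores(loaded, records),
                               predict_scores(ckpt, records), atol=1e-7)
    assert loaded.best_epoch == ckpt.best_epoch
    assert loaded.feature_names == ckpt.feature_names
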