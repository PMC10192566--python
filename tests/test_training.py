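"""Loss oracles, fold mechanics, determinism and leakage protection."""

import copy
import math

import numpy as np
import pytest

from seizefuse import loocv, train_fold
from seizefuse.autodiff import Tensor, gradient_reversal
from seizefuse.networks import Head
from seizefuse.nnet import Adam, Linear
from seizefuse.training import (TrainConfig, classifier_loss, cross_entropy,
                                discriminator_losses, total_loss)


# -- loss oracles -------------------------------------------------------------

def test_perfect_one_hot_predictions_give_near_zero_loss():
    p = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert float(classifier_loss(p, [0, 1]).data) <= 1e-6


def test_uniform_predictions_give_ln2():
    p = np.full((7, 2), 0.5)
    y = [0, 1, 0, 1, 1, 0, 0]
    assert float(classifier_loss(p, y).data) == pytest.approx(math.log(2),
                                                              rel=1e-9)


def test_hand_computed_two_sample_batch():
    p = np.array([[0.9, 0.1], [0.2, 0.8]])
    expected = -(math.log(0.9) + math.log(0.8)) / 2
    assert float(classifier_loss(p, [0, 1]).data) == pytest.approx(
        expected, rel=1e-9)
    assert expected == pytest.approx(0.164252, abs=1e-6)


@pytest.mark.parametrize("k", [2, 3, 5])
def test_uniform_discriminator_outputs_give_ln_k(k):
    p = np.full((6, k), 1.0 / k)
    d = np.arange(6) % k
    l1, l2 = discriminator_losses(p, p, d)
    assert float(l1.data) == pytest.approx(math.log(k), rel=1e-10)
    assert float(l2.data) == pytest.approx(math.log(k), rel=1e-10)


def test_discriminator_hand_batch():
    p_eeg = np.array([[0.7, 0.2, 0.1], [0.1, 0.6, 0.3]])
    p_ecg = np.array([[0.5, 0.25, 0.25], [0.2, 0.2, 0.6]])
    d = [0, 1]
    l1, l2 = discriminator_losses(p_eeg, p_ecg, d)
    assert float(l1.data) == pytest.approx(-(math.log(0.7) + math.log(0.6)) / 2)
    assert float(l2.data) == pytest.approx(-(math.log(0.5) + math.log(0.2)) / 2)


def test_total_loss_affine_combination():
    assert total_loss(1.0, 0.5, 0.5, 0.1) == pytest.approx(0.9)
    assert total_loss(1.7, 9.9, 3.3, 0.0) == pytest.approx(1.7)
    assert total_loss(0.0, 0.0, 0.0, 0.1) == 0.0
    out = total_loss(Tensor(np.array(2.0)), Tensor(np.array(1.0)),
                     Tensor(np.array(3.0)), 0.25)
    assert float(out.data) == pytest.approx(1.0)


# -- adversarial direction on a toy problem -----------------------------------

def test_reversal_step_opposes_episode_discrimination(rng):
    """From identical initializations, a single optimization step with the
    reversal layer lowers the discriminator's loss *less* than the no-GRL
    control: the features move against, not toward, episode separation."""
    n, dim = 60, 2
    x = np.vstack([rng.normal(-1, 1, (n // 2, dim)),
                   rng.normal(+1, 1, (n // 2, dim))])
    d = np.repeat([0, 1], n // 2)

    def one_step(with_reversal, steps=1):
        feat = Linear(dim, 4, np.random.default_rng(0))
        disc = Head(4, 8, 2, np.random.default_rng(1), dropout=0.0)
        opt = Adam(feat.parameters() + disc.parameters(), lr=0.01)
        for _ in range(steps):
            h = feat(Tensor(x)).tanh()
            if with_reversal:
                h = gradient_reversal(h, 1.0)
            loss = cross_entropy(disc(h), d)
            opt.zero_grad()
            loss.backward()
            opt.step()
        return float(cross_entropy(disc(feat(Tensor(x)).tanh()), d).data)

    for steps in (1, 5, 20):
        assert one_step(True, steps) > one_step(False, steps)


# -- fold mechanics -----------------------------------------------------------

def test_loocv_produces_one_fold_per_episode(tiny_dataset, tiny_train_cfg,
                                             branch_cfg):
    reports, summary, results = loocv(tiny_dataset, tiny_train_cfg, branch_cfg)
    assert [r.held_out_episode for r in reports] == [0, 1, 2]
    assert summary["n_folds"] == 3
    # perfect test partition: every segment tested exactly once
    total = sum(r.counts.total for r in reports)
    assert total == tiny_dataset.n_segments
    for res in results:
        mask = tiny_dataset.d == res.held_out_episode
        assert len(res.y_true) == int(mask.sum())
        assert np.array_equal(res.y_true, tiny_dataset.y[mask])


def test_loocv_refuses_fewer_than_three_episodes(tiny_dataset, tiny_train_cfg,
                                                 branch_cfg):
    two = tiny_dataset.subset(tiny_dataset.d < 2)
    with pytest.raises(ValueError, match="at least 3 episodes"):
        loocv(two, tiny_train_cfg, branch_cfg)


def test_single_class_training_fold_is_rejected(tiny_dataset, tiny_train_cfg,
                                                branch_cfg):
    only_inter = tiny_dataset.subset(tiny_dataset.y == 0)
    with pytest.raises(ValueError, match="single class"):
        train_fold(only_inter, 0, tiny_train_cfg, branch_cfg)


def test_missing_episode_is_rejected(tiny_dataset, tiny_train_cfg, branch_cfg):
    with pytest.raises(ValueError, match="episode 9"):
        train_fold(tiny_dataset, 9, tiny_train_cfg, branch_cfg)


def test_train_fold_is_deterministic(tiny_dataset, tiny_train_cfg, branch_cfg):
    a = train_fold(tiny_dataset, 0, tiny_train_cfg, branch_cfg)
    b = train_fold(tiny_dataset, 0, tiny_train_cfg, branch_cfg)
    assert np.array_equal(a.p_fused, b.p_fused)
    assert a.weights == b.weights
    assert a.history == b.history


def test_extreme_lambda_remains_finite(tiny_dataset, branch_cfg):
    cfg = TrainConfig(epochs=2, batch_size=16, lr=0.003, seed=3,
                      lambda_adv=10.0)
    res = train_fold(tiny_dataset, 1, cfg, branch_cfg)
    assert np.all(np.isfinite(res.p_fused))
    assert all(np.isfinite(h["L_c"]) for h in res.history)


def test_center_loss_variant_runs_and_stays_finite(tiny_dataset, branch_cfg):
    cfg = TrainConfig(epochs=2, batch_size=16, lr=0.003, seed=3,
                      center_loss=True)
    res = train_fold(tiny_dataset, 0, cfg, branch_cfg)
    assert np.all(np.isfinite(res.p_fused))


@pytest.mark.parametrize("mode", ["data", "feature"])
def test_ablation_fusion_modes_run_end_to_end(tiny_dataset, branch_cfg, mode):
    cfg = TrainConfig(epochs=2, batch_size=16, lr=0.003, seed=3,
                      fusion_mode=mode)
    res = train_fold(tiny_dataset, 2, cfg, branch_cfg)
    assert res.weights is None and res.p_eeg is None
    assert res.p_fused.shape == (len(res.y_true), 2)
    assert np.allclose(res.p_fused.sum(axis=1), 1.0)


def test_learned_weight_variant_produces_normalized_weights(tiny_dataset,
                                                            branch_cfg):
    cfg = TrainConfig(epochs=2, batch_size=16, lr=0.003, seed=3,
                      weight_mode="learned")
    res = train_fold(tiny_dataset, 0, cfg, branch_cfg)
    assert res.weights.W1 + res.weights.W2 == pytest.approx(1.0)


def test_fixed_weight_mode_uses_half_half(tiny_dataset, branch_cfg):
    cfg = TrainConfig(epochs=2, batch_size=16, lr=0.003, seed=3,
                      weight_mode="fixed")
    res = train_fold(tiny_dataset, 0, cfg, branch_cfg)
    assert res.weights.W1 == res.weights.W2 == 0.5


def test_config_validation_errors():
    with pytest.raises(ValueError, match="lambda_adv"):
        TrainConfig(lambda_adv=-1.0).validate()
    with pytest.raises(ValueError, match="epochs"):
        TrainConfig(epochs=0).validate()
    with pytest.raises(ValueError, match="validation_fraction"):
        TrainConfig(validation_fraction=1.5).validate()
    with pytest.raises(ValueError, match="weight_mode"):
        TrainConfig(weight_mode="sideways").validate()


def test_held_out_episode_never_influences_training(tiny_dataset,
                                                    tiny_train_cfg, branch_cfg):
    """Sentinel leakage check: corrupting the test episode's signals must
    leave the trained parameters and the whole training history untouched."""
    poisoned = copy.deepcopy(tiny_dataset)
    mask = poisoned.d == 1
    poisoned.eeg[mask] = 1e6
    poisoned.scalogram[mask] = -1e6
    poisoned.ecg[mask] = 1e6

    clean = train_fold(tiny_dataset, 1, tiny_train_cfg, branch_cfg)
    dirty = train_fold(poisoned, 1, tiny_train_cfg, branch_cfg)

    assert clean.history == dirty.history
    assert clean.weights == dirty.weights
    for pa, pb in zip(clean.model.parameters(), dirty.model.parameters()):
        assert np.array_equal(pa.data, pb.data)
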