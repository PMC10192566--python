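"""Reusable scaled-down experiment protocols.

Each function runs a complete multi-seed experiment on synthetic patients
at the scaled study conditions (see :mod:`seizefuse.presets`) and returns
plain dictionaries of measured quantities.  They are the building blocks
behind the benchmark scripts and the heavier end of the test suite:

* :func:`adversarial_experiment` — episode-adversarial training (lambda =
  0.1) against the lambda = 0 control, paired over seeds, with linear
  probes of episode information left in the frozen features.
* :func:`fusion_experiment` — decision-level fusion against each single
  branch, and error-rate (dynamic) weights against fixed 0.5/0.5 weights
  when one branch is deliberately degraded.
* :func:`null_experiment` — zero-effect recordings: held-out accuracy
  should be statistically indistinguishable from coin flipping and the
  false alarm rate should match the overall predicted-positive rate.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from . import presets
from .autodiff import Tensor
from .evaluation import false_alarm_rate
from .fusion import fixed_weights, fuse_decisions, predict_classes
from .preprocessing import EpisodeDataset, build_dataset
from .synthetic import generate_patient
from .training import loocv, train_fold

__all__ = ["adversarial_experiment", "fusion_experiment", "null_experiment"]


def _features(model, ds: EpisodeDataset, chunk: int = 256):
    """Frozen per-modality features of a decision-level model."""
    model.eval()
    f1 = np.concatenate([model.gf1(Tensor(ds.eeg[i:i + chunk])).data
                         for i in range(0, ds.n_segments, chunk)])
    f2 = np.concatenate([model.gf2(Tensor(ds.scalogram[i:i + chunk])).data
                         for i in range(0, ds.n_segments, chunk)])
    model.train()
    return f1, f2


def _linear_probe(features: np.ndarray, d: np.ndarray, seed: int) -> float:
    """Held-out accuracy of a linear episode probe on frozen features."""
    idx = np.arange(len(d))
    tr, te = train_test_split(idx, test_size=0.3, random_state=seed,
                              stratify=d)
    clf = LogisticRegression(max_iter=1000).fit(features[tr], d[tr])
    return float(clf.score(features[te], d[te]))


def adversarial_experiment(seeds, lambda_adv: float = 0.1,
                           progress=None) -> dict:
    """Paired comparison: episode-adversarial training vs plain training.

    For every seed, one synthetic patient is generated at the scaled
    study conditions, and full leave-one-episode-out evaluation is run
    twice from identical initializations — once with the adversarial term
    (lambda = lambda_adv) and once without it.  Episode-probe accuracies
    are averaged over folds and the two modalities.
    """
    seeds = list(seeds)
    pre = presets.scaled_preprocess()
    bc = presets.scaled_branch()
    acc_adv, acc_ctl, probe_adv, probe_ctl = [], [], [], []
    for seed in seeds:
        spec = presets.scaled_synthetic_spec(seed)
        ds = build_dataset(generate_patient(spec), pre)
        for arm, no_adv in (("adv", False), ("ctl", True)):
            cfg = presets.scaled_train(seed, lambda_adv=lambda_adv,
                                       no_adversarial=no_adv)
            _, summary, results = loocv(ds, cfg, bc)
            probes = []
            for res in results:
                train_part = ds.subset(ds.d != res.held_out_episode)
                f1, f2 = _features(res.model, train_part)
                probes.append(_linear_probe(f1, train_part.d, seed))
                probes.append(_linear_probe(f2, train_part.d, seed))
            if arm == "adv":
                acc_adv.append(summary["acc"]["mean"])
                probe_adv.append(float(np.mean(probes)))
            else:
                acc_ctl.append(summary["acc"]["mean"])
                probe_ctl.append(float(np.mean(probes)))
        if progress:
            progress(seed)
    # two training episodes per fold -> probe chance level is 1/2
    t = stats.ttest_rel(acc_adv, acc_ctl, alternative="greater")
    return {
        "seeds": seeds,
        "acc_adversarial": acc_adv,
        "acc_control": acc_ctl,
        "mean_acc_adversarial": float(np.mean(acc_adv)),
        "mean_acc_control": float(np.mean(acc_ctl)),
        "paired_t_pvalue": float(t.pvalue),
        "probe_adversarial": float(np.mean(probe_adv)),
        "probe_control": float(np.mean(probe_ctl)),
        "probe_chance": 0.5,
    }


def fusion_experiment(seeds, progress=None) -> dict:
    """Decision-level fusion vs single branches, dynamic vs fixed weights.

    Part A (complementary signal, both modalities informative): per seed,
    one held-out episode; fused accuracy is compared with each branch's.
    Part B (degraded EEG branch): the same fold is evaluated under the
    error-rate weights and under fixed 0.5/0.5 weights.
    """
    seeds = list(seeds)
    pre = presets.scaled_preprocess()
    bc = presets.scaled_branch()
    fused, br_eeg, br_ecg = [], [], []
    for seed in seeds:
        spec = presets.scaled_synthetic_spec(seed, episode_shift=1.5,
                                             eeg_effect=3.0, ecg_effect=1.2)
        ds = build_dataset(generate_patient(spec), pre)
        res = train_fold(ds, seed % 3, presets.scaled_train(seed), bc)
        fused.append(res.accuracy)
        br_eeg.append(float(np.mean(predict_classes(res.p_eeg) == res.y_true)))
        br_ecg.append(float(np.mean(predict_classes(res.p_ecg) == res.y_true)))
        if progress:
            progress(seed)

    dyn, fix = [], []
    for seed in seeds:
        spec = presets.scaled_synthetic_spec(seed, episode_shift=2.5,
                                             eeg_effect=0.6, ecg_effect=2.5)
        ds = build_dataset(generate_patient(spec), pre)
        res = train_fold(ds, seed % 3, presets.scaled_train(seed), bc)
        dyn.append(res.accuracy)
        p_fixed = fuse_decisions(res.p_eeg, res.p_ecg, fixed_weights())
        fix.append(float(np.mean(predict_classes(p_fixed) == res.y_true)))
        if progress:
            progress(seed)
    return {
        "seeds": seeds,
        "mean_acc_fused": float(np.mean(fused)),
        "mean_acc_eeg_branch": float(np.mean(br_eeg)),
        "mean_acc_ecg_branch": float(np.mean(br_ecg)),
        "mean_acc_dynamic_weights": float(np.mean(dyn)),
        "mean_acc_fixed_weights": float(np.mean(fix)),
    }


def null_experiment(seeds) -> dict:
    """Zero-effect recordings: accuracy CI and FAR vs positive rate."""
    seeds = list(seeds)
    pre = presets.scaled_preprocess()
    bc = presets.scaled_branch()
    correct = total = alarms = interictal = positives = 0
    for seed in seeds:
        spec = presets.scaled_synthetic_spec(seed, eeg_effect=0.0,
                                             ecg_effect=0.0, episode_shift=1.0)
        ds = build_dataset(generate_patient(spec), pre)
        res = train_fold(ds, seed % 3, presets.scaled_train(seed), bc)
        correct += int(np.sum(res.y_pred == res.y_true))
        total += len(res.y_true)
        far, n_wo, n_alarm = false_alarm_rate(res.y_true, res.y_pred)
        alarms += n_alarm
        interictal += n_wo
        positives += int(np.sum(res.y_pred == 1))
    lo, hi = stats.binomtest(correct, total).proportion_ci(0.95)
    return {
        "seeds": seeds,
        "accuracy": correct / total,
        "ci95": (float(lo), float(hi)),
        "far": alarms / interictal,
        "predicted_positive_rate": positives / total,
    }
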