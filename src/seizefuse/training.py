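"""Joint adversarial training and the leave-one-episode-out driver.

The objective couples three terms.  The classifier loss is the
cross-entropy of the *fused* prediction

    L_c = CE(W1 * G_c1(G_f1(x_eeg)) + W2 * G_c2(G_f2(x_ecg)), y),

and each modality carries an episode discriminator whose cross-entropy
losses L_d_eeg / L_d_ecg are attached to the feature extractors through a
gradient-reversal connector.  A single optimizer then minimizes

    L_sum = L_c - lambda * (L_d_eeg + L_d_ecg)

with respect to features and classifiers while the reversed gradient
maximizes the discriminator terms with respect to the features — the
discriminators themselves descend their own losses in the same backward
pass.  lambda defaults to 0.1; lambda = 0 (or ``no_adversarial``)
recovers the plain fused classifier.

Branch error rates come from a stratified validation split (20% of the
training segments); fusion weights are recomputed from them after every
epoch and the best-validation epoch's parameters and weights are kept.
Leave-one-episode-out cross-validation trains one such model per episode;
discriminator classes are always the *training* episodes of the current
fold, relabeled 0..K-1, so the held-out episode has no discriminator
class and never influences any training statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .autodiff import Tensor, concat, gradient_reversal
from .evaluation import FoldReport, aggregate, fold_report
from .fusion import FusionWeights, dynamic_weights, fixed_weights, fuse_decisions, predict_classes
from .networks import (BranchConfig, Head, build_discriminator,
                       build_ecg_branch, build_eeg_branch)
from .nnet import Adam, Module, SGD
from .preprocessing import EpisodeDataset

__all__ = [
    "TrainConfig", "FoldResult", "classifier_loss", "discriminator_losses",
    "cross_entropy", "total_loss", "train_fold", "loocv",
    "probe_episode_accuracy",
]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    lr: float = 0.001
    lambda_adv: float = 0.1
    grl_lambda: float = 1.0
    no_adversarial: bool = False
    weight_mode: str = "dynamic"    # dynamic | fixed | learned
    fusion_mode: str = "decision"   # decision | data | feature
    center_loss: bool = False
    center_loss_weight: float = 0.01
    center_loss_lr: float = 0.05
    validation_fraction: float = 0.2
    seed: int = 0
    #: weight of the per-branch auxiliary cross-entropies added to the
    #: fused loss; keeps each branch independently competent so its error
    #: rate (and hence its fusion weight) is meaningful.  0 disables.
    branch_loss_weight: float = 0.5
    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("TrainConfig.epochs must be >= 1")
        if self.lambda_adv < 0:
            raise ValueError("TrainConfig.lambda_adv must be >= 0")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("TrainConfig.validation_fraction must be in (0, 1)")
        if self.weight_mode not in ("dynamic", "fixed", "learned"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.fusion_mode not in ("decision", "data", "feature"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")

    @property
    def effective_lambda(self) -> float:
        return 0.0 if self.no_adversarial else self.lambda_adv


# -- loss primitives ----------------------------------------------------------

def _as_tensor(p) -> Tensor:
    return p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=float))


def cross_entropy(probs, labels) -> Tensor:
    """Mean cross-entropy of probability rows against integer labels."""
    p = _as_tensor(probs)
    labels = np.asarray(labels, dtype=int)
    return -((p.gather_rows(labels) + 1e-12).log().mean())


def classifier_loss(p_fused, y) -> Tensor:
    """L_c: cross-entropy of the fused probabilities against class labels."""
    return cross_entropy(p_fused, y)


def discriminator_losses(p_d_eeg, p_d_ecg, d) -> tuple[Tensor, Tensor]:
    """(L_d_eeg, L_d_ecg): per-modality episode cross-entropies."""
    return cross_entropy(p_d_eeg, d), cross_entropy(p_d_ecg, d)


def total_loss(l_c, l_d_eeg, l_d_ecg, lambda_adv: float):
    """L_sum = L_c - lambda * (L_d_eeg + L_d_ecg)."""
    if isinstance(l_c, Tensor) or isinstance(l_d_eeg, Tensor):
        return _as_tensor(l_c) - lambda_adv * (_as_tensor(l_d_eeg) + _as_tensor(l_d_ecg))
    return l_c - lambda_adv * (l_d_eeg + l_d_ecg)


# -- model assemblies ---------------------------------------------------------

class _DecisionModel(Module):
    """Two independent branches fused at the decision level."""

    def __init__(self, bc: BranchConfig, shapes: dict, rng, adversarial: bool,
                 learned_weights: bool):
        self.gf1, self.gc1 = build_eeg_branch(bc, shapes["n_channels"],
                                              shapes["window"], rng)
        self.gf2, self.gc2 = build_ecg_branch(bc, shapes["n_scales"],
                                              shapes["scal_w"], rng)
        self.gd1 = build_discriminator(bc, rng) if adversarial else None
        self.gd2 = build_discriminator(bc, rng) if adversarial else None
        self.w_theta = Tensor(np.zeros(2), requires_grad=True) if learned_weights else None

    def branch_probs(self, x_eeg: Tensor, x_scal: Tensor):
        f1 = self.gf1(x_eeg)
        f2 = self.gf2(x_scal)
        return self.gc1(f1), self.gc2(f2), f1, f2

    def learned_w(self) -> np.ndarray:
        e = np.exp(self.w_theta.data - self.w_theta.data.max())
        return e / e.sum()


class _DataLevelModel(Module):
    """ECG stacked as an extra channel into a single EEG-type branch."""

    def __init__(self, bc: BranchConfig, shapes: dict, rng, adversarial: bool):
        self.gf, self.gc = build_eeg_branch(bc, shapes["n_channels"] + 1,
                                            shapes["window"], rng)
        self.gd = build_discriminator(bc, rng) if adversarial else None


class _FeatureLevelModel(Module):
    """Both extractors feed one classifier on the concatenated feature."""

    def __init__(self, bc: BranchConfig, shapes: dict, rng, adversarial: bool):
        self.gf1, _ = build_eeg_branch(bc, shapes["n_channels"],
                                       shapes["window"], rng)
        self.gf2, _ = build_ecg_branch(bc, shapes["n_scales"],
                                       shapes["scal_w"], rng)
        self.gc = Head(2 * bc.feature_dim, bc.fc_sizes[0], bc.n_classes, rng,
                       bc.dropout)
        self.gd1 = build_discriminator(bc, rng) if adversarial else None
        self.gd2 = build_discriminator(bc, rng) if adversarial else None


@dataclass
class FoldResult:
    held_out_episode: int
    weights: FusionWeights | None
    y_true: np.ndarray
    y_pred: np.ndarray
    p_fused: np.ndarray
    p_eeg: np.ndarray | None
    p_ecg: np.ndarray | None
    history: list[dict]
    model: Module
    err1: float | None = None
    err2: float | None = None

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_pred == self.y_true))


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for a in range(0, n, batch_size):
        yield order[a:a + batch_size]


def _predict_decision(model: _DecisionModel, ds: EpisodeDataset,
                      chunk: int = 512):
    model.eval()
    p1s, p2s, f1s, f2s = [], [], [], []
    for a in range(0, ds.n_segments, chunk):
        sl = slice(a, a + chunk)
        p1, p2, f1, f2 = model.branch_probs(Tensor(ds.eeg[sl]),
                                            Tensor(ds.scalogram[sl]))
        p1s.append(p1.data)
        p2s.append(p2.data)
        f1s.append(f1.data)
        f2s.append(f2.data)
    model.train()
    return (np.concatenate(p1s), np.concatenate(p2s),
            np.concatenate(f1s), np.concatenate(f2s))


def _predict_single(forward, n: int, chunk: int = 512):
    outs = []
    for a in range(0, n, chunk):
        outs.append(forward(slice(a, a + chunk)))
    return np.concatenate(outs)


def _center_loss(features: Tensor, centers: Tensor, y: np.ndarray) -> Tensor:
    onehot = np.zeros((len(y), centers.data.shape[0]))
    onehot[np.arange(len(y)), y] = 1.0
    c_y = Tensor(onehot) @ centers
    diff = features - c_y
    return 0.5 * (diff * diff).sum(axis=1).mean()


def _weights_from_mode(cfg: TrainConfig, err1: float, err2: float,
                       model) -> FusionWeights:
    if cfg.weight_mode == "dynamic":
        return dynamic_weights(err1, err2)
    if cfg.weight_mode == "fixed":
        return fixed_weights()
    w = model.learned_w()
    return FusionWeights(err1, err2, float(w[0]), float(w[1]),
                         float(w[0]), float(w[1]))


def train_fold(dataset: EpisodeDataset, held_out_episode: int,
               cfg: TrainConfig, branch_cfg: BranchConfig | None = None) -> FoldResult:
    """Train on all episodes except one; predict the held-out episode."""
    cfg.validate()
    bc = branch_cfg or BranchConfig()
    test_mask = dataset.d == held_out_episode
    if not test_mask.any():
        raise ValueError(f"episode {held_out_episode} not present in dataset")
    train_ds = dataset.subset(~test_mask)
    test_ds = dataset.subset(test_mask)

    train_eps = np.unique(train_ds.d)
    if len(np.unique(train_ds.y)) < 2:
        raise ValueError("training fold contains a single class; "
                         "cannot fit a classifier")
    relabel = {ep: k for k, ep in enumerate(train_eps)}
    d_rel = np.array([relabel[e] for e in train_ds.d])
    n_eps = len(train_eps)

    import dataclasses
    bc = dataclasses.replace(bc, n_episode_classes=n_eps)
    seq = np.random.SeedSequence([cfg.seed, int(held_out_episode)])
    init_ss, shuffle_ss, split_ss = seq.spawn(3)
    init_rng = np.random.default_rng(init_ss)
    shuffle_rng = np.random.default_rng(shuffle_ss)

    # stratify jointly on class and episode so both are represented in
    # the validation split used for error-rate weighting
    strat = train_ds.y * n_eps + d_rel
    idx = np.arange(train_ds.n_segments)
    counts = np.bincount(strat)
    strat_key = strat if counts.min() >= 2 else train_ds.y
    tr_idx, val_idx = train_test_split(
        idx, test_size=cfg.validation_fraction,
        random_state=int(split_ss.generate_state(1)[0] % (2 ** 31)),
        stratify=strat_key)
    fit_ds, val_ds = train_ds.subset(tr_idx), train_ds.subset(val_idx)
    d_fit, d_val = d_rel[tr_idx], d_rel[val_idx]

    shapes = {"n_channels": dataset.eeg.shape[1], "window": dataset.eeg.shape[2],
              "n_scales": dataset.scalogram.shape[1],
              "scal_w": dataset.scalogram.shape[2]}
    lam = cfg.effective_lambda
    adversarial = lam > 0

    if cfg.fusion_mode == "decision":
        model = _DecisionModel(bc, shapes, init_rng, adversarial,
                               cfg.weight_mode == "learned")
    elif cfg.fusion_mode == "data":
        model = _DataLevelModel(bc, shapes, init_rng, adversarial)
    else:
        model = _FeatureLevelModel(bc, shapes, init_rng, adversarial)

    opt = Adam(model.parameters(), lr=cfg.lr)
    centers = center_opt = None
    if cfg.center_loss and cfg.fusion_mode == "decision":
        centers = [Tensor(np.zeros((bc.n_classes, bc.feature_dim)), requires_grad=True)
                   for _ in range(2)]
        center_opt = SGD(centers, lr=cfg.center_loss_lr)

    weights = fixed_weights()  # epoch-0 starting point
    history: list[dict] = []
    # best epoch = lowest fused validation error; ties broken by the sum
    # of branch errors so both branches stay competent in the snapshot
    best = {"key": (math.inf, math.inf), "state": None, "weights": weights,
            "err1": 0.5, "err2": 0.5}

    for epoch in range(cfg.epochs):
        ep_lc = ep_ld1 = ep_ld2 = 0.0
        n_batches = 0
        for sel in _batches(fit_ds.n_segments, cfg.batch_size, shuffle_rng):
            y = fit_ds.y[sel]
            d = d_fit[sel]
            if cfg.fusion_mode == "decision":
                p1, p2, f1, f2 = model.branch_probs(Tensor(fit_ds.eeg[sel]),
                                                    Tensor(fit_ds.scalogram[sel]))
                if cfg.weight_mode == "learned":
                    from .autodiff import softmax as _softmax
                    wt = _softmax(model.w_theta.reshape(1, 2))
                    fused = (wt.narrow(1, 0, 1) * p1 + wt.narrow(1, 1, 1) * p2)
                else:
                    fused = weights.W1 * p1 + weights.W2 * p2
                l_c = classifier_loss(fused, y)
                graph = l_c
                if cfg.branch_loss_weight > 0:
                    graph = graph + cfg.branch_loss_weight * (
                        cross_entropy(p1, y) + cross_entropy(p2, y))
                l_d1 = l_d2 = None
                if adversarial:
                    # canonical domain-adversarial coupling: the
                    # discriminators descend their full-strength losses
                    # while the reversal layer scales the confusion
                    # gradient reaching the features by -lambda
                    pd1 = model.gd1(gradient_reversal(f1, lam * cfg.grl_lambda))
                    pd2 = model.gd2(gradient_reversal(f2, lam * cfg.grl_lambda))
                    l_d1, l_d2 = discriminator_losses(pd1, pd2, d)
                    graph = graph + (l_d1 + l_d2)
                if centers is not None:
                    graph = graph + cfg.center_loss_weight * (
                        _center_loss(f1, centers[0], y)
                        + _center_loss(f2, centers[1], y))
            elif cfg.fusion_mode == "data":
                stacked = np.concatenate([fit_ds.eeg[sel],
                                          fit_ds.ecg[sel][:, None, :]], axis=1)
                f = model.gf(Tensor(stacked))
                l_c = classifier_loss(model.gc(f), y)
                graph, l_d1, l_d2 = l_c, None, None
                if adversarial:
                    pd = model.gd(gradient_reversal(f, lam * cfg.grl_lambda))
                    l_d1 = cross_entropy(pd, d)
                    graph = graph + l_d1
            else:  # feature-level
                f1 = model.gf1(Tensor(fit_ds.eeg[sel]))
                f2 = model.gf2(Tensor(fit_ds.scalogram[sel]))
                l_c = classifier_loss(model.gc(concat([f1, f2], axis=-1)), y)
                graph, l_d1, l_d2 = l_c, None, None
                if adversarial:
                    pd1 = model.gd1(gradient_reversal(f1, lam * cfg.grl_lambda))
                    pd2 = model.gd2(gradient_reversal(f2, lam * cfg.grl_lambda))
                    l_d1, l_d2 = discriminator_losses(pd1, pd2, d)
                    graph = graph + (l_d1 + l_d2)

            opt.zero_grad()
            if center_opt is not None:
                center_opt.zero_grad()
            graph.backward()
            opt.step()
            if center_opt is not None:
                center_opt.step()
            ep_lc += float(l_c.data)
            ep_ld1 += float(l_d1.data) if l_d1 is not None else 0.0
            ep_ld2 += float(l_d2.data) if l_d2 is not None else 0.0
            n_batches += 1

        # -- end of epoch: validation errors and fusion weights ---------------
        if cfg.fusion_mode == "decision":
            p1v, p2v, _, _ = _predict_decision(model, val_ds)
            err1 = float(np.mean(predict_classes(p1v) != val_ds.y))
            err2 = float(np.mean(predict_classes(p2v) != val_ds.y))
            weights = _weights_from_mode(cfg, err1, err2, model)
            fused_v = fuse_decisions(p1v, p2v, weights)
        else:
            err1 = err2 = float("nan")
            weights = None
            fused_v = _predict_eval(model, cfg, val_ds)
        val_err = float(np.mean(predict_classes(fused_v) != val_ds.y))
        history.append({
            "epoch": epoch, "L_c": ep_lc / n_batches,
            "L_d_eeg": ep_ld1 / n_batches, "L_d_ecg": ep_ld2 / n_batches,
            "err1": err1, "err2": err2,
            "W1": weights.W1 if weights else math.nan,
            "W2": weights.W2 if weights else math.nan,
            "val_err": val_err,
        })
        key = (val_err, (err1 + err2) if cfg.fusion_mode == "decision" else 0.0)
        # <= : among equally validating epochs keep the latest snapshot,
        # whose features have seen the most training
        if key <= best["key"]:
            best = {"key": key, "state": model.state(), "weights": weights,
                    "err1": err1, "err2": err2}

    if best["state"] is not None:
        model.load_state(best["state"])
    weights = best["weights"]

    # -- held-out predictions -------------------------------------------------
    if cfg.fusion_mode == "decision":
        p1t, p2t, _, _ = _predict_decision(model, test_ds)
        p_fused = fuse_decisions(p1t, p2t, weights)
    else:
        p1t = p2t = None
        p_fused = _predict_eval(model, cfg, test_ds)
    y_pred = predict_classes(p_fused)
    return FoldResult(held_out_episode, weights, test_ds.y, y_pred, p_fused,
                      p1t, p2t, history, model,
                      err1=best["err1"], err2=best["err2"])


def _predict_eval(model, cfg: TrainConfig, ds: EpisodeDataset) -> np.ndarray:
    model.eval()
    if cfg.fusion_mode == "data":
        def fwd(sl):
            stacked = np.concatenate([ds.eeg[sl], ds.ecg[sl][:, None, :]], axis=1)
            return model.gc(model.gf(Tensor(stacked))).data
    else:
        def fwd(sl):
            f1 = model.gf1(Tensor(ds.eeg[sl]))
            f2 = model.gf2(Tensor(ds.scalogram[sl]))
            return model.gc(concat([f1, f2], axis=-1)).data
    out = _predict_single(fwd, ds.n_segments)
    model.train()
    return out


def loocv(dataset: EpisodeDataset, cfg: TrainConfig,
          branch_cfg: BranchConfig | None = None):
    """One fold per episode.  Returns (fold_reports, summary, fold_results).

    Refuses patients with fewer than three episodes: with fewer than three
    preictal/interictal units per patient the folds overfit.
    """
    episodes = dataset.episodes
    if len(episodes) < 3:
        raise ValueError(
            f"leave-one-episode-out needs at least 3 episodes, got "
            f"{len(episodes)}; fewer preictal/interictal units overfit in training")
    reports, results = [], []
    for ep in sorted(int(e) for e in episodes):
        res = train_fold(dataset, ep, cfg, branch_cfg)
        results.append(res)
        reports.append(fold_report(dataset.patient_id, ep, res.y_true,
                                   res.y_pred))
    return reports, aggregate(reports), results


def probe_episode_accuracy(features: np.ndarray, d: np.ndarray, seed: int = 0,
                           epochs: int = 80, lr: float = 0.01,
                           hidden: int = 32) -> tuple[float, float]:
    """Train a fresh discriminator head on frozen features.

    Measures how episode-discriminable the feature space is: a 70/30
    stratified split, a two-layer head trained full-batch, held-out
    episode accuracy returned together with the chance level (majority
    episode share).  Adversarially trained features should land near
    chance; features trained without the adversarial term should not.
    """
    d = np.asarray(d, dtype=int)
    classes, d_rel = np.unique(d, return_inverse=True)
    idx = np.arange(len(d_rel))
    tr, te = train_test_split(idx, test_size=0.3, random_state=seed,
                              stratify=d_rel)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 997]))
    head = Head(features.shape[1], hidden, len(classes), rng, dropout=0.0)
    opt = Adam(head.parameters(), lr=lr)
    x_tr = Tensor(features[tr])
    for _ in range(epochs):
        loss = cross_entropy(head(x_tr), d_rel[tr])
        opt.zero_grad()
        loss.backward()
        opt.step()
    head.eval()
    pred = predict_classes(head(Tensor(features[te])).data)
    acc = float(np.mean(pred == d_rel[te]))
    chance = float(np.bincount(d_rel[te]).max() / len(te))
    return acc, chance
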