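"""Training regimes over the shared latent code.

Three regimes are supported, all sharing the encoder/classifier
architecture and seeding so they differ only in how the auxiliary report
text is used:

* ``baseline`` -- image-only: encoder + classifier, classification loss.
* ``m1`` -- two-stage: stage 1 trains encoder + decoder on report
  reconstruction alone; stage 2 trains the classifier on the (by default
  frozen) encoder's latents.
* ``m2`` -- joint: every step minimizes classification loss plus
  lambda-weighted reconstruction loss from the same latent code.

Reports are consumed at training time only; inference is image-only in
every regime.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict, field

import numpy as np
from sklearn.model_selection import KFold

from . import losses, metrics, text as textmod
from .manifest import DatasetManifest
from .models import (SharedLatentModel, EncoderConfig, DecoderConfig,
                     ClassifierConfig)
from . import nn
from .seeding import derive_seed, rng_for
from .synth import load_split


@dataclass
class TrainConfig:
    regime: str = "m2"                 # baseline | m1 | m2
    epochs: int = 30                   # per stage
    batch_size: int = 8
    learning_rate: float = 1e-4
    lam: float = 0.5                   # weight of the reconstruction loss
    loss: str = "cross-entropy"        # cross-entropy | focal
    focal_gamma: float = 2.0
    focal_alpha: str = "inverse-frequency"   # inverse-frequency | none
    seed: int = 0
    freeze_encoder_in_stage2: bool = True
    vocab_size: int = 300
    max_len: int = 40
    glove_window: int = 5
    glove_epochs: int = 60
    embedding_mode: str = "glove-finetune"  # glove-finetune | glove-frozen | scratch
    recon_step_reduction: str = "mean"      # mean | sum over sequence steps

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.regime not in ("baseline", "m1", "m2"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class TrainLog:
    rows: list = field(default_factory=list)

    def add(self, **kw):
        kw.setdefault("timestamp", time.time())
        self.rows.append(kw)

    def save(self, path):
        with open(path, "w") as fh:
            for row in self.rows:
                fh.write(json.dumps(row) + "\n")


class _TextBundle:
    """Vocabulary, padded teacher ids, one-hot targets and initial
    embeddings derived from the paired training reports."""

    def __init__(self, reports: list[str], cfg: TrainConfig):
        corpus = [textmod.tokenize(r) for r in reports]
        self.vocab = textmod.build_vocabulary(corpus, cfg.vocab_size)
        self.steps = min(cfg.max_len, max(len(t) for t in corpus))
        toks = [textmod.TokenizedReport(t[:self.steps],
                                        [self.vocab.id_of(x) for x in t[:self.steps]])
                for t in corpus]
        self.ids = np.stack([textmod.pad_ids(t, self.vocab, self.steps)
                             for t in toks])
        self.mask = np.stack([
            np.concatenate([np.ones(t.length), np.zeros(self.steps - t.length)])
            for t in toks])
        self.embeddings = None
        if cfg.embedding_mode.startswith("glove"):
            cooc = textmod.build_cooccurrence(corpus, self.vocab,
                                              window=cfg.glove_window,
                                              weighting="inverse-distance")
            if cooc.counts.sum() > 0:
                emb = textmod.fit_glove(cooc, d=128, epochs=cfg.glove_epochs,
                                        seed=derive_seed(cfg.seed, "glove"))
                self.embeddings = emb.vectors


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    return np.eye(k)[labels]


def _cls_grad(probs, onehot, cfg: TrainConfig, alpha):
    """Value and d(loss)/d(logits) of the configured classification loss."""
    B = probs.shape[0]
    if cfg.loss == "cross-entropy":
        val = losses.classifier_loss(probs, onehot)
        grad = (probs - onehot) / B
        return val, grad
    gamma = cfg.focal_gamma
    val = losses.focal_loss(probs, onehot, gamma, alpha)
    p_t = (probs * onehot).sum(axis=1, keepdims=True)
    a_t = ((onehot * alpha).sum(axis=1, keepdims=True)
           if alpha is not None else 1.0)
    p_t_c = np.clip(p_t, losses.EPS, None)
    dL_dpt = a_t * (gamma * (1 - p_t) ** (gamma - 1) * np.log(p_t_c)
                    - (1 - p_t) ** gamma / p_t_c)
    # d p_t / d logit_j = p_t (delta_tj - p_j)
    grad = dL_dpt * p_t * (onehot - probs) / B
    return val, grad


def _alpha_for(labels, cfg: TrainConfig, k=7):
    if cfg.loss != "focal" or cfg.focal_alpha == "none":
        return None
    counts = np.bincount(labels, minlength=k)
    return losses.inverse_frequency_alpha(counts)


def _accuracy(model, images, labels, batch=64):
    preds = []
    for i in range(0, len(images), batch):
        z = model.encode(images[i:i + batch])
        preds.append(model.classify(z).argmax(axis=1))
    return float((np.concatenate(preds) == labels).mean())


def _load_for_training(man: DatasetManifest, need_reports: bool):
    images, labels, reports = load_split(man, "train")
    if need_reports and any(r is None for r in reports):
        raise ValueError("regime requires a fully paired training split "
                         "(every record must carry a report)")
    val = man.split("val")
    val_data = load_split(man, "val")[:2] if len(val) else None
    return images, labels, reports, val_data


def _fit(model, data, cfg: TrainConfig, mode: str, log: TrainLog,
         stage: str, tb: _TextBundle | None = None):
    """Shared epoch loop.  ``mode``: 'cls' (baseline), 'recon' (m1 stage 1)
    or 'joint' (m2)."""
    images, labels, val_data = data
    n = len(images)
    onehot_all = _one_hot(labels, model.cls_cfg.classes)
    alpha = _alpha_for(labels, cfg)
    modules = [model.encoder]
    if mode in ("cls", "joint"):
        modules.append(model.classifier)
    if mode in ("recon", "joint"):
        modules.append(model.decoder)
    opt = nn.Adam(modules, lr=cfg.learning_rate)
    shuffle_rng = rng_for(cfg.seed, "shuffle")
    V = tb.vocab.size if tb is not None else 0
    for epoch in range(cfg.epochs):
        perm = shuffle_rng.permutation(n)
        tot = tot_cls = tot_rec = 0.0
        correct = 0
        for i in range(0, n, cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            x = images[idx]
            B = len(idx)
            opt.zero_grads()
            z = model.encode(x, train=True)
            dz = np.zeros_like(z)
            l_cls = l_rec = 0.0
            if mode in ("cls", "joint"):
                logits = model.classify(z, train=True)
                probs = nn.softmax(logits, axis=-1)
                l_cls, dlog = _cls_grad(probs, onehot_all[idx], cfg, alpha)
                correct += int((logits.argmax(1) == labels[idx]).sum())
                dz += model.classifier.backward(dlog.astype(z.dtype))
            if mode in ("recon", "joint"):
                ids = tb.ids[idx]
                m = tb.mask[idx]
                dprobs = model.decoder.forward(z, ids, train=True)
                tgt = np.eye(V)[ids]
                l_rec = losses.encoder_decoder_loss(
                    dprobs, tgt, m, cfg.recon_step_reduction)
                w = cfg.lam if mode == "joint" else 1.0
                if cfg.recon_step_reduction == "mean":
                    mw = m / np.maximum(m.sum(axis=1, keepdims=True), 1)
                else:
                    mw = m
                # scaling the logit gradient by w scales both the decoder
                # parameter grads and dz by lambda, matching the joint loss
                dlogits = (w * (dprobs - tgt) * mw[:, :, None] / B).astype(z.dtype)
                dz += model.decoder.backward(dlogits)
            model.encoder.backward(dz)
            opt.step()
            w = cfg.lam if mode == "joint" else (1.0 if mode == "recon" else 0.0)
            l_tot = l_cls + (w * l_rec if mode != "cls" else 0.0)
            tot += l_tot * B; tot_cls += l_cls * B; tot_rec += l_rec * B
        row = {"stage": stage, "epoch": epoch,
               "loss_total": tot / n, "seed": cfg.seed}
        if mode in ("cls", "joint"):
            row["loss_cls"] = tot_cls / n
            row["train_acc"] = correct / n
        if mode in ("recon", "joint"):
            row["loss_encdec"] = tot_rec / n
        if val_data is not None and mode != "recon":
            row["val_acc"] = _accuracy(model, *val_data)
        log.add(**row)
    return model


def train_baseline(man: DatasetManifest, cfg: TrainConfig,
                   enc_cfg: EncoderConfig | None = None,
                   cls_cfg: ClassifierConfig | None = None):
    """Image-only model: reports are never read."""
    enc_cfg = enc_cfg or EncoderConfig()
    cls_cfg = cls_cfg or ClassifierConfig()
    images, labels, _, val_data = _load_for_training(man, need_reports=False)
    if len(images) == 0:
        raise ValueError("empty training split")
    model = SharedLatentModel(enc_cfg, cls_cfg, None, cfg.seed)
    log = TrainLog()
    _fit(model, (images, labels, val_data), cfg, "cls", log, "baseline")
    return model, log


def _make_paired_model(man, cfg, enc_cfg, cls_cfg):
    images, labels, reports, val_data = _load_for_training(man, need_reports=True)
    if len(images) == 0:
        raise ValueError("empty training split")
    tb = _TextBundle(reports, cfg)
    dec_cfg = DecoderConfig(steps=tb.steps, vocab_size=tb.vocab.size,
                            train_embeddings=cfg.embedding_mode != "glove-frozen")
    emb = tb.embeddings if cfg.embedding_mode.startswith("glove") else None
    model = SharedLatentModel(enc_cfg, cls_cfg, dec_cfg, cfg.seed,
                              embeddings=emb)
    return model, tb, images, labels, val_data


def train_m1(man: DatasetManifest, cfg: TrainConfig,
             enc_cfg: EncoderConfig | None = None,
             cls_cfg: ClassifierConfig | None = None):
    """Two-stage: reconstruction first, then a classifier on the latents."""
    enc_cfg = enc_cfg or EncoderConfig()
    cls_cfg = cls_cfg or ClassifierConfig()
    model, tb, images, labels, val_data = _make_paired_model(
        man, cfg, enc_cfg, cls_cfg)
    log = TrainLog()
    _fit(model, (images, labels, val_data), cfg, "recon", log, "stage1", tb)
    if cfg.freeze_encoder_in_stage2:
        # encoder is frozen: precompute latents once and train the
        # classifier head on them directly
        zs = []
        for i in range(0, len(images), 64):
            zs.append(model.encode(images[i:i + 64]))
        Z = np.concatenate(zs)
        onehot = _one_hot(labels, cls_cfg.classes)
        alpha = _alpha_for(labels, cfg)
        opt = nn.Adam([model.classifier], lr=cfg.learning_rate)
        shuffle_rng = rng_for(cfg.seed, "shuffle.stage2")
        n = len(Z)
        for epoch in range(cfg.epochs):
            perm = shuffle_rng.permutation(n)
            tot = 0.0; correct = 0
            for i in range(0, n, cfg.batch_size):
                idx = perm[i:i + cfg.batch_size]
                opt.zero_grads()
                logits = model.classify(Z[idx], train=True)
                probs = nn.softmax(logits, axis=-1)
                l_cls, dlog = _cls_grad(probs, onehot[idx], cfg, alpha)
                correct += int((logits.argmax(1) == labels[idx]).sum())
                model.classifier.backward(dlog.astype(Z.dtype))
                opt.step()
                tot += l_cls * len(idx)
            row = {"stage": "stage2", "epoch": epoch, "loss_total": tot / n,
                   "loss_cls": tot / n, "train_acc": correct / n,
                   "seed": cfg.seed}
            if val_data is not None:
                row["val_acc"] = _accuracy(model, *val_data)
            log.add(**row)
    else:
        _fit(model, (images, labels, val_data), cfg, "cls", log, "stage2")
    return model, log


def train_m2(man: DatasetManifest, cfg: TrainConfig,
             enc_cfg: EncoderConfig | None = None,
             cls_cfg: ClassifierConfig | None = None):
    """Joint training: L = L_cls + lambda * L_encoder-decoder each step."""
    enc_cfg = enc_cfg or EncoderConfig()
    cls_cfg = cls_cfg or ClassifierConfig()
    model, tb, images, labels, val_data = _make_paired_model(
        man, cfg, enc_cfg, cls_cfg)
    log = TrainLog()
    _fit(model, (images, labels, val_data), cfg, "joint", log, "joint", tb)
    return model, log


TRAINERS = {"baseline": train_baseline, "m1": train_m1, "m2": train_m2}


def train(man: DatasetManifest, cfg: TrainConfig, **kw):
    return TRAINERS[cfg.regime](man, cfg, **kw)


def cross_validate(man: DatasetManifest, cfg: TrainConfig, k: int = 5,
                   enc_cfg: EncoderConfig | None = None,
                   cls_cfg: ClassifierConfig | None = None) -> dict:
    """k-fold cross-validation over the paired training split.

    Folds partition the paired set; each sample is validated exactly
    once; assignment is deterministic under the config seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    enc_cfg = enc_cfg or EncoderConfig()
    cls_cfg = cls_cfg or ClassifierConfig()
    images, labels, reports = load_split(man, "train")
    n = len(images)
    if k > n:
        raise ValueError(f"k={k} exceeds number of paired samples n={n}")
    if cfg.regime != "baseline" and any(r is None for r in reports):
        raise ValueError("cross-validation requires the paired set")
    kf = KFold(n_splits=k, shuffle=True,
               random_state=derive_seed(cfg.seed, "cv"))
    folds = []
    for fold_idx, (tr, va) in enumerate(kf.split(np.arange(n))):
        sub_images, sub_labels = images[tr], labels[tr]
        sub_reports = [reports[i] for i in tr]
        tb = None
        if cfg.regime == "baseline":
            model = SharedLatentModel(enc_cfg, cls_cfg, None, cfg.seed)
            _fit(model, (sub_images, sub_labels, None), cfg, "cls",
                 TrainLog(), "cv")
        else:
            tb = _TextBundle(sub_reports, cfg)
            dec_cfg = DecoderConfig(steps=tb.steps, vocab_size=tb.vocab.size)
            model = SharedLatentModel(enc_cfg, cls_cfg, dec_cfg, cfg.seed,
                                      embeddings=tb.embeddings)
            mode = "joint" if cfg.regime == "m2" else "recon"
            _fit(model, (sub_images, sub_labels, None), cfg, mode,
                 TrainLog(), "cv", tb)
            if cfg.regime == "m1":
                Z = model.encode(sub_images)
                # brief classifier fit on frozen latents
                onehot = _one_hot(sub_labels, cls_cfg.classes)
                opt = nn.Adam([model.classifier], lr=cfg.learning_rate)
                srng = rng_for(cfg.seed, f"cv.stage2.{fold_idx}")
                for _ in range(cfg.epochs):
                    perm = srng.permutation(len(Z))
                    for i in range(0, len(Z), cfg.batch_size):
                        idx = perm[i:i + cfg.batch_size]
                        opt.zero_grads()
                        logits = model.classify(Z[idx], train=True)
                        probs = nn.softmax(logits, axis=-1)
                        _, dlog = _cls_grad(probs, onehot[idx], cfg, None)
                        model.classifier.backward(dlog.astype(Z.dtype))
                        opt.step()
        preds = model.predict_proba(images[va]).argmax(axis=1)
        cm = metrics.confusion_matrix(labels[va], preds,
                                      cls_cfg.classes)
        rep = metrics.metrics(cm)
        folds.append({"fold": fold_idx, "indices": va.tolist(),
                      "accuracy": rep.accuracy, "avg_f1": rep.avg_f1})
    return {
        "k": k, "seed": cfg.seed, "folds": folds,
        "mean_accuracy": float(np.mean([f["accuracy"] for f in folds])),
        "mean_avg_f1": float(np.mean([f["avg_f1"] for f in folds])),
    }
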