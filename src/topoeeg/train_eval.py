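"""Training harness and evaluation metrics for persistence-image forecasting.

Stages: consecutive-window PI pairs; subject-level train/validation/test
split; generator pretraining (pixelwise BCE, RMSprop, lr 0.01); adversarial
training (alternating discriminator/generator updates, RMSprop, lr 0.001,
generator loss = adversarial BCE + recon_weight * pixelwise BCE); evaluation
by AUC / MAP / MAE; subject-level classification by reconstruction error;
GAT-only / LSTM-only ablation variants.

Metrics: MAE is the mean absolute pixel difference between predicted and
actual images.  AP is the area under the precision-recall curve (step
interpolation) per query, MAP the mean AP over queries, and AUC the
Mann-Whitney probability P(score_pos > score_neg) + 0.5 P(tie).  The primary
evaluation protocol is pixelwise: each target image is binarized at the
classification threshold (default 0.4) to give labels, and the predicted
pixel intensities are the scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .pigat_gan import (GatOnlyGenerator, Generator, LstmOnlyGenerator,
                        RMSProp, bce_grad_logits, bce_loss)
from .synthetic import substream_rng

logger = logging.getLogger("topoeeg")

__all__ = [
    "TrainingConfig",
    "PIPair",
    "EvaluationReport",
    "make_pairs",
    "split_subjects",
    "pretrain_generator",
    "adversarial_train",
    "mae",
    "average_precision",
    "map_metric",
    "auc_metric",
    "evaluate_prediction",
    "identity_baseline_mae",
    "classify_subjects",
    "ablation_variants",
]


@dataclass
class TrainingConfig:
    """Optimization and evaluation settings.

    The dropout default (0.6) applies to the first GAT layer's input
    features and attention coefficients during training; recon_weight
    balances the generator's reconstruction BCE against its adversarial
    term.  The split is by subject: 80% train / 20% test, with 10% of the
    training subjects held out for validation.
    """

    lr_pretrain: float = 0.01
    lr_joint: float = 0.001
    batch_size: int = 32
    classification_threshold: float = 0.4
    gat_dropout: float = 0.6
    epochs_pretrain: int = 100
    epochs_joint: int = 800
    train_frac: float = 0.8
    val_frac: float = 0.1
    recon_weight: float = 1.0
    disc_loss_floor: float = 1.0
    disc_lr_scale: float = 0.1
    resolution: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.lr_pretrain <= 0 or self.lr_joint <= 0:
            raise ValueError("learning rates must be positive")
        if not (0 < self.train_frac < 1 and 0 <= self.val_frac < 1):
            raise ValueError("split fractions must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class PIPair:
    """Input image at window t and target image at window t + 1."""

    subject_id: str
    band: str
    t: int
    x: np.ndarray
    y: np.ndarray


@dataclass
class EvaluationReport:
    band: str
    n_samples: int
    auc: float
    map: float
    mae: float
    gen_curve: list[float] = field(default_factory=list)
    disc_curve: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Pairs and splits
# ---------------------------------------------------------------------------

def make_pairs(sequences: dict[tuple[str, str], np.ndarray]) -> list[PIPair]:
    """One pair per consecutive window couple, never crossing subjects.

    ``sequences`` maps (subject_id, band) to a (T, R, R) stack of images in
    temporal order; T windows yield T - 1 pairs.  Singleton sequences are
    skipped with a warning.
    """
    pairs: list[PIPair] = []
    for (sid, band), stack in sequences.items():
        stack = np.asarray(stack, dtype=float)
        if stack.shape[0] < 2:
            logger.warning("skipping singleton PI sequence for %s/%s", sid, band)
            continue
        for t in range(stack.shape[0] - 1):
            pairs.append(PIPair(sid, band, t, stack[t], stack[t + 1]))
    return pairs


def split_subjects(subject_ids, seed: int, train_frac: float = 0.8,
                   val_frac: float = 0.1):
    """Seeded subject-level split into (train, validation, test) id lists.

    Validation is carved out of the training portion (default 10% of it).
    Splitting by subject keeps all of a subject's temporally adjacent pairs
    on one side of the train/test boundary.
    """
    ids = sorted(set(subject_ids))
    rng = substream_rng(seed, "split")
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_train = max(1, int(round(train_frac * len(ids))))
    train_all, test = perm[:n_train], perm[n_train:]
    n_val = int(round(val_frac * len(train_all)))
    val, train = train_all[:n_val], train_all[n_val:]
    return train, val, test


def _stack_pairs(pairs: list[PIPair]):
    x = np.stack([p.x for p in pairs])
    y = np.stack([p.y for p in pairs])
    return x, y


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _check_finite(loss: float, stage: str) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(f"{stage} diverged: loss = {loss}")


def pretrain_generator(gen, pairs: list[PIPair],
                       cfg: TrainingConfig) -> list[float]:
    """Minimize pixelwise BCE(predicted, target) with RMSprop at lr_pretrain.

    Returns the per-epoch mean training loss.  Fully determined by
    cfg.seed (shuffling and dropout draw from named substreams).
    """
    cfg.validate()
    if not pairs:
        raise ValueError("no training pairs")
    x, y = _stack_pairs(pairs)
    opt = RMSProp(gen.params, lr=cfg.lr_pretrain)
    shuffle_rng = substream_rng(cfg.seed, "pretrain-shuffle")
    drop_rng = substream_rng(cfg.seed, "pretrain-dropout")
    curve: list[float] = []
    for _epoch in range(cfg.epochs_pretrain):
        order = shuffle_rng.permutation(len(pairs))
        losses = []
        for lo in range(0, len(pairs), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            gen.zero_grads()
            pred = gen.forward(xb, training=True, rng=drop_rng)
            loss = bce_loss(pred, yb)
            _check_finite(loss, "pretraining")
            gen.backward(bce_grad_logits(pred, yb).reshape(len(idx), -1))
            opt.step(gen.params, gen.grads)
            losses.append(loss)
        curve.append(float(np.mean(losses)))
    return curve


def adversarial_train(gen, disc, pairs: list[PIPair], cfg: TrainingConfig):
    """Alternating GAN updates; returns (generator, discriminator) loss curves.

    Per batch: the discriminator takes a BCE step on real targets (label 1)
    versus generated images (label 0); the generator then takes a step on
    adversarial BCE towards label 1 plus recon_weight times the pixelwise
    reconstruction BCE against the true next image.
    """
    cfg.validate()
    if not pairs:
        raise ValueError("no training pairs")
    x, y = _stack_pairs(pairs)
    opt_g = RMSProp(gen.params, lr=cfg.lr_joint)
    opt_d = RMSProp(disc.params, lr=cfg.lr_joint * cfg.disc_lr_scale)
    shuffle_rng = substream_rng(cfg.seed, "joint-shuffle")
    drop_rng = substream_rng(cfg.seed, "joint-dropout")
    gen_curve: list[float] = []
    disc_curve: list[float] = []
    for _epoch in range(cfg.epochs_joint):
        order = shuffle_rng.permutation(len(pairs))
        g_losses, d_losses = [], []
        for lo in range(0, len(pairs), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            nb = len(idx)
            ones, zeros = np.ones(nb), np.zeros(nb)

            fake = gen.forward(xb, training=True, rng=drop_rng)

            # Discriminator step: real vs generated (generator held fixed).
            # Gradient balance: the discriminator learns at a reduced rate
            # and pauses below the loss floor, so it cannot run away from
            # the generator on small desk-scale pair sets.
            disc.zero_grads()
            p_real = disc.forward(yb)
            disc.backward(bce_grad_logits(p_real, ones))
            p_fake = disc.forward(fake)
            disc.backward(bce_grad_logits(p_fake, zeros))
            d_loss = bce_loss(p_real, ones) + bce_loss(p_fake, zeros)
            _check_finite(d_loss, "discriminator")
            if d_loss > cfg.disc_loss_floor:
                opt_d.step(disc.params, disc.grads)

            # Generator step: fool the updated discriminator + reconstruct.
            disc.zero_grads()
            p_fool = disc.forward(fake)
            dfake = disc.backward(bce_grad_logits(p_fool, ones))
            disc.zero_grads()  # discard grads from the generator's pass
            dlogits = dfake * fake * (1.0 - fake) \
                + cfg.recon_weight * (fake - yb) / fake.size
            g_loss = bce_loss(p_fool, ones) + cfg.recon_weight * bce_loss(fake, yb)
            _check_finite(g_loss, "generator")
            gen.zero_grads()
            gen.backward(dlogits.reshape(nb, -1))
            opt_g.step(gen.params, gen.grads)

            g_losses.append(g_loss)
            d_losses.append(d_loss)
        gen_curve.append(float(np.mean(g_losses)))
        disc_curve.append(float(np.mean(d_losses)))
    return gen_curve, disc_curve


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def mae(pred, true) -> float:
    """Mean absolute difference over all entries of equally shaped stacks."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean(np.abs(p - t)))


def average_precision(scores, labels) -> float:
    """Area under the precision-recall curve (step interpolation).

    Equals the mean of precision-at-rank over the ranks of the positive
    items when sorted by descending score (stable under ties).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if s.shape != lab.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    n_pos = int(lab.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positives")
    order = np.argsort(-s, kind="stable")
    ranked = lab[order]
    cum_hits = np.cumsum(ranked)
    ranks = np.arange(1, len(s) + 1)
    return float(np.sum(cum_hits[ranked] / ranks[ranked]) / n_pos)


def map_metric(queries) -> float:
    """Mean AP over queries; zero-positive queries are excluded with a warning."""
    aps = []
    for scores, labels in queries:
        if not np.any(labels):
            logger.warning("excluding query with no positive labels from MAP")
            continue
        aps.append(average_precision(scores, labels))
    if not aps:
        raise ValueError("no evaluable queries for MAP")
    return float(np.mean(aps))


def auc_metric(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)
    u = ranks[lab].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------

def evaluate_prediction(gen, pairs: list[PIPair], cfg: TrainingConfig,
                        gen_curve=None, disc_curve=None) -> EvaluationReport:
    """Pixelwise protocol: binarized targets as labels, predictions as scores.

    Each target image is thresholded at cfg.classification_threshold; the
    predicted intensities of the same image are the ranking scores.  AUC and
    AP are averaged over images (degenerate all-positive / all-negative
    targets are excluded); MAE is computed over every pixel of every pair.
    """
    if not pairs:
        raise ValueError("no evaluation pairs")
    x, y = _stack_pairs(pairs)
    pred = _forward_in_batches(gen, x, cfg.batch_size)
    aucs, queries = [], []
    for k in range(len(pairs)):
        labels = (y[k] > cfg.classification_threshold).ravel()
        scores = pred[k].ravel()
        if labels.all() or not labels.any():
            logger.warning("excluding degenerate target image %d", k)
            continue
        aucs.append(auc_metric(scores, labels))
        queries.append((scores, labels))
    band = pairs[0].band
    report = EvaluationReport(
        band=band,
        n_samples=len(pairs),
        auc=float(np.mean(aucs)) if aucs else float("nan"),
        map=map_metric(queries) if queries else float("nan"),
        mae=mae(pred, y),
        gen_curve=list(gen_curve or []),
        disc_curve=list(disc_curve or []),
    )
    return report


def identity_baseline_mae(pairs: list[PIPair]) -> float:
    """MAE of the persistence baseline that predicts PI_t for window t + 1."""
    x, y = _stack_pairs(pairs)
    return mae(x, y)


def _forward_in_batches(gen, x: np.ndarray, batch_size: int) -> np.ndarray:
    outs = [gen.forward(x[lo:lo + batch_size])
            for lo in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def classify_subjects(gen, pairs_by_subject: dict[str, list[PIPair]],
                      labels: dict[str, str], cfg: TrainingConfig,
                      mode: str = "recon", disc=None):
    """Subject-level scores from a generator trained on the patient class.

    mode "recon": subject score = mean pixelwise BCE between the generator's
    prediction and the true next image over the subject's pairs.  Sequences
    with richer, more variable topology (here: the amplitude-elevated
    patient class) are intrinsically harder to forecast, so the patient
    class is the positive label and a higher residual votes "patient".
    mode "disc": mean discriminator output on the subject's true images.
    Returns (scores dict, AUC over subjects).
    """
    scores: dict[str, float] = {}
    for sid, pairs in pairs_by_subject.items():
        x, y = _stack_pairs(pairs)
        if mode == "recon":
            pred = _forward_in_batches(gen, x, cfg.batch_size)
            scores[sid] = bce_loss(pred, y)
        elif mode == "disc":
            if disc is None:
                raise ValueError("mode 'disc' requires a discriminator")
            scores[sid] = float(np.mean(disc.forward(y)))
        else:
            raise ValueError(f"unknown scoring mode {mode!r}")
    sids = sorted(scores)
    lab = np.array([labels[s] == "patient" for s in sids])
    auc = auc_metric(np.array([scores[s] for s in sids]), lab)
    return scores, auc


# ---------------------------------------------------------------------------
# Ablations
# ---------------------------------------------------------------------------

def ablation_variants(resolution: int, cfg: TrainingConfig, seed: int = 0,
                      **model_kwargs):
    """The three generator variants under an identical training harness."""
    return {
        "full": Generator(resolution, dropout=cfg.gat_dropout, seed=seed,
                          **model_kwargs),
        "gat_only": GatOnlyGenerator(resolution, dropout=cfg.gat_dropout,
                                     seed=seed, **model_kwargs),
        "lstm_only": LstmOnlyGenerator(resolution, seed=seed),
    }
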