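"""Training objectives and schedules.

Covers the supervised group-classification objective (optionally
class-balanced), masked-gene self-supervised pretraining of the
single-cell encoder, and the progressive-unfreezing fine-tuning recipe for
single-cell classification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .data import CellTable, GeneVocabulary, ValidationError
from .grouping import GroupSamplerConfig, batch_group_members, sample_group_batches
from .model import SingleCellEncoder, TissueFormer
from .nn import AdamW, cross_entropy, warmup_linear_decay
from .nn import autograd as ag

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Class-balanced weighting
# ---------------------------------------------------------------------------

@dataclass
class ClassWeightSpec:
    """Per-class loss weights ``w_i = M / (C * M_i)``.

    With these weights the loss magnitude reflects every class equally:
    the identity ``sum_i w_i * M_i = M`` holds exactly.
    """

    M: int
    C: int
    class_counts: np.ndarray
    weights: np.ndarray


def compute_class_weights(class_counts) -> ClassWeightSpec:
    counts = np.asarray(class_counts, dtype=np.int64)
    if (counts <= 0).any():
        raise ValidationError(
            "every class must have a positive count; drop empty classes upstream"
        )
    M = int(counts.sum())
    C = len(counts)
    weights = M / (C * counts.astype(float))
    return ClassWeightSpec(M=M, C=C, class_counts=counts, weights=weights)


# ---------------------------------------------------------------------------
# Group-classification training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    warmup_ratio: float = 0.1
    epochs: int = 10
    steps_per_epoch: int = 50
    weight_decay: float = 0.01
    rng_seed: int = 0
    class_balanced: bool = False
    max_steps: int | None = None
    early_stopping_patience: int = 3
    n_val_groups: int = 256
    val_fraction: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.warmup_ratio <= 1.0:
            raise ValidationError("warmup_ratio must lie in [0, 1]")


def per_brain_split(
    table: CellTable, val_fraction: float, rng_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random per-brain cell partition into train / validation masks."""
    rng = np.random.default_rng(rng_seed)
    val = np.zeros(table.n_cells, dtype=bool)
    brains = np.asarray(table.brain_id)
    for b in np.unique(brains):
        idx = np.nonzero(brains == b)[0]
        n_val = int(round(val_fraction * len(idx)))
        val[rng.choice(idx, size=n_val, replace=False)] = True
    return ~val, val


def _label_indices(labels, class_labels: list[str]) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(class_labels)}
    try:
        return np.array([lookup[str(l)] for l in labels], dtype=np.int64)
    except KeyError as e:
        raise ValidationError(f"label {e} not among model classes") from None


def train_group_classifier(
    model: TissueFormer,
    table: CellTable,
    tokens: np.ndarray,
    sampler_cfg: GroupSamplerConfig,
    cfg: TrainConfig,
    train_mask: np.ndarray | None = None,
    val_mask: np.ndarray | None = None,
) -> tuple[TissueFormer, list[dict]]:
    """Train on streamed group batches; returns the model and a metrics log.

    ``tokens`` is the tokenized matrix aligned with ``table`` rows.  When no
    masks are given, cells are split per brain into train/validation with
    ``cfg.val_fraction``.  Training is deterministic given the seeds under
    single-threaded execution.
    """
    if table.area_label is None:
        raise ValidationError("training requires area labels")
    if train_mask is None or val_mask is None:
        train_mask, val_mask = per_brain_split(table, cfg.val_fraction, cfg.rng_seed)

    areas = np.asarray(table.area_label).astype(str)
    class_weights = None
    if cfg.class_balanced:
        train_areas = areas[train_mask]
        labels, counts = np.unique(train_areas, return_counts=True)
        spec = compute_class_weights(counts)
        full = np.ones(len(model.class_labels), dtype=float)
        for lbl, w in zip(labels, spec.weights):
            full[model.class_labels.index(lbl)] = w
        class_weights = full

    total_steps = (
        cfg.max_steps
        if cfg.max_steps is not None
        else cfg.epochs * cfg.steps_per_epoch
    )
    if total_steps == 0 or cfg.epochs == 0:
        return model, []
    lr_factor = warmup_linear_decay(total_steps, cfg.warmup_ratio)
    optimizer = AdamW(
        model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay
    )

    # fixed validation groups, seeded from validation cells
    val_rng_cfg = GroupSamplerConfig(
        group_size=sampler_cfg.group_size,
        total_cells_per_batch=sampler_cfg.group_size * cfg.n_val_groups,
        rng_seed=cfg.rng_seed + 7_919,
        homogeneous_level=sampler_cfg.homogeneous_level,
        split_policy=sampler_cfg.split_policy,
    )
    val_batch = next(sample_group_batches(table, val_rng_cfg, val_mask, n_batches=1))
    val_tokens = np.stack([tokens[g.member_indices] for g in val_batch])
    val_targets = _label_indices([g.label for g in val_batch], model.class_labels)

    stream = sample_group_batches(table, sampler_cfg, train_mask)
    metrics: list[dict] = []
    step = 0
    best_val = np.inf
    stale = 0
    model.train()
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for _ in range(cfg.steps_per_epoch):
            if step >= total_steps:
                break
            batch = next(stream)
            bt = np.stack([tokens[g.member_indices] for g in batch])
            targets = _label_indices([g.label for g in batch], model.class_labels)
            logits = model.forward_group(bt)
            sw = class_weights[targets] if class_weights is not None else None
            loss = cross_entropy(logits, targets, sw)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"divergent loss at step {step}: {float(loss.data)!r}"
                )
            model.zero_grad()
            loss.backward()
            optimizer.step(lr=cfg.learning_rate * lr_factor(step))
            epoch_losses.append(float(loss.data))
            step += 1
        val_loss, val_acc = _evaluate(model, val_tokens, val_targets)
        metrics.append(
            {
                "epoch": epoch,
                "step": step,
                "train_loss": float(np.mean(epoch_losses)) if epoch_losses else np.nan,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best_val - 1e-6:
            best_val, stale = val_loss, 0
        else:
            stale += 1
            if stale >= cfg.early_stopping_patience:
                logger.info("early stopping at epoch %d", epoch)
                break
        if step >= total_steps:
            break
    model.eval()
    return model, metrics


def _evaluate(model: TissueFormer, group_tokens, targets) -> tuple[float, float]:
    was_training = model.training
    model.eval()
    losses, correct, seen = [], 0, 0
    for i in range(0, len(group_tokens), 64):
        logits = model.forward_group(group_tokens[i : i + 64])
        t = targets[i : i + 64]
        losses.append(float(cross_entropy(logits.detach(), t).data) * len(t))
        correct += int((np.argmax(logits.data, axis=1) == t).sum())
        seen += len(t)
    model.train(was_training)
    return sum(losses) / seen, correct / seen


def evaluate_group_accuracy(
    model: TissueFormer,
    table: CellTable,
    tokens: np.ndarray,
    N: int,
    mask: np.ndarray | None = None,
    n_groups: int = 256,
    rng_seed: int = 0,
) -> float:
    """Accuracy of group predictions on freshly sampled columnar groups."""
    cfg = GroupSamplerConfig(
        group_size=N, total_cells_per_batch=N * n_groups, rng_seed=rng_seed
    )
    batch = next(sample_group_batches(table, cfg, mask, n_batches=1))
    gt = np.stack([tokens[g.member_indices] for g in batch])
    targets = _label_indices([g.label for g in batch], model.class_labels)
    preds = model.predict_groups(gt)
    return float((preds == targets).mean())


# ---------------------------------------------------------------------------
# Masked-gene pretraining
# ---------------------------------------------------------------------------

@dataclass
class PretrainConfig:
    mask_fraction: float = 0.15
    epochs: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 32
    rng_seed: int = 0
    weight_decay: float = 0.01
    bert_mix: bool = False  # replace with <mask> always; optionally 80/10/10

    def __post_init__(self):
        if not 0.0 < self.mask_fraction < 1.0:
            raise ValidationError("mask_fraction must lie in (0, 1)")


@dataclass
class PretrainResult:
    encoder: SingleCellEncoder
    mlm_head: nn.Linear
    loss_curve: list[float] = field(default_factory=list)


def n_masked(n_expressed: int, mask_fraction: float) -> int:
    """Round-half-up count of masked genes, floored at 1 for nonempty cells."""
    if n_expressed < 1:
        return 0
    return max(1, int(np.floor(mask_fraction * n_expressed + 0.5)))


def sample_mask_positions(
    tokens_row: np.ndarray,
    vocab: GeneVocabulary,
    mask_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Positions to mask in one sequence: gene slots only, never cls/pad."""
    gene_pos = np.nonzero(
        (tokens_row != vocab.pad_id)
        & (tokens_row != vocab.cls_id)
        & (tokens_row != vocab.mask_id)
    )[0]
    k = n_masked(len(gene_pos), mask_fraction)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(gene_pos, size=k, replace=False)


def masked_gene_pretrain(
    encoder: SingleCellEncoder,
    token_matrix: np.ndarray,
    vocab: GeneVocabulary,
    cfg: PretrainConfig,
) -> PretrainResult:
    """Self-supervised pretraining: predict the identity of masked genes.

    Per cell, ``round(mask_fraction * n_expressed)`` gene positions
    (minimum one) are replaced by ``<mask>`` and the encoder + a linear
    vocabulary head are trained with cross-entropy to recover the original
    tokens at those positions.  Pad positions are never maskable.
    """
    token_matrix = np.asarray(token_matrix)
    expressed = (token_matrix != vocab.pad_id).sum(axis=1) - 1
    usable = np.nonzero(expressed >= 1)[0]
    if len(usable) == 0:
        raise ValidationError("pretraining corpus contains only empty cells")
    rng = np.random.default_rng(cfg.rng_seed)
    head = nn.Linear(
        encoder.cfg.hidden_dim, vocab.size,
        np.random.default_rng(cfg.rng_seed + 1), init_scale=0.0,
    )
    params = encoder.parameters() + head.parameters()
    total_steps = cfg.epochs * max(1, len(usable) // cfg.batch_size)
    optimizer = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    lr_factor = warmup_linear_decay(total_steps, 0.1)
    losses: list[float] = []
    step = 0
    encoder.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(usable)
        for i in range(0, len(order) - cfg.batch_size + 1, cfg.batch_size):
            rows = order[i : i + cfg.batch_size]
            batch = token_matrix[rows].copy()
            mask_rows, mask_cols, targets = [], [], []
            for r in range(len(rows)):
                pos = sample_mask_positions(batch[r], vocab, cfg.mask_fraction, rng)
                for p in pos:
                    mask_rows.append(r)
                    mask_cols.append(p)
                    targets.append(batch[r, p])
                    if cfg.bert_mix:
                        u = rng.random()
                        if u < 0.8:
                            batch[r, p] = vocab.mask_id
                        elif u < 0.9:
                            batch[r, p] = rng.integers(vocab.n_special, vocab.size)
                    else:
                        batch[r, p] = vocab.mask_id
            hidden = encoder.hidden_states(batch, vocab.pad_id, rng)
            picked = ag.take_positions(hidden, np.array(mask_rows), np.array(mask_cols))
            logits = head(picked)
            loss = cross_entropy(logits, np.array(targets))
            for p in params:
                p.grad = None
            loss.backward()
            optimizer.step(lr=cfg.learning_rate * lr_factor(step))
            losses.append(float(loss.data))
            step += 1
    encoder.eval()
    return PretrainResult(encoder=encoder, mlm_head=head, loss_curve=losses)


def save_encoder_checkpoint(
    encoder: SingleCellEncoder, vocab: GeneVocabulary, path: str | Path
) -> None:
    """Encoder-only checkpoint loadable via :func:`load_pretrained_single_cell`."""
    from dataclasses import asdict

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "params.npz", **encoder.state_dict())
    meta = {
        "encoder": asdict(encoder.cfg),
        "vocab_hash": vocab.content_hash(),
        "vocab_genes": list(vocab.gene_ids),
    }
    (path / "config.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# Progressive-unfreezing single-cell fine-tuning
# ---------------------------------------------------------------------------

@dataclass
class SingleCellClassifier:
    """A linear head over the encoder's <cls> embedding."""

    encoder: SingleCellEncoder
    head: nn.Linear
    class_labels: list[str]
    pad_id: int

    def predict(self, tokens: np.ndarray, batch_size: int = 256) -> np.ndarray:
        self.encoder.eval()
        out = []
        for i in range(0, len(tokens), batch_size):
            emb = self.encoder.cls_embeddings(tokens[i : i + batch_size], self.pad_id)
            out.append(np.argmax(self.head(emb).data, axis=1))
        return np.concatenate(out)

    def loss(self, tokens: np.ndarray, targets: np.ndarray) -> float:
        self.encoder.eval()
        emb = self.encoder.cls_embeddings(tokens, self.pad_id)
        return float(cross_entropy(self.head(emb).detach(), targets).data)


def finetune_single_cell_progressive(
    encoder: SingleCellEncoder,
    tokens: np.ndarray,
    labels: np.ndarray,
    vocab: GeneVocabulary,
    n_epochs: int,
    batch_size: int = 32,
    learning_rate: float = 5e-4,
    rng_seed: int = 0,
    val_tokens: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    loss_target: float | None = None,
) -> tuple[SingleCellClassifier, list[dict]]:
    """Fine-tune a single-cell classifier with progressive unfreezing.

    Epoch 1 trains the classification head only; each subsequent epoch
    unfreezes one more encoder layer from the top, so the number of
    unfrozen layers after epoch ``k`` is ``min(k - 1, n_layers)``.  When a
    ``loss_target`` and validation data are given, the per-step validation
    loss is tracked and the step at which the target is first reached is
    recorded in the metrics (for matched-budget comparisons).
    """
    if n_epochs < 1:
        raise ValidationError("n_epochs must be >= 1")
    rng = np.random.default_rng(rng_seed)
    class_labels = sorted(set(str(l) for l in labels))
    lookup = {c: i for i, c in enumerate(class_labels)}
    targets = np.array([lookup[str(l)] for l in labels])
    head = nn.Linear(
        encoder.cfg.hidden_dim, len(class_labels),
        np.random.default_rng(rng_seed + 1), init_scale=0.0,
    )
    clf = SingleCellClassifier(encoder, head, class_labels, vocab.pad_id)
    val_t = None
    if val_tokens is not None and val_labels is not None:
        val_t = np.array([lookup[str(l)] for l in val_labels])

    metrics: list[dict] = []
    step = 0
    steps_to_target = None
    n_layers = len(encoder.layers)
    for epoch in range(1, n_epochs + 1):
        n_unfrozen = min(epoch - 1, n_layers)
        trainable = head.parameters()
        for layer in encoder.layers[n_layers - n_unfrozen :]:
            trainable = trainable + layer.parameters()
        optimizer = AdamW(trainable, lr=learning_rate)
        encoder.train()
        order = rng.permutation(len(tokens))
        epoch_losses = []
        for i in range(0, len(order), batch_size):
            rows = order[i : i + batch_size]
            emb = encoder.cls_embeddings(tokens[rows], vocab.pad_id, rng)
            loss = cross_entropy(head(emb), targets[rows])
            for p in trainable:
                p.grad = None
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
            step += 1
            if loss_target is not None and val_t is not None and steps_to_target is None:
                if clf.loss(val_tokens, val_t) <= loss_target:
                    steps_to_target = step
                encoder.train()
        encoder.eval()
        record = {
            "epoch": epoch,
            "n_unfrozen_layers": n_unfrozen,
            "train_loss": float(np.mean(epoch_losses)),
        }
        if val_t is not None:
            preds = clf.predict(val_tokens)
            record["val_accuracy"] = float((preds == val_t).mean())
            record["val_loss"] = clf.loss(val_tokens, val_t)
        record["steps_to_target"] = steps_to_target
        metrics.append(record)
    return clf, metrics
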