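"""The TissueFormer network.

A single-cell encoder (BERT-style, rank-token input, ``<cls>`` pooling)
produces one embedding per cell; an aggregation transformer with no
positional encoding attends across the cells of a group; average pooling
and a linear head yield per-group class logits.  Because the aggregation
stack is position-free and pooling averages over cells, the group logits
are invariant to the order in which cells are presented.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .data import GeneVocabulary, ValidationError
from .nn import Tensor
from .nn import autograd as ag


@dataclass
class SingleCellModuleConfig:
    """BERT-style encoder over rank-token sentences.

    Defaults follow the 12-layer Geneformer-scale setting; ``tiny()`` is a
    desk-scale preset preserving every contract.
    """

    n_layers: int = 12
    hidden_dim: int = 512
    n_heads: int = 8
    context_window: int = 2048
    activation: str = "relu"
    positional_encoding: str = "sinusoidal"
    dropout: float = 0.1

    def __post_init__(self):
        if self.hidden_dim % self.n_heads:
            raise ValidationError("hidden_dim must be divisible by n_heads")
        if self.activation != "relu":
            raise ValidationError("single-cell module uses ReLU activations")
        if self.positional_encoding != "sinusoidal":
            raise ValidationError("single-cell module uses sinusoidal positions")

    @classmethod
    def tiny(cls, context_window: int = 16) -> "SingleCellModuleConfig":
        return cls(n_layers=2, hidden_dim=32, n_heads=4, context_window=context_window)


@dataclass
class AggregationConfig:
    """Order-free transformer over cell embeddings.

    Positional encoding is absent by construction — that is what makes the
    stack equivariant, and the average pool then invariant, to cell order.
    """

    n_layers: int = 6
    hidden_dim: int = 768
    n_heads: int = 8
    activation: str = "gelu"
    normalization: str = "layernorm"
    dropout: float = 0.1

    def __post_init__(self):
        if self.hidden_dim % self.n_heads:
            raise ValidationError("hidden_dim must be divisible by n_heads")
        if self.activation != "gelu" or self.normalization != "layernorm":
            raise ValidationError("aggregation stack uses GELU + LayerNorm")

    @classmethod
    def tiny(cls) -> "AggregationConfig":
        return cls(n_layers=2, hidden_dim=32, n_heads=4)


class SingleCellEncoder(nn.Module):
    """Token embedding + sinusoidal positions + post-norm encoder stack."""

    def __init__(self, cfg: SingleCellModuleConfig, vocab_size: int, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.vocab_size = vocab_size
        self.tok_emb = nn.Embedding(vocab_size, cfg.hidden_dim, rng)
        self.layers = [
            nn.TransformerEncoderLayer(
                cfg.hidden_dim, cfg.n_heads, cfg.activation, rng, dropout=cfg.dropout
            )
            for _ in range(cfg.n_layers)
        ]
        self._posenc = nn.sinusoidal_positions(cfg.context_window + 1, cfg.hidden_dim)

    def hidden_states(
        self, tokens: np.ndarray, pad_id: int, rng: np.random.Generator | None = None
    ) -> Tensor:
        """Final hidden states, shape (M, L, D); pads masked out of attention."""
        tokens = np.asarray(tokens)
        if tokens.ndim != 2 or tokens.shape[1] > self._posenc.shape[0]:
            raise ValidationError(
                f"token matrix shape {tokens.shape} exceeds context window "
                f"{self.cfg.context_window}"
            )
        mask = tokens == pad_id
        # canonical transformer scaling keeps token identity from being
        # drowned by the unit-amplitude sinusoidal positions
        scale = float(np.sqrt(self.cfg.hidden_dim))
        x = self.tok_emb(tokens) * Tensor(np.asarray(scale))
        x = x + Tensor(self._posenc[: tokens.shape[1]])
        for layer in self.layers:
            x = layer(x, key_padding_mask=mask, rng=rng)
        return x

    def cls_embeddings(
        self, tokens: np.ndarray, pad_id: int, rng: np.random.Generator | None = None
    ) -> Tensor:
        """The encoder output at the leading ``<cls>`` position, (M, D)."""
        return ag.take_first_token(self.hidden_states(tokens, pad_id, rng))


class TissueFormer(nn.Module):
    """Single-cell encoder → cell embeddings → aggregation → pooled logits."""

    def __init__(
        self,
        sc_cfg: SingleCellModuleConfig,
        agg_cfg: AggregationConfig,
        n_classes: int,
        vocab: GeneVocabulary,
        seed: int = 0,
        class_labels: list[str] | None = None,
    ):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.sc_cfg = sc_cfg
        self.agg_cfg = agg_cfg
        self.vocab = vocab
        self.n_classes = n_classes
        self.class_labels = class_labels or [str(i) for i in range(n_classes)]
        self.encoder = SingleCellEncoder(sc_cfg, vocab.size, rng)
        if sc_cfg.hidden_dim != agg_cfg.hidden_dim:
            self.adapter = nn.Linear(sc_cfg.hidden_dim, agg_cfg.hidden_dim, rng)
        else:
            self.adapter = None
        self.agg_layers = [
            nn.TransformerEncoderLayer(
                agg_cfg.hidden_dim, agg_cfg.n_heads, agg_cfg.activation, rng,
                dropout=agg_cfg.dropout,
            )
            for _ in range(agg_cfg.n_layers)
        ]
        self.head = nn.Linear(agg_cfg.hidden_dim, n_classes, rng, init_scale=0.02)
        self._drop_rng = np.random.default_rng(seed + 1)

    # -- forward passes ---------------------------------------------------
    def encode_cell(self, tokens: np.ndarray) -> np.ndarray:
        """Cell embedding (the <cls> state) for one token sequence."""
        tokens = np.asarray(tokens)
        if tokens.ndim == 1:
            tokens = tokens[None, :]
        was_training = self.training
        self.eval()
        out = self.encoder.cls_embeddings(tokens, self.vocab.pad_id).data[0]
        self.train(was_training)
        return out

    def aggregate(self, cell_emb: Tensor) -> Tensor:
        """Aggregation stack outputs per cell, (G, N, D_agg) — pre-pooling."""
        x = self.adapter(cell_emb) if self.adapter is not None else cell_emb
        for layer in self.agg_layers:
            x = layer(x, rng=self._drop_rng)
        return x

    def forward_group(self, group_tokens: np.ndarray) -> Tensor:
        """Logits for a batch of groups; input shape (G, N, L) or (N, L)."""
        group_tokens = np.asarray(group_tokens)
        if group_tokens.ndim == 2:
            group_tokens = group_tokens[None]
        G, N, L = group_tokens.shape
        if N < 1:
            raise ValidationError("a cell group must contain at least one cell")
        flat = group_tokens.reshape(G * N, L)
        emb = self.encoder.cls_embeddings(flat, self.vocab.pad_id, self._drop_rng)
        emb = emb.reshape(G, N, self.sc_cfg.hidden_dim)
        hidden = self.aggregate(emb)
        pooled = ag.mean_axis(hidden, axis=1)
        return self.head(pooled)

    def predict_groups(self, group_tokens: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Argmax class index per group, computed in eval mode in chunks."""
        group_tokens = np.asarray(group_tokens)
        was_training = self.training
        self.eval()
        out = []
        for i in range(0, len(group_tokens), batch_size):
            logits = self.forward_group(group_tokens[i : i + batch_size]).data
            out.append(np.argmax(logits, axis=1))
        self.train(was_training)
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    # -- persistence ------------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> None:
        """Parameter archive + JSON config + vocabulary hash."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "params.npz", **self.state_dict())
        meta = {
            "single_cell": asdict(self.sc_cfg),
            "aggregation": asdict(self.agg_cfg),
            "n_classes": self.n_classes,
            "class_labels": self.class_labels,
            "vocab_hash": self.vocab.content_hash(),
            "vocab_genes": list(self.vocab.gene_ids),
        }
        (path / "config.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load_checkpoint(cls, path: str | Path, vocab: GeneVocabulary | None = None) -> "TissueFormer":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        ck_vocab = GeneVocabulary.from_genes(meta["vocab_genes"])
        if vocab is not None and vocab.content_hash() != meta["vocab_hash"]:
            raise ValidationError(
                "vocabulary hash mismatch; use load_pretrained_single_cell with "
                "allow_vocab_transfer for cross-vocabulary loading"
            )
        model = cls(
            SingleCellModuleConfig(**meta["single_cell"]),
            AggregationConfig(**meta["aggregation"]),
            n_classes=meta["n_classes"],
            vocab=vocab or ck_vocab,
            class_labels=meta["class_labels"],
        )
        with np.load(path / "params.npz") as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model


def predict_cells_as_seeds(
    model: TissueFormer,
    table,
    tokens: np.ndarray,
    N: int,
    cell_indices: np.ndarray | None = None,
    chunk: int = 256,
) -> np.ndarray:
    """Per-cell predicted labels, using each cell once as a column seed.

    Every requested cell seeds its own columnar group of size ``N``; the
    group prediction is stored as that cell's label.  ``tokens`` is the
    tokenized matrix aligned with ``table`` rows.  Deterministic.
    """
    from .grouping import batch_group_members

    idx = (
        np.arange(table.n_cells)
        if cell_indices is None
        else np.asarray(cell_indices, dtype=np.int64)
    )
    preds = np.empty(len(idx), dtype=np.int64)
    for i in range(0, len(idx), chunk):
        seeds = idx[i : i + chunk]
        members = batch_group_members(table, seeds, N)
        preds[i : i + chunk] = model.predict_groups(tokens[members])
    return np.asarray(model.class_labels, dtype=object)[preds]


def load_pretrained_single_cell(
    model: TissueFormer,
    checkpoint: str | Path,
    ortho=None,
    target_vocab: GeneVocabulary | None = None,
    allow_vocab_transfer: bool = False,
    rng_seed: int = 0,
) -> TissueFormer:
    """Replace the single-cell encoder parameters from a checkpoint.

    The checkpoint may be a full-model directory or an encoder-only
    directory (as written by masked pretraining).  When the checkpoint's
    vocabulary differs from the model's, loading is refused unless
    ``allow_vocab_transfer`` is set, in which case gene embeddings pass
    through ortholog-based transfer and everything downstream of the
    encoder (adapter, aggregation stack, classifier head) is untouched.
    """
    from .tokenization import transfer_embeddings

    path = Path(checkpoint)
    meta = json.loads((path / "config.json").read_text())
    sc_meta = meta.get("single_cell", meta.get("encoder"))
    ck_cfg = SingleCellModuleConfig(**sc_meta)
    for fld in ("n_layers", "hidden_dim", "n_heads"):
        if getattr(ck_cfg, fld) != getattr(model.sc_cfg, fld):
            raise ValidationError(
                f"single-cell config mismatch on {fld}: checkpoint "
                f"{getattr(ck_cfg, fld)}, model {getattr(model.sc_cfg, fld)}"
            )
    with np.load(path / "params.npz") as npz:
        state = {k: npz[k] for k in npz.files}
    enc_state = {
        k.removeprefix("encoder."): v for k, v in state.items() if k.startswith("encoder.")
    } or state

    same_vocab = meta["vocab_hash"] == model.vocab.content_hash()
    if not same_vocab:
        if not allow_vocab_transfer:
            raise ValidationError(
                "checkpoint vocabulary differs; pass allow_vocab_transfer=True "
                "with an ortholog map to transfer gene embeddings"
            )
        src_genes = meta["vocab_genes"]
        src_vocab = GeneVocabulary.from_genes(src_genes)
        emb = enc_state["tok_emb.weight"]
        from .data import SPECIAL_TOKENS

        source = {name: emb[i] for i, name in enumerate(SPECIAL_TOKENS)}
        source.update(
            {g: emb[src_vocab.token_of_gene(g)] for g in src_genes}
        )
        enc_state["tok_emb.weight"] = transfer_embeddings(
            source, ortho, target_vocab or model.vocab, rng_seed
        )
    model.encoder.load_state_dict(enc_state)
    return model
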