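"""Rank-value tokenization of single-cell count vectors.

Each cell is converted into a "sentence" of gene tokens: counts are
total-normalized, divided by a fixed per-gene median reference, and the
expressed genes are listed in descending order of the result.  The sequence
is prefixed with ``<cls>`` (whose final-layer state becomes the cell
embedding) and padded with ``<pad>`` to a fixed length, so every sequence
has length ``context_window + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data import CellTable, GeneVocabulary, MedianReference, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TokenSequence:
    """Fixed-length token ids for one cell: ``[<cls>, g1, ..., gk, <pad>...]``."""

    tokens: np.ndarray
    n_expressed: int

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.tokens)


def build_median_reference(table: CellTable) -> MedianReference:
    """Per-gene median of total-count-normalized expression over nonzero cells.

    Genes never expressed anywhere get the excluded sentinel (NaN) and are
    dropped before ranking; taking the median over nonzero cells only keeps
    it strictly positive so the normalization in :func:`rank_tokenize` is
    well defined.
    """
    counts = table.counts_dense().astype(float)
    totals = counts.sum(axis=1)
    if totals.sum() == 0:
        raise ValidationError("cannot build a median reference from an all-zero table")
    keep = totals > 0
    normed = counts[keep] / totals[keep, None]
    medians = np.full(table.n_genes, np.nan)
    for g in range(table.n_genes):
        col = normed[:, g]
        nz = col[col > 0]
        if nz.size:
            medians[g] = np.median(nz)
    return MedianReference(gene_ids=list(table.gene_ids), median_of_gene=medians)


def rank_tokenize(
    counts_row: np.ndarray,
    ref: MedianReference,
    vocab: GeneVocabulary,
    context_window: int,
) -> TokenSequence:
    """Tokenize one cell's count vector.

    Steps: total-count normalize; divide by the reference medians (excluded
    genes dropped); sort the remaining nonzero genes by descending value,
    breaking ties by ascending gene-token id; truncate to ``context_window``
    genes; emit ``[<cls>, g(1), ..., g(k), <pad>, ...]`` of fixed length
    ``context_window + 1``.  An all-zero row yields ``[<cls>, <pad>, ...]``
    with a logged warning rather than an error.
    """
    counts_row = np.asarray(counts_row)
    if counts_row.ndim != 1 or len(counts_row) != len(vocab.gene_ids):
        raise ValidationError(
            f"counts row has length {counts_row.shape}, vocabulary has "
            f"{len(vocab.gene_ids)} genes"
        )
    if context_window < 1:
        raise ValueError("context_window must be >= 1")
    mat = tokenize_table_counts(counts_row[None, :], ref, vocab, context_window)
    tokens = mat[0]
    n_expressed = int((tokens != vocab.pad_id).sum()) - 1
    if n_expressed == 0:
        logger.warning("all-zero count row tokenized to an empty sentence")
    return TokenSequence(tokens=tokens, n_expressed=n_expressed)


def tokenize_table_counts(
    counts: np.ndarray | sp.spmatrix,
    ref: MedianReference,
    vocab: GeneVocabulary,
    context_window: int,
) -> np.ndarray:
    """Vectorized tokenization of a whole count matrix.

    Returns an integer matrix ``[n_cells, context_window + 1]`` whose rows
    are the :func:`rank_tokenize` sequences.
    """
    if sp.issparse(counts):
        counts = np.asarray(counts.todense())
    counts = np.asarray(counts, dtype=float)
    n, g = counts.shape
    if g != len(vocab.gene_ids):
        raise ValidationError("counts / vocabulary gene dimension mismatch")
    if list(ref.gene_ids) != list(vocab.gene_ids):
        raise ValidationError("median reference and vocabulary gene lists differ")
    totals = counts.sum(axis=1, keepdims=True)
    med = ref.median_of_gene
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 0.0)
        vals = vals / med
    # zero counts and excluded genes never enter the ranking
    vals = np.where((counts > 0) & ~np.isnan(med), vals, -np.inf)

    # Columns are already in ascending gene-token-id order, so a stable
    # descending-value argsort implements the tie rule (ascending token id).
    order = np.argsort(-vals, axis=1, kind="stable")
    gene_tokens = vocab.gene_token_ids()

    L = context_window + 1
    out = np.full((n, L), vocab.pad_id, dtype=np.int64)
    out[:, 0] = vocab.cls_id
    k = min(context_window, g)
    top = order[:, :k]
    top_vals = np.take_along_axis(vals, top, axis=1)
    tok = gene_tokens[top]
    keep = np.isfinite(top_vals)
    # ragged fill: position j+1 gets the j-th kept token of that row
    n_exp = keep.sum(axis=1)
    rows, cols = np.nonzero(keep)
    # within-row running position
    pos = np.concatenate([np.arange(c) for c in n_exp]) if rows.size else rows
    out[rows, pos + 1] = tok[rows, cols]
    return out


def transfer_embeddings(
    source_embeddings: dict[str, np.ndarray],
    ortho,
    target_vocab: GeneVocabulary,
    rng_seed: int,
    init_scale: float = 0.02,
) -> np.ndarray:
    """Initialize a target embedding table from a source model via orthologs.

    ``source_embeddings`` maps source gene ids (and optionally the special
    token names ``"<cls>"`` etc.) to vectors of one shared dimensionality.
    Target genes whose ortholog exists in the source copy its vector
    bitwise; unmatched genes (and missing specials) are drawn fresh from a
    normal initializer with the given seed.
    """
    from .data import SPECIAL_TOKENS

    dims = {v.shape for v in source_embeddings.values()}
    if len(dims) > 1:
        raise ValidationError(f"source embeddings have mixed shapes: {dims}")
    if not dims:
        raise ValidationError("source embeddings are empty; dimensionality unknown")
    (d,) = dims.pop()
    rng = np.random.default_rng(rng_seed)
    out = rng.normal(0.0, init_scale, size=(target_vocab.size, d))
    for i, name in enumerate(SPECIAL_TOKENS):
        if name in source_embeddings:
            out[i] = source_embeddings[name]
    for gene in target_vocab.gene_ids:
        src = ortho.get(gene) if ortho is not None else None
        if src is not None and src in source_embeddings:
            out[target_vocab.token_of_gene(gene)] = source_embeddings[src]
    return out
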