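"""Masked-gene pretraining, then progressive-unfreezing fine-tuning.

The encoder is first trained to recover randomly hidden gene tokens (15%
of each cell's expressed genes) from an unlabeled corpus with built-in
gene co-occurrence structure.  A classifier head is then fine-tuned on
only 100 labeled cells: epoch 1 trains the head alone, and each later
epoch unfreezes one more encoder layer from the top.  Against a
from-scratch run, the pretrained start reaches a fixed validation loss in
fewer steps — the transfer benefit of self-supervision at small n.
"""

import numpy as np

from tissueformer import GeneVocabulary
from tissueformer.data import CellTable
from tissueformer.model import SingleCellEncoder, SingleCellModuleConfig
from tissueformer.tokenization import build_median_reference, tokenize_table_counts
from tissueformer.training import (
    PretrainConfig,
    finetune_single_cell_progressive,
    masked_gene_pretrain,
)


def module_corpus(n, rng, n_genes=24, n_modules=4):
    """Cells express one of four gene modules; the module is the label."""
    per = n_genes // n_modules
    labels = rng.integers(0, n_modules, size=n)
    lam = np.full((n, n_genes), 0.15)
    for m in range(n_modules):
        lam[labels == m, m * per:(m + 1) * per] = 3.0
    t = CellTable(counts=rng.poisson(lam),
                  gene_ids=[f"g{i}" for i in range(n_genes)],
                  xy=rng.uniform(0, 1, (n, 2)), brain_id=["b"] * n)
    return t, np.array([f"M{m}" for m in labels])


rng = np.random.default_rng(0)
corpus, _ = module_corpus(1500, rng)
labeled, labels = module_corpus(400, rng)
vocab = GeneVocabulary.from_genes(corpus.gene_ids)
ref = build_median_reference(corpus)
corpus_tok = tokenize_table_counts(corpus.counts, ref, vocab, 10)
lab_tok = tokenize_table_counts(labeled.counts, ref, vocab, 10)

cfg = SingleCellModuleConfig.tiny(10)
cfg.dropout = 0.0
for arm in ("pretrained", "scratch"):
    enc = SingleCellEncoder(cfg, vocab.size, np.random.default_rng(10))
    if arm == "pretrained":
        result = masked_gene_pretrain(
            enc, corpus_tok, vocab, PretrainConfig(epochs=4, batch_size=32, rng_seed=0)
        )
        print(f"masked loss: {result.loss_curve[0]:.2f} -> {result.loss_curve[-1]:.2f} "
              f"(uniform guess = {np.log(vocab.size):.2f})")
    _, metrics = finetune_single_cell_progressive(
        enc, lab_tok[:100], labels[:100], vocab, n_epochs=25, rng_seed=0,
        val_tokens=lab_tok[100:], val_labels=labels[100:], loss_target=0.45,
    )
    print(f"{arm:>10}: steps to reach val loss 0.45 = "
          f"{metrics[-1]['steps_to_target']}, "
          f"final val accuracy {metrics[-1]['val_accuracy']:.1%}")
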