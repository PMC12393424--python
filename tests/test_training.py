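import numpy as np
import pytest

from tissueformer.data import GeneVocabulary, ValidationError
from tissueformer.grouping import GroupSamplerConfig
from tissueformer.model import AggregationConfig, SingleCellModuleConfig, TissueFormer
from tissueformer.nn import cross_entropy
from tissueformer.nn import autograd as ag
from tissueformer.synthetic import generate_atlas, sample_cells
from tissueformer.tokenization import build_median_reference, tokenize_table_counts
from tissueformer.training import (
    PretrainConfig,
    TrainConfig,
    compute_class_weights,
    finetune_single_cell_progressive,
    masked_gene_pretrain,
    n_masked,
    sample_mask_positions,
    train_group_classifier,
)


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        np.testing.assert_array_equal(compute_class_weights([50, 50]).weights, [1.0, 1.0])

    def test_printed_factor_on_imbalanced_counts(self):
        spec = compute_class_weights([25, 75])
        np.testing.assert_allclose(spec.weights, [2.0, 2.0 / 3.0])

    def test_weight_count_identity_holds_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            counts = rng.integers(1, 1000, size=rng.integers(2, 12))
            spec = compute_class_weights(counts)
            assert (spec.weights * counts).sum() == pytest.approx(spec.M, rel=1e-12)
            assert (spec.weights * counts * spec.C == spec.M * np.ones(spec.C)).all() or (
                np.allclose(spec.weights * counts * spec.C, spec.M)
            )

    def test_zero_count_class_rejected(self):
        with pytest.raises(ValidationError):
            compute_class_weights([10, 0])

    def test_weighted_loss_equals_unweighted_on_balanced_batch(self):
        rng = np.random.default_rng(1)
        logits = ag.Tensor(rng.normal(size=(6, 2)))
        targets = np.array([0, 0, 0, 1, 1, 1])
        w = compute_class_weights([3, 3]).weights[targets]
        assert float(cross_entropy(logits, targets, w).data) == pytest.approx(
            float(cross_entropy(ag.Tensor(logits.data), targets).data)
        )


@pytest.fixture(scope="module")
def separable_task():
    """2 areas, 2 disjoint types, shared programs: label = type, trivially separable."""
    atlas = generate_atlas(2, 2, 20, signal_strength=1.0, rng_seed=0, library_size=100.0)
    table = sample_cells(atlas, 2500, rng_seed=1)
    vocab = GeneVocabulary.from_genes(table.gene_ids)
    ref = build_median_reference(table)
    tokens = tokenize_table_counts(table.counts, ref, vocab, context_window=10)
    return atlas, table, vocab, tokens


def make_tiny(vocab, n_classes, seed=0, drop=0.0, ctx=10):
    sc = SingleCellModuleConfig.tiny(ctx)
    sc.dropout = drop
    agg = AggregationConfig.tiny()
    agg.dropout = drop
    return TissueFormer(sc, agg, n_classes, vocab, seed=seed, class_labels=["A0", "A1"])


class TestGroupClassifierTraining:
    def test_reaches_high_accuracy_on_separable_task(self, separable_task):
        _, table, vocab, tokens = separable_task
        model = make_tiny(vocab, 2)
        scfg = GroupSamplerConfig(group_size=1, total_cells_per_batch=128, rng_seed=0)
        tcfg = TrainConfig(
            epochs=20, steps_per_epoch=15, rng_seed=0, n_val_groups=150,
            early_stopping_patience=20,
        )
        model, metrics = train_group_classifier(model, table, tokens, scfg, tcfg)
        assert max(m["val_accuracy"] for m in metrics) >= 0.99
        assert len(metrics) <= 20

    def test_zero_epoch_run_returns_model_unchanged(self, separable_task):
        _, table, vocab, tokens = separable_task
        model = make_tiny(vocab, 2)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        scfg = GroupSamplerConfig(group_size=1, total_cells_per_batch=64, rng_seed=0)
        model, metrics = train_group_classifier(
            model, table, tokens, scfg, TrainConfig(epochs=0)
        )
        assert metrics == []
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_identical_seeds_give_identical_metric_logs(self, separable_task):
        _, table, vocab, tokens = separable_task
        logs = []
        for _ in range(2):
            model = make_tiny(vocab, 2, seed=3)
            scfg = GroupSamplerConfig(group_size=2, total_cells_per_batch=64, rng_seed=3)
            tcfg = TrainConfig(epochs=2, steps_per_epoch=5, rng_seed=3, n_val_groups=40)
            _, metrics = train_group_classifier(model, table, tokens, scfg, tcfg)
            logs.append(metrics)
        assert logs[0] == logs[1]

    def test_class_balancing_raises_minority_recall(self):
        # 2 areas with a 9:1 cell imbalance; same seed with and without weights
        atlas = generate_atlas(2, 4, 30, signal_strength=0.55, rng_seed=5, library_size=80.0)
        table = sample_cells(atlas, 4000, rng_seed=6)
        # make area A1 rare by dropping most of its cells
        areas = np.asarray(table.area_label)
        rng = np.random.default_rng(7)
        keep = np.ones(table.n_cells, bool)
        a1 = np.nonzero(areas == "A1")[0]
        keep[rng.choice(a1, size=int(0.85 * len(a1)), replace=False)] = False
        table = table.subset(np.nonzero(keep)[0])
        vocab = GeneVocabulary.from_genes(table.gene_ids)
        ref = build_median_reference(table)
        tokens = tokenize_table_counts(table.counts, ref, vocab, 10)

        recalls = {}
        for balanced in (False, True):
            model = make_tiny(vocab, 2, seed=8)
            scfg = GroupSamplerConfig(group_size=1, total_cells_per_batch=128, rng_seed=8)
            tcfg = TrainConfig(
                epochs=6, steps_per_epoch=15, rng_seed=8, class_balanced=balanced,
                n_val_groups=200, early_stopping_patience=10,
            )
            model, _ = train_group_classifier(model, table, tokens, scfg, tcfg)
            val_areas = np.asarray(table.area_label).astype(str)
            idx = np.nonzero(val_areas == "A1")[0][:150]
            preds = model.predict_groups(tokens[idx][:, None, :])
            recalls[balanced] = (np.array(model.class_labels)[preds] == "A1").mean()
        assert recalls[True] >= recalls[False]

    def test_divergent_loss_aborts_with_diagnostic(self, separable_task):
        _, table, vocab, tokens = separable_task
        model = make_tiny(vocab, 2)
        model.head.weight.data[:] = np.nan
        scfg = GroupSamplerConfig(group_size=1, total_cells_per_batch=32, rng_seed=0)
        with pytest.raises(RuntimeError, match="divergent"):
            train_group_classifier(
                model, table, tokens, scfg, TrainConfig(epochs=1, steps_per_epoch=2)
            )


class TestMaskedPretraining:
    def test_rounding_rule(self):
        assert n_masked(20, 0.15) == 3
        assert n_masked(1, 0.15) == 1  # floor of one
        assert n_masked(10, 0.15) == 2  # round half up: 1.5 -> 2
        assert n_masked(0, 0.15) == 0

    def test_pad_and_cls_positions_never_masked(self, small_vocab, small_tokens):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            row = small_tokens[rng.integers(0, len(small_tokens))]
            pos = sample_mask_positions(row, small_vocab, 0.15, rng)
            assert 0 not in pos
            assert all(row[p] not in (small_vocab.pad_id, small_vocab.cls_id) for p in pos)

    def test_initial_loss_near_log_vocab_size(self, small_vocab, small_tokens):
        from tissueformer.model import SingleCellEncoder

        enc = SingleCellEncoder(
            SingleCellModuleConfig.tiny(12), small_vocab.size, np.random.default_rng(0)
        )
        cfg = PretrainConfig(epochs=1, batch_size=64, rng_seed=0)
        result = masked_gene_pretrain(enc, small_tokens[:64], small_vocab, cfg)
        assert result.loss_curve[0] == pytest.approx(np.log(small_vocab.size), rel=0.1)

    def test_empty_corpus_rejected(self, small_vocab):
        from tissueformer.model import SingleCellEncoder

        enc = SingleCellEncoder(
            SingleCellModuleConfig.tiny(12), small_vocab.size, np.random.default_rng(0)
        )
        empty = np.full((5, 13), small_vocab.pad_id)
        empty[:, 0] = small_vocab.cls_id
        with pytest.raises(ValidationError):
            masked_gene_pretrain(enc, empty, small_vocab, PretrainConfig())

    def test_learns_deterministic_cooccurrence(self):
        """Gene B always accompanies gene A: masked accuracy beats chance."""
        from tissueformer.model import SingleCellEncoder

        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(12)]
        vocab = GeneVocabulary.from_genes(genes)
        # cells express a pair (2k, 2k+1) plus two random other genes
        rows = []
        for _ in range(400):
            k = rng.integers(0, 6)
            others = rng.choice(np.setdiff1d(np.arange(12), [2 * k, 2 * k + 1]), 2, replace=False)
            toks = [vocab.cls_id, 3 + 2 * k, 3 + 2 * k + 1, 3 + others[0], 3 + others[1]]
            rows.append(toks + [vocab.pad_id] * 2)
        corpus = np.array(rows)
        cfg = SingleCellModuleConfig.tiny(6)
        cfg.dropout = 0.0  # nothing to regularize at this scale
        enc = SingleCellEncoder(cfg, vocab.size, np.random.default_rng(2))
        enc_cfg = PretrainConfig(epochs=25, batch_size=32, rng_seed=3)
        result = masked_gene_pretrain(enc, corpus, vocab, enc_cfg)
        # probe: mask the partner gene, check recovery accuracy
        correct = 0
        probes = 100
        for i in range(probes):
            row = corpus[i].copy()
            target = row[2]
            row[2] = vocab.mask_id
            hidden = enc.hidden_states(row[None], vocab.pad_id)
            logits = result.mlm_head(ag.take_positions(hidden, [0], [2])).data[0]
            gene_logits = logits[vocab.n_special :]
            if int(np.argmax(gene_logits)) + vocab.n_special == target:
                correct += 1
        assert correct / probes > 3 * (1 / 12)


class TestProgressiveFinetuning:
    @pytest.fixture(scope="class")
    def toy(self):
        atlas = generate_atlas(2, 2, 16, 1.0, rng_seed=0, library_size=150.0)
        table = sample_cells(atlas, 600, rng_seed=1)
        vocab = GeneVocabulary.from_genes(table.gene_ids)
        ref = build_median_reference(table)
        tokens = tokenize_table_counts(table.counts, ref, vocab, 10)
        labels = np.asarray(table.area_label).astype(str)
        return vocab, tokens, labels

    def _fresh_encoder(self, vocab, seed=0):
        from tissueformer.model import SingleCellEncoder

        cfg = SingleCellModuleConfig.tiny(10)
        cfg.dropout = 0.0
        return SingleCellEncoder(cfg, vocab.size, np.random.default_rng(seed))

    def test_first_epoch_trains_head_only(self, toy):
        vocab, tokens, labels = toy
        enc = self._fresh_encoder(vocab)
        before = {k: v.copy() for k, v in enc.state_dict().items()}
        _, metrics = finetune_single_cell_progressive(
            enc, tokens[:128], labels[:128], vocab, n_epochs=1, rng_seed=0
        )
        for k, v in enc.state_dict().items():
            np.testing.assert_array_equal(v, before[k])
        assert metrics[0]["n_unfrozen_layers"] == 0

    def test_unfrozen_layer_count_schedule(self, toy):
        vocab, tokens, labels = toy
        enc = self._fresh_encoder(vocab)
        _, metrics = finetune_single_cell_progressive(
            enc, tokens[:64], labels[:64], vocab, n_epochs=5, rng_seed=0
        )
        assert [m["n_unfrozen_layers"] for m in metrics] == [0, 1, 2, 2, 2]

    def test_reaches_high_accuracy_on_separable_labels(self, toy):
        vocab, tokens, labels = toy
        enc = self._fresh_encoder(vocab, seed=3)
        clf, metrics = finetune_single_cell_progressive(
            enc, tokens[:400], labels[:400], vocab, n_epochs=12,
            rng_seed=3, val_tokens=tokens[400:], val_labels=labels[400:],
        )
        assert max(m["val_accuracy"] for m in metrics) >= 0.99

    def test_zero_epochs_rejected(self, toy):
        vocab, tokens, labels = toy
        with pytest.raises(ValidationError):
            finetune_single_cell_progressive(
                self._fresh_encoder(vocab), tokens[:32], labels[:32], vocab, n_epochs=0
            )
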