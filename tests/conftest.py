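import numpy as np
import pandas as pd
import pytest

from tissueformer.data import CellTable, GeneVocabulary
from tissueformer.synthetic import generate_atlas, sample_cells
from tissueformer.tokenization import build_median_reference, tokenize_table_counts


@pytest.fixture
def tiny_table() -> CellTable:
    """8 cells, 4 genes, 2 areas, handmade — small enough to verify by eye."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 6, size=(8, 4))
    counts[0] = [0, 3, 1, 5]
    return CellTable(
        counts=counts,
        gene_ids=["g0", "g1", "g2", "g3"],
        xy=np.column_stack([np.arange(8.0), np.zeros(8)]),
        brain_id=pd.Categorical(["b1"] * 8),
        type_h2=pd.Categorical(["X", "X", "Y", "Y", "X", "Y", "X", "Y"]),
        type_h3=pd.Categorical(["X.a", "X.b", "Y.a", "Y.a", "X.a", "Y.b", "X.b", "Y.a"]),
        area_label=pd.Categorical(["A", "A", "A", "B", "B", "B", "A", "B"]),
        depth=np.linspace(0, 1, 8),
    )


@pytest.fixture(scope="session")
def small_atlas():
    return generate_atlas(
        n_areas=3, n_types=5, n_genes=30, signal_strength=0.8,
        composition_only=True, rng_seed=11, library_size=120.0,
    )


@pytest.fixture(scope="session")
def small_table(small_atlas) -> CellTable:
    return sample_cells(small_atlas, 3000, rng_seed=12)


@pytest.fixture(scope="session")
def small_vocab(small_table) -> GeneVocabulary:
    return GeneVocabulary.from_genes(small_table.gene_ids)


@pytest.fixture(scope="session")
def small_tokens(small_table, small_vocab):
    ref = build_median_reference(small_table)
    return tokenize_table_counts(small_table.counts, ref, small_vocab, context_window=12)
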