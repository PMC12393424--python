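"""Render a smooth area map, a hex gene density, and a perceptual colormap.

A trained model labels every cell (each cell seeds its own column group);
an RBF-kernel support vector classifier then turns the labeled point
cloud into a smooth pixel map with low-density regions masked.  Gene
densities are hex-binned after within-cell normalization, and cell types
get colors whose perceptual (CIELUV) distances track the correlation
structure of their pseudobulk profiles.
"""

import numpy as np

from tissueformer import (
    AggregationConfig,
    GeneVocabulary,
    GroupSamplerConfig,
    SingleCellModuleConfig,
    TissueFormer,
    TrainConfig,
    build_median_reference,
    generate_atlas,
    predict_cells_as_seeds,
    sample_cells,
    tokenize_table_counts,
    train_group_classifier,
)
from tissueformer.mapping import (
    MapSmootherConfig,
    hex_gene_density,
    make_type_colormap,
    smooth_area_map,
)
from tissueformer.training import per_brain_split

atlas = generate_atlas(4, 8, 104, 0.8, True, rng_seed=0)
table = sample_cells(atlas, 20_000, rng_seed=1)
vocab = GeneVocabulary.from_genes(table.gene_ids)
ref = build_median_reference(table.subset(np.arange(4_000)))
tokens = tokenize_table_counts(table.counts, ref, vocab, 16)
train_mask, val_mask = per_brain_split(table, 0.1, 0)

sc, agg = SingleCellModuleConfig.tiny(16), AggregationConfig.tiny()
sc.dropout = agg.dropout = 0.0
model = TissueFormer(sc, agg, 4, vocab, seed=0,
                     class_labels=[f"A{i}" for i in range(4)])
model, _ = train_group_classifier(
    model, table, tokens,
    GroupSamplerConfig(group_size=16, total_cells_per_batch=256, rng_seed=0),
    TrainConfig(epochs=3, steps_per_epoch=80, rng_seed=0, n_val_groups=80,
                early_stopping_patience=99),
    train_mask=train_mask, val_mask=val_mask,
)

cells = np.random.default_rng(5).choice(np.nonzero(val_mask)[0], 2000, replace=False)
preds = predict_cells_as_seeds(model, table, tokens, N=16, cell_indices=cells)
amap = smooth_area_map(table.xy[cells], preds,
                       MapSmootherConfig(gamma=30.0, grid_resolution=96))
unmasked = (~amap.mask).sum()
print(f"area map: {amap.labels.shape[0]}x{amap.labels.shape[1]} pixels, "
      f"{unmasked} unmasked, labels {amap.label_names}")
print("label at domain center:", amap.label_at(2.0, 0.5))

centers, dens = hex_gene_density(table, table.gene_ids[0], hex_size=0.15)
print(f"hex density of {table.gene_ids[0]}: {len(centers)} occupied hexes, "
      f"mean normalized expression {np.nanmean(dens):.4f}")

colors = make_type_colormap(atlas.programs, atlas.type_names, rng_seed=0)
first = atlas.type_names[0]
print(f"type {first} color (RGB): {tuple(round(c, 3) for c in colors[first])}")
# Similar expression programs receive perceptually similar colors.
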