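# Methods

## Model

TissueFormer is a two-stage transformer for classifying an unordered group
of single-cell RNA profiles. The single-cell stage is a BERT-style encoder
over rank-value token sentences (defaults: 12 layers, hidden 512, 8 heads,
context window 2048 genes, ReLU activations, additive sinusoidal
positional encoding); the state of the leading `<cls>` token is the cell
embedding. The aggregation stage is a transformer over the cell embeddings
of a group with **no positional encoding** — its outputs are therefore
equivariant to cell order — followed by average pooling over cells and a
linear classifier, making the group logits order-invariant by
construction. When the two stages have different widths a learned affine
adapter maps cell embeddings between them. Both stages use post-norm layer
placement (LayerNorm after each residual sum), 4× feed-forward widths, and
dropout 0.1 during training (0 at evaluation), all configurable. The
aggregation stage uses GELU activations and 8 heads by default, mirroring
the single-cell stage where unstated.

Assumptions: all cells of a group share one sample (brain); the group's
label is a function of the multiset of member profiles; pad positions
within a cell are masked out of attention and never reach the aggregation
stage.

A `tiny` preset (2 layers / 32 dims / 4 heads per stack) preserves every
contract — permutation invariance, pad invariance, gradient bottleneck —
and is what the tests and the acceptance script train.

## Tokenization

Counts are divided by the cell's total, then elementwise by a fixed
per-gene median reference; the expressed genes are sorted by descending
normalized value and truncated to the context window, keeping the
top-ranked genes. Sentences have fixed length `context + 1`:
`[<cls>, g(1), …, g(k), <pad>, …]`. Zero-count rows tokenize to
`[<cls>, <pad>, …]` with a logged warning. Choices made where a convention
was needed:

- ties in normalized value break by ascending gene-token id (stable sort) —
  deterministic and checkable against an exact `Fraction`-arithmetic
  oracle, which the tests do on 1,000 random vectors including ties and
  zeros;
- the reference median of a gene is taken over the cells in which it is
  nonzero (a zero median would make the normalization undefined); genes
  never expressed in the reference carry a NaN sentinel and are dropped
  before ranking, so vocabulary/reference mismatches degrade gracefully;
- the median reference is always an explicit input and never silently
  recomputed, since reusing a pretraining-corpus reference is often
  preferable to refitting.

## Group construction

A columnar group is the seed cell plus the N−1 same-brain cells nearest in
the planar (x, y) coordinates; homogeneous groups additionally restrict
members to the seed's coarse (H2) type. Neighbor search uses a KD-tree
with an exact-match contract: results equal a brute-force all-pairs
distance sort, with the seed always ranked first at distance zero and
remaining ties broken by ascending cell index. Groups are labeled by the
modal area of their members, ties broken lexicographically. The batch
sampler draws seed cells uniformly at random from the training split and
yields `total_cells_per_batch / group_size` groups per batch,
deterministically given its seed. Validation splits are random per-brain
cell partitions; under the default `seed_only` policy groups seeded from
one split may include neighbors from the other (the spatial reality of
columnar groups), while `strict_members` confines members to the split —
the right protocol whenever train and evaluation sets must not share
cells (see "Benchmark protocol" below).

## Training

- Group classification: cross-entropy over group logits; Adam with
  decoupled weight decay (0.01), learning rate 1e-3, linear decay after a
  10% warmup. Optional class balancing weights each example by
  `w_i = M / (C · M_i)` (M training examples, C classes, M_i per class),
  which leaves a perfectly balanced loss unchanged and satisfies
  `Σ w_i M_i = M` exactly. Weight decay applies only to weight matrices —
  not embeddings, LayerNorm gains or biases — which also preserves the
  invariant that embedding rows of genes absent from a batch are untouched
  by a step.
- Masked-gene pretraining: per cell, `round(0.15 · n_expressed)` gene
  positions (minimum 1; round half up) are replaced by `<mask>` (always,
  by default; the 80/10/10 BERT mix is a config option) and a linear
  vocabulary head is trained to recover the original tokens. Pads and the
  `<cls>` slot are never maskable. Output heads are zero-initialized, so
  the initial masked loss is exactly log(vocabulary size).
- Progressive fine-tuning of a single-cell classifier: epoch 1 trains the
  head only; each later epoch unfreezes one more encoder layer from the
  top (embeddings stay frozen); batch size 32, learning rate 5e-4.
- "Convergence" is operationalized as early stopping on validation loss
  with patience 3 plus a hard epoch cap; `max_steps` supports
  matched-budget comparisons.

Numerics: the `tissueformer.nn` engine is reverse-mode autodiff over
float64 numpy arrays with fused, numerically stable softmax / layer-norm /
cross-entropy kernels, gradient-checked against central finite
differences. Linear layers use fan-in-scaled normal initialization
(std = 1/√fan_in); token embeddings are scaled by √hidden_dim before the
unit-amplitude sinusoidal positions are added (the classic transformer
convention) — at tiny widths both choices are what keeps token identity
from being drowned out and training from stalling. Training is
deterministic given seeds under single-threaded BLAS.

## Synthetic data

The generator emulates a 2D tissue of contiguous labeled areas with
area-specific cell-type compositions, shared per-type expression programs,
and Poisson (optionally negative-binomial, for overdispersed panels) count
noise. Areas are equal-width vertical strips — deliberately unrealistic
geometry chosen so boundary fractions and compositions stay analytically
controllable. Compositions interpolate between a shared uniform baseline
(signal 0) and disjoint per-area type preferences (signal 1). With
`composition_only=True` programs are area-independent, a single cell is
informative only through its type, and the exact Bayes accuracy of
classifying a group from its N type draws is computable (enumeration for
small problems, Monte Carlo otherwise; ties go to the lowest area index,
so identical compositions give exactly chance). Defaults: library size 200
counts/cell, Poisson noise. What this generator does **not** model:
segmentation errors, probe dropout, spatial expression gradients within an
area, batch effects between brains, realistic area geometry — so passing
tests bound correctness of the machinery, not performance on real tissue.

The *mean-matched* variant builds two areas with identical expected
pseudobulk but disjoint type alphabets: each area draws uniformly from its
own 4 type pairs `m(1 ± a·σ)` with relative amplitude a = 0.8 and balanced
±1 sign patterns σ (m-weighted sums near zero, greedy partition). Pairs
cancel within each area, so class-conditional means match exactly; and
because the *per-gene magnitude multisets* are identical across areas, the
per-gene marginal distribution of a group's mean expression is the same in
both classes — nothing leaks through a nonlinear per-gene transform such
as log1p. Only the cross-gene composition structure differs, which
aggregate features cannot represent but a cell-level model can.

## Benchmark protocol

Group-feature baselines (pseudobulk mean with log1p + train-fitted
z-score; normalized H3 type histograms) are classified with logistic
regression (lbfgs, no regularization) or a random forest (200 trees,
depth 15, 33% features per split, min samples 5/2). For baseline
comparisons, train and evaluation groups are sampled with
`strict_members` from disjoint cell splits: an unregularized
104-feature classifier otherwise partially memorizes the cells shared
between overlapping spatial groups, inflating its measured accuracy by
5–15 points on tasks with no aggregate signal. The learned model is
trained and evaluated under the same protocol in those comparisons.

Training protocol across group sizes: the N=1 model trains from scratch;
larger-N models load its single-cell encoder through the checkpoint
interface and train end-to-end from there. This is the pretrained-module
workflow the architecture is built around, and it removes the long
optimization plateau the aggregation stack otherwise shows before cell
embeddings become informative.

## Problem sizes and tolerances in the shipped checks

The accuracy-versus-group-size study uses 6 areas / 10 types / 104 genes /
signal 0.7 / 50,000 cells, tiny models with context 16 and no dropout
(online group sampling cannot overfit at this scale), 240 training steps
at N=1 and 160 warm-started steps at N ∈ {4, 16, 64}, 256 cells per batch,
and, per (N, seed) over 3 seeds, 1,500 evaluation groups at N ∈ {1, 4}
(where binomial noise is largest) and 500 at N ∈ {16, 64} (where accuracy
saturates and the noise is tiny). Monotonicity of the mean accuracy in N
is asserted with a 1-point allowance, and the ceiling comparison with a
2-point band plus twice the binomial standard error of the evaluation:
near the saturated ceiling the estimate's Monte-Carlo resolution is a few
tenths of a point, and excursions within it are measurement noise, not a
trend reversal or a ceiling violation.
Permutation invariance is checked to 1e-4 relative over 100 permutations
of 20 random groups (the architecture delivers ~1e-16). The mean-matched
study uses 20,000 cells, a 50/50 strict split, N=32, and 300–400
evaluation groups. The pretraining-transfer study uses a 4-module
co-occurrence corpus (1,500 unlabeled, 100 labeled, 300 validation cells)
and compares steps to reach validation loss 0.45, with runs that never
reach it scored at the step cap. Map fidelity fits the RBF-SVC smoother
(γ = 30 on the unit-strip domain; the 1e-5 default suits micron-scale
flatmap coordinates; C = 1) on 3,000 labeled cells and scores pixels at
least two pixel-widths from true boundaries on a 128-pixel grid.

## Map rendering and colors

`smooth_area_map` fits an SVC with RBF kernel to per-cell predicted labels
and evaluates it at pixel centers — each pixel is effectively a
proximity-weighted vote of nearby cells — masking pixels with fewer than 3
cells within a configurable radius (default three pixel widths). The grid
defaults to 512 pixels along the longer axis. Hex gene densities average
within-cell total-normalized expression per hexagon, making the map
invariant to per-cell library size. The type colormap embeds the pairwise
correlation distances (1 − Pearson r) of type pseudobulk vectors into 3D
with metric MDS (classical init, deterministic per seed), collapses
zero-distance duplicates so identical types get identical colors, reads
the embedding as CIELUV coordinates after a rigid orientation fix (axes
flipped so the first type sits in the positive octant) and a single
uniform rescale into a conservative gamut box (uniform, not per-axis, so
distance ranks survive), and converts LUV → RGB with per-channel clipping.
Distances are meaningful in LUV; the RGB conversion is for display.

## Known limitations

- The numpy engine is single-threaded and float64; paper-scale
  configurations construct and run correctly but are not practical to
  train here — the tiny presets are the supported training scale.
- The Bayes oracle requires `composition_only` (the type multiset must be
  a sufficient statistic); there is no closed ceiling when programs vary
  by area.
- h5ad round-trips preserve the recognized obs columns, not arbitrary
  metadata; counts must be integral within 1e-6.
- The SVC smoother's γ must match the coordinate scale; no automatic
  bandwidth selection is attempted.
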