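"""Map rendering: smooth area maps, hex-binned gene densities, type colors.

``smooth_area_map`` turns per-cell predicted labels into a pixel map by
fitting an RBF-kernel support vector classifier to the labeled positions
and evaluating it at pixel centers — effectively coloring each pixel by a
weighted vote of the surrounding cells' predictions.  Pixels with too few
nearby cells are masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.svm import SVC

from .data import CellTable, ValidationError


@dataclass
class MapSmootherConfig:
    """RBF-SVC smoother settings.

    ``gamma`` is the RBF width parameter (its natural scale depends on the
    coordinate units; 1e-5 suits flatmap-style micron-scale coordinates)
    and ``C`` the margin-regularization constant.
    """

    gamma: float = 1e-5
    C: float = 1.0
    grid_resolution: int = 512
    min_cells: int = 3
    mask_radius: float | None = None  # default: 3 pixel widths

    def __post_init__(self):
        if self.gamma <= 0 or self.C <= 0:
            raise ValidationError("gamma and C must be positive")


@dataclass
class AreaMap:
    """Categorical pixel grid with a low-density mask."""

    labels: np.ndarray  # [H, W] int codes, -1 where masked
    label_names: list[str]
    bbox: tuple[float, float, float, float]  # x0, y0, x1, y1
    pixel_size: float
    mask: np.ndarray  # [H, W] bool, True = masked (low density)

    def label_at(self, x: float, y: float) -> str | None:
        x0, y0, _, _ = self.bbox
        j = int((x - x0) / self.pixel_size)
        i = int((y - y0) / self.pixel_size)
        if not (0 <= i < self.labels.shape[0] and 0 <= j < self.labels.shape[1]):
            return None
        if self.mask[i, j]:
            return None
        return self.label_names[self.labels[i, j]]


def smooth_area_map(
    positions: np.ndarray,
    predicted_labels: np.ndarray,
    cfg: MapSmootherConfig | None = None,
) -> AreaMap:
    """Fit an RBF-SVC to labeled cell positions and rasterize its decision.

    The pixel grid spans the bounding box of the positions with
    ``cfg.grid_resolution`` pixels along the longer axis.  Pixels with
    fewer than ``cfg.min_cells`` cells within ``cfg.mask_radius`` (default
    three pixel widths) are masked.  A single-label input yields a constant
    map.
    """
    cfg = cfg or MapSmootherConfig()
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or len(positions) == 0:
        raise ValidationError("positions must be a nonempty (n, 2) array")
    labels = np.asarray(predicted_labels).astype(str)
    names = sorted(np.unique(labels).tolist())

    x0, y0 = positions.min(axis=0)
    x1, y1 = positions.max(axis=0)
    long_axis = max(x1 - x0, y1 - y0)
    px = long_axis / cfg.grid_resolution
    W = max(1, int(np.ceil((x1 - x0) / px)))
    H = max(1, int(np.ceil((y1 - y0) / px)))
    xs = x0 + (np.arange(W) + 0.5) * px
    ys = y0 + (np.arange(H) + 0.5) * px
    gx, gy = np.meshgrid(xs, ys)
    pixels = np.column_stack([gx.ravel(), gy.ravel()])

    if len(names) == 1:
        codes = np.zeros(H * W, dtype=int)
    else:
        svc = SVC(kernel="rbf", gamma=cfg.gamma, C=cfg.C)
        svc.fit(positions, labels)
        pred = svc.predict(pixels)
        lut = {n: i for i, n in enumerate(names)}
        codes = np.array([lut[p] for p in pred])

    radius = cfg.mask_radius if cfg.mask_radius is not None else 3 * px
    tree = cKDTree(positions)
    n_near = tree.query_ball_point(pixels, r=radius, return_length=True)
    mask = (n_near < cfg.min_cells).reshape(H, W)
    grid = codes.reshape(H, W)
    grid = np.where(mask, -1, grid)
    return AreaMap(
        labels=grid, label_names=names, bbox=(x0, y0, x1, y1), pixel_size=px, mask=mask
    )


# ---------------------------------------------------------------------------
# Hex-binned normalized gene density
# ---------------------------------------------------------------------------

def hex_gene_density(
    table: CellTable,
    gene: str,
    hex_size: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-hex mean of within-cell total-normalized expression of one gene.

    Each cell's transcription is first normalized by its total counts, so
    the map is invariant to per-cell library size — the point being to
    decouple expression patterns from unequal spatial sampling.  Returns
    ``(hex_centers [K, 2], values [K])`` over occupied hexes.
    """
    if gene not in table.gene_ids:
        raise ValidationError(f"unknown gene {gene!r}")
    gi = table.gene_ids.index(gene)
    counts = table.counts_dense().astype(float)
    totals = counts.sum(axis=1)
    normed = np.divide(
        counts[:, gi], totals, out=np.zeros(len(totals)), where=totals > 0
    )
    centers, idx = _hex_assign(table.xy, hex_size)
    K = len(centers)
    sums = np.bincount(idx, weights=normed, minlength=K)
    ns = np.bincount(idx, minlength=K)
    return centers, sums / ns


def _hex_assign(xy: np.ndarray, size: float) -> tuple[np.ndarray, np.ndarray]:
    """Assign points to a pointy-top hex grid; returns (centers, hex index)."""
    x, y = xy[:, 0], xy[:, 1]
    q = (np.sqrt(3) / 3 * x - 1.0 / 3 * y) / size
    r = (2.0 / 3 * y) / size
    qi, ri = _cube_round(q, r)
    keys, idx = np.unique(np.column_stack([qi, ri]), axis=0, return_inverse=True)
    cx = size * np.sqrt(3) * (keys[:, 0] + keys[:, 1] / 2.0)
    cy = size * 1.5 * keys[:, 1]
    return np.column_stack([cx, cy]), idx


def _cube_round(q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = -q - r
    qi, ri, si = np.round(q), np.round(r), np.round(s)
    dq, dr, ds = np.abs(qi - q), np.abs(ri - r), np.abs(si - s)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    qi = np.where(fix_q, -ri - si, qi)
    ri = np.where(fix_r, -qi - si, ri)
    return qi.astype(int), ri.astype(int)


# ---------------------------------------------------------------------------
# Perceptual cell-type colormap (MDS -> LUV)
# ---------------------------------------------------------------------------

def make_type_colormap(
    type_pseudobulk: np.ndarray,
    type_names: list[str] | None = None,
    rng_seed: int = 0,
    return_luv: bool = False,
):
    """Assign each cell type an RGB color whose perceptual distance tracks
    expression similarity.

    Pairwise correlation distances (1 - Pearson r) between the types'
    pseudobulk vectors are embedded into 3D with metric MDS; the embedding
    is read as coordinates of the perceptually uniform CIELUV space after a
    rigid orientation fix and a single uniform rescale into the gamut, then
    converted to RGB (out-of-gamut channels clipped).  Deterministic per
    seed; identical pseudobulk vectors receive identical colors.  With
    ``return_luv`` the LUV coordinates are returned alongside the RGB map
    (color distances are meaningful in LUV, not in RGB).
    """
    from sklearn.manifold import MDS
    from skimage.color import luv2rgb

    x = np.asarray(type_pseudobulk, dtype=float)
    T = len(x)
    if T < 2:
        raise ValidationError("need at least two types")
    if type_names is None:
        type_names = [f"type{i}" for i in range(T)]
    sd = x.std(axis=1)
    for i, s in enumerate(sd):
        if s == 0:
            raise ValidationError(
                f"type {type_names[i]!r} has a constant pseudobulk vector; "
                "its correlation distance is undefined"
            )
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)

    # collapse zero-distance duplicates so identical types get bitwise
    # identical colors despite the iterative MDS solver
    rep = np.arange(T)
    for i in range(T):
        for j in range(i):
            if dist[i, j] < 1e-12:
                rep[i] = rep[j]
                break
    uniq = np.unique(rep)
    sub = dist[np.ix_(uniq, uniq)]

    mds = MDS(
        n_components=3,
        metric="precomputed",
        metric_mds=True,
        init="classical_mds",
        n_init=1,
        random_state=rng_seed,
        normalized_stress=False,
    )
    emb_u = mds.fit_transform(sub) if len(uniq) > 1 else np.zeros((1, 3))
    if emb_u.shape[1] < 3:  # rank-limited solutions for very few types
        emb_u = np.pad(emb_u, ((0, 0), (0, 3 - emb_u.shape[1])))
    lookup = {u: k for k, u in enumerate(uniq)}
    emb = emb_u[[lookup[r] for r in rep]]
    emb = emb - emb.mean(axis=0)
    # orientation fix: flip axes so the first type sits in the positive octant
    for ax in range(3):
        if emb[0, ax] < 0:
            emb[:, ax] *= -1.0

    # uniform rescale into a conservative LUV gamut box (preserves distance
    # ranks, unlike per-axis scaling), then shift L to be positive
    half_ranges = np.array([30.0, 60.0, 60.0])  # L spread, u, v
    maxabs = np.abs(emb).max() or 1.0
    scale = half_ranges.min() / maxabs
    luv = emb * scale
    luv[:, 0] += 55.0  # center lightness

    rgb = luv2rgb(luv[None, :, :])[0]
    rgb = np.clip(rgb, 0.0, 1.0)
    colors = {
        name: tuple(float(v) for v in rgb[i]) for i, name in enumerate(type_names)
    }
    if return_luv:
        return colors, {name: luv[i].copy() for i, name in enumerate(type_names)}
    return colors
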