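"""Construction and sampling of labeled cell groups.

A "columnar" group is the set of N cells in a seed cell's brain closest to
the seed in the planar (flatmap XY) coordinates — the spatial analogue of a
cortical column.  Homogeneous groups additionally restrict members to the
seed's coarse (H2) cell type.  Groups are labeled by the modal area of
their members and streamed as training batches without duplicating cell
data.

Neighbor search uses a KD-tree with an exact-match contract: results equal
a brute-force all-pairs-distance oracle, with distance ties at the group
boundary broken by ascending cell index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .data import CellTable, ValidationError


@dataclass
class CellGroup:
    """An unordered set of same-brain cells sharing one label."""

    member_indices: np.ndarray
    seed_index: int
    label: object | None
    brain_id: object

    def __post_init__(self):
        self.member_indices = np.asarray(self.member_indices, dtype=np.int64)
        if self.seed_index not in self.member_indices:
            raise ValidationError("seed must be a member of its group")

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class GroupSamplerConfig:
    """How training batches of groups are drawn.

    ``group_size`` is N, the cells per group; ``total_cells_per_batch`` is
    the batch size counted in cells, so each batch holds
    ``total_cells_per_batch / group_size`` groups.
    """

    group_size: int = 16
    total_cells_per_batch: int = 4096
    rng_seed: int = 0
    homogeneous_level: str | None = None  # None or "h2"
    split_policy: str = "seed_only"  # or "strict_members"

    def __post_init__(self):
        if self.group_size < 1 or self.total_cells_per_batch < 1:
            raise ValidationError("group_size and batch size must be positive")
        if self.total_cells_per_batch % self.group_size:
            raise ValidationError(
                f"total_cells_per_batch={self.total_cells_per_batch} is not "
                f"divisible by group_size={self.group_size}"
            )
        if self.homogeneous_level not in (None, "none", "h2"):
            raise ValidationError("homogeneous_level must be None or 'h2'")

    @property
    def groups_per_batch(self) -> int:
        return self.total_cells_per_batch // self.group_size


def _exact_knn(points: np.ndarray, cand_pool: np.ndarray, seeds: np.ndarray, N: int) -> np.ndarray:
    """Indices (into ``cand_pool``) of the N nearest pool points per seed.

    The seed itself sits at distance 0 and always ranks first; other ties
    (including the tie at the N-th slot) resolve to the lower cell index.
    A KD-tree answers the bulk; rows whose boundary distance is tied are
    re-answered by exhaustive distance sort so the result matches the
    brute-force oracle exactly.
    """
    pool_pts = points[cand_pool]
    tree = cKDTree(pool_pts)
    k = min(N + 1, len(cand_pool))
    d, idx = tree.query(points[seeds], k=k)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    out = np.empty((len(seeds), N), dtype=np.int64)
    if k > N:
        ambiguous = d[:, N - 1] == d[:, N]
    else:
        ambiguous = np.zeros(len(seeds), dtype=bool)
    # co-located points can evict the seed from the KD-tree's arbitrary
    # tie order; those rows are re-answered exactly as well
    picked = cand_pool[idx[:, :N]]
    ambiguous |= ~(picked == seeds[:, None]).any(axis=1)
    easy = ~ambiguous
    out[easy] = np.sort(picked[easy], axis=1)
    for row in np.nonzero(ambiguous)[0]:
        sq = ((pool_pts - points[seeds[row]]) ** 2).sum(axis=1)
        not_seed = cand_pool != seeds[row]
        order = np.lexsort((cand_pool, not_seed, sq))  # distance, seed-first, index
        out[row] = np.sort(cand_pool[order[:N]])
    return out


def _candidate_pool(
    table: CellTable,
    seed_index: int,
    level: str | None,
    mask: np.ndarray | None,
) -> np.ndarray:
    same_brain = np.asarray(table.brain_id) == np.asarray(table.brain_id)[seed_index]
    pool = same_brain
    if level == "h2":
        if table.type_h2 is None:
            raise ValidationError("homogeneous grouping requires type_h2 labels")
        types = np.asarray(table.type_h2)
        pool = pool & (types == types[seed_index])
    if mask is not None:
        pool = pool & np.asarray(mask, dtype=bool)
        pool[seed_index] = True  # the seed always belongs to its own group
    return np.nonzero(pool)[0]


def build_column_group(
    table: CellTable,
    seed_index: int,
    N: int,
    mask: np.ndarray | None = None,
) -> CellGroup:
    """The N same-brain cells nearest the seed in the XY plane (seed included)."""
    pool = _candidate_pool(table, seed_index, None, mask)
    brain = np.asarray(table.brain_id)[seed_index]
    if len(pool) < N:
        raise ValidationError(
            f"brain {brain!r} has only {len(pool)} available cells, need N={N}"
        )
    members = _exact_knn(table.xy, pool, np.array([seed_index]), N)[0]
    group = CellGroup(members, seed_index=seed_index, label=None, brain_id=brain)
    if table.area_label is not None:
        group.label = group_modal_label(group, table)
    return group


def build_homogeneous_group(
    table: CellTable,
    seed_index: int,
    N: int,
    level: str = "h2",
    mask: np.ndarray | None = None,
) -> CellGroup:
    """The N nearest same-brain cells sharing the seed's coarse (H2) type."""
    if level != "h2":
        raise ValidationError(f"unsupported homogeneity level {level!r}")
    pool = _candidate_pool(table, seed_index, level, mask)
    brain = np.asarray(table.brain_id)[seed_index]
    if len(pool) < N:
        t = np.asarray(table.type_h2)[seed_index]
        raise ValidationError(
            f"brain {brain!r} has only {len(pool)} cells of type {t!r}, need N={N}"
        )
    members = _exact_knn(table.xy, pool, np.array([seed_index]), N)[0]
    group = CellGroup(members, seed_index=seed_index, label=None, brain_id=brain)
    if table.area_label is not None:
        group.label = group_modal_label(group, table)
    return group


def group_modal_label(group: CellGroup, table: CellTable) -> object:
    """Most common area label among members; ties break lexicographically."""
    if table.area_label is None:
        raise ValidationError("table has no area labels")
    labels = np.asarray(table.area_label)[group.member_indices]
    missing = group.member_indices[pd_isna(labels)]
    if len(missing):
        raise ValidationError(f"members without area label: {missing.tolist()}")
    uniq, counts = np.unique(labels.astype(str), return_counts=True)
    # np.unique returns sorted labels, so argmax takes the lexicographically
    # first label among tied counts
    return uniq[np.argmax(counts)]


def pd_isna(arr: np.ndarray) -> np.ndarray:
    import pandas as pd

    return pd.isna(arr)


def batch_group_members(
    table: CellTable,
    seeds: np.ndarray,
    N: int,
    level: str | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Member index matrix ``[n_seeds, N]`` for many seeds at once.

    Seeds are grouped per brain (and per H2 type when ``level='h2'``) so one
    KD-tree serves each stratum; the result row order matches ``seeds``.
    """
    seeds = np.asarray(seeds, dtype=np.int64)
    out = np.empty((len(seeds), N), dtype=np.int64)
    brains = np.asarray(table.brain_id)
    types = np.asarray(table.type_h2) if level == "h2" else None
    strata: dict[tuple, list[int]] = {}
    for i, s in enumerate(seeds):
        key = (brains[s],) if types is None else (brains[s], types[s])
        strata.setdefault(key, []).append(i)
    base = np.ones(table.n_cells, dtype=bool) if mask is None else np.asarray(mask, bool)
    for key, rows in strata.items():
        pool = (brains == key[0]) & base
        if types is not None:
            pool &= types == key[1]
        pool_idx_rows = seeds[rows]
        pool = pool.copy()
        pool[pool_idx_rows] = True
        pool_idx = np.nonzero(pool)[0]
        if len(pool_idx) < N:
            raise ValidationError(
                f"stratum {key!r} has only {len(pool_idx)} cells, need N={N}"
            )
        out[rows] = _exact_knn(table.xy, pool_idx, seeds[rows], N)
    return out


def sample_group_batches(
    table: CellTable,
    cfg: GroupSamplerConfig,
    split_mask: np.ndarray | None = None,
    n_batches: int | None = None,
) -> Iterator[list[CellGroup]]:
    """Stream batches of groups with uniformly random seed cells.

    Seeds are drawn uniformly (with ``cfg.rng_seed``) from masked cells.
    Under the default ``seed_only`` policy, group members may include
    out-of-split neighbors; ``strict_members`` restricts members to the
    masked cells.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    mask = (
        np.ones(table.n_cells, dtype=bool)
        if split_mask is None
        else np.asarray(split_mask, dtype=bool)
    )
    eligible = np.nonzero(mask)[0]
    if len(eligible) == 0:
        raise ValidationError("split mask selects no cells")
    member_mask = mask if cfg.split_policy == "strict_members" else None
    level = None if cfg.homogeneous_level in (None, "none") else cfg.homogeneous_level
    G = cfg.groups_per_batch
    produced = 0
    brains = np.asarray(table.brain_id)
    while n_batches is None or produced < n_batches:
        seeds = rng.choice(eligible, size=G, replace=True)
        members = batch_group_members(table, seeds, cfg.group_size, level, member_mask)
        batch = []
        for s, m in zip(seeds, members):
            g = CellGroup(m, seed_index=int(s), label=None, brain_id=brains[s])
            if table.area_label is not None:
                g.label = group_modal_label(g, table)
            batch.append(g)
        yield batch
        produced += 1


def fraction_of_groups_containing_boundary(
    table: CellTable, seeds: Sequence[int], N: int
) -> float:
    """Fraction of columnar groups whose members span more than one area."""
    members = batch_group_members(table, np.asarray(seeds), N)
    areas = np.asarray(table.area_label).astype(str)
    frac = np.mean([len(np.unique(areas[m])) > 1 for m in members])
    return float(frac)


def export_group_manifest(groups: Sequence[CellGroup], path) -> None:
    """Audit CSV of (seed_index, member_indices, label) per group."""
    import pandas as pd

    rows = [
        {
            "seed_index": g.seed_index,
            "member_indices": ";".join(map(str, sorted(g.member_indices))),
            "label": g.label,
            "brain_id": g.brain_id,
        }
        for g in groups
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
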