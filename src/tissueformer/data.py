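"""Core data containers and file I/O.

The central container is :class:`CellTable`, a validated bundle of a
cell-by-gene count matrix with per-cell spatial coordinates and optional
hierarchical cell-type / area annotations.  On disk a table is either an
h5ad file following the common single-cell container convention (``X``
counts, ``obs`` metadata, ``var`` gene index) or a directory of plain-text
files (MatrixMarket or CSV counts plus ``genes.txt`` and ``obs.csv``), so
real datasets and text-only fixtures both drop in.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: obs column names recognized by default; remappable via ``column_map``.
DEFAULT_COLUMNS = {
    "x": "x_flat",
    "y": "y_flat",
    "brain": "brain",
    "type_h2": "type_h2",
    "type_h3": "type_h3",
    "area": "area",
    "depth": "depth",
}

_INTEGRALITY_TOL = 1e-6


class FormatError(ValueError):
    """A file does not follow the expected on-disk layout."""


class ValidationError(ValueError):
    """A container violates one of its invariants."""


def _as_categorical(values) -> pd.Categorical:
    if isinstance(values, pd.Categorical):
        return values
    return pd.Categorical(np.asarray(values))


@dataclass
class CellTable:
    """Cell-by-gene counts plus per-cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, dense ``ndarray`` or ``scipy.sparse``
        CSR, shape ``(n_cells, n_genes)``.
    gene_ids
        Unique gene identifier per column.
    xy
        Planar coordinates, shape ``(n_cells, 2)``, arbitrary Euclidean
        units (flatmap-style: the third anatomical axis, depth, is a
        separate optional column).
    brain_id
        Categorical sample/animal identifier per cell; cell groups never
        span brains.
    type_h2, type_h3
        Optional coarse/fine cell-type labels.
    area_label
        Optional area annotation per cell, drawn from a finite label set.
    depth
        Optional per-cell cortical depth.
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    xy: np.ndarray
    brain_id: pd.Categorical
    type_h2: pd.Categorical | None = None
    type_h3: pd.Categorical | None = None
    area_label: pd.Categorical | None = None
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = _coerce_counts(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.xy = np.asarray(self.xy, dtype=float)
        self.brain_id = _as_categorical(self.brain_id)
        for name in ("type_h2", "type_h3", "area_label"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, _as_categorical(v))
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, g = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"gene_ids has length {len(self.gene_ids)}, counts has {g} columns"
            )
        if len(set(self.gene_ids)) != g:
            raise ValidationError("gene_ids are not unique")
        mn = self.counts.min() if n and g else 0
        if mn < 0:
            raise ValidationError("counts has negative entries")
        if self.xy.shape != (n, 2):
            raise ValidationError(
                f"column 'xy' has shape {self.xy.shape}, expected ({n}, 2)"
            )
        for name in ("brain_id", "type_h2", "type_h3", "area_label", "depth"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValidationError(
                    f"column '{name}' has length {len(v)}, expected {n}"
                )

    # -- basic properties -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def counts_dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return self.counts

    def subset(self, index) -> "CellTable":
        """Row-subset the table (copy); ``index`` is any numpy fancy index."""
        index = np.asarray(index)
        return CellTable(
            counts=self.counts[index],
            gene_ids=list(self.gene_ids),
            xy=self.xy[index],
            brain_id=self.brain_id[index],
            type_h2=None if self.type_h2 is None else self.type_h2[index],
            type_h3=None if self.type_h3 is None else self.type_h3[index],
            area_label=None if self.area_label is None else self.area_label[index],
            depth=None if self.depth is None else self.depth[index],
        )

    def equals(self, other: "CellTable") -> bool:
        """Field-by-field equality (sparse storage order ignored)."""
        if self.gene_ids != other.gene_ids:
            return False
        a, b = self.counts_dense(), other.counts_dense()
        if a.shape != b.shape or not np.array_equal(a, b):
            return False
        if not np.array_equal(self.xy, other.xy):
            return False
        for name in ("brain_id", "type_h2", "type_h3", "area_label"):
            u, v = getattr(self, name), getattr(other, name)
            if (u is None) != (v is None):
                return False
            if u is not None and (
                list(u.categories) != list(v.categories)
                or not np.array_equal(u.codes, v.codes)
            ):
                return False
        u, v = self.depth, other.depth
        if (u is None) != (v is None):
            return False
        if u is not None and not np.array_equal(u, v):
            return False
        return True


def concat_tables(tables: Sequence[CellTable]) -> CellTable:
    """Stack tables sharing one gene list (e.g. to build a multi-brain set)."""
    first = tables[0]
    for t in tables[1:]:
        if t.gene_ids != first.gene_ids:
            raise ValidationError("cannot concatenate tables with different genes")

    def cat(name):
        vals = [getattr(t, name) for t in tables]
        if any(v is None for v in vals):
            return None
        return pd.Categorical(np.concatenate([np.asarray(v) for v in vals]))

    any_sparse = any(sp.issparse(t.counts) for t in tables)
    if any_sparse:
        counts = sp.vstack([sp.csr_matrix(t.counts) for t in tables]).tocsr()
    else:
        counts = np.vstack([t.counts_dense() for t in tables])
    depths = [t.depth for t in tables]
    return CellTable(
        counts=counts,
        gene_ids=list(first.gene_ids),
        xy=np.vstack([t.xy for t in tables]),
        brain_id=cat("brain_id"),
        type_h2=cat("type_h2"),
        type_h3=cat("type_h3"),
        area_label=cat("area_label"),
        depth=None if any(d is None for d in depths) else np.concatenate(depths),
    )


def _coerce_counts(counts):
    """Validate non-negative, integral-within-tolerance; return int storage.

    Floats from permissive exporters are accepted when within 1e-6 of an
    integer, then stored as integers.
    """
    if sp.issparse(counts):
        counts = counts.tocsr()
        data = counts.data
        if data.size and np.abs(data - np.round(data)).max() > _INTEGRALITY_TOL:
            raise ValidationError("counts are not integral within tolerance")
        out = counts.copy()
        out.data = np.round(data).astype(np.int64)
        return out
    arr = np.asarray(counts)
    if arr.dtype.kind not in "iu":
        if arr.size and np.abs(arr - np.round(arr)).max() > _INTEGRALITY_TOL:
            raise ValidationError("counts are not integral within tolerance")
        arr = np.round(arr).astype(np.int64)
    return arr.astype(np.int64, copy=False)


# ---------------------------------------------------------------------------
# Gene vocabulary
# ---------------------------------------------------------------------------

SPECIAL_TOKENS = ("<cls>", "<pad>", "<mask>")


@dataclass(frozen=True)
class GeneVocabulary:
    """Contiguous 0-based token ids: specials first, then genes.

    ``cls_id``/``pad_id``/``mask_id`` are reserved and never collide with
    gene token ids.
    """

    gene_ids: tuple[str, ...]
    cls_id: int = 0
    pad_id: int = 1
    mask_id: int = 2

    @classmethod
    def from_genes(cls, gene_ids: Sequence[str]) -> "GeneVocabulary":
        genes = tuple(str(g) for g in gene_ids)
        if len(set(genes)) != len(genes):
            raise ValidationError("gene ids must be unique")
        return cls(gene_ids=genes)

    @property
    def n_special(self) -> int:
        return len(SPECIAL_TOKENS)

    @property
    def size(self) -> int:
        return len(self.gene_ids) + self.n_special

    def token_of_gene(self, gene: str) -> int:
        return self._index()[gene]

    def _index(self) -> dict[str, int]:
        # cached lazily on the instance despite frozen dataclass
        idx = self.__dict__.get("_idx")
        if idx is None:
            idx = {g: i + self.n_special for i, g in enumerate(self.gene_ids)}
            object.__setattr__(self, "_idx", idx)
        return idx

    def gene_token_ids(self) -> np.ndarray:
        """Token id of each gene, aligned with ``gene_ids`` order."""
        return np.arange(self.n_special, self.size)

    def gene_of_token(self, token: int) -> str:
        if token < self.n_special:
            return SPECIAL_TOKENS[token]
        return self.gene_ids[token - self.n_special]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for g in self.gene_ids:
            h.update(g.encode())
            h.update(b"\0")
        return h.hexdigest()[:16]


@dataclass
class MedianReference:
    """Per-gene median of total-normalized expression over nonzero cells.

    Genes with no usable median (never expressed in the reference corpus)
    carry NaN and are dropped before ranking.
    """

    gene_ids: list[str]
    median_of_gene: np.ndarray  # NaN = excluded

    def __post_init__(self):
        self.median_of_gene = np.asarray(self.median_of_gene, dtype=float)
        usable = self.median_of_gene[~np.isnan(self.median_of_gene)]
        if usable.size and usable.min() <= 0:
            raise ValidationError("usable medians must be strictly positive")


@dataclass
class OrthologMap:
    """Source-gene → target-gene pairs (first match kept on duplicates)."""

    pairs: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, gene: str) -> str | None:
        return self.pairs.get(gene)


class ParseError(ValueError):
    pass


def load_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV (with header) of source → target gene pairs.

    Duplicate source rows collapse to the first occurrence, matching the
    convention of keeping the first ortholog when several exist.
    """
    path = Path(path)
    pairs: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file, expected a header line")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated fields")
        pairs.setdefault(fields[0], fields[1])
    if not pairs:
        logger.warning("ortholog map %s is empty", path)
    return OrthologMap(pairs=pairs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _obs_to_table(counts, gene_ids, obs: pd.DataFrame, column_map=None) -> CellTable:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    for key in ("x", "y", "brain"):
        if cols[key] not in obs.columns:
            raise ValidationError(f"obs is missing required column '{cols[key]}'")
    n = counts.shape[0]
    if len(obs) != n:
        raise ValidationError(
            f"obs has {len(obs)} rows but counts has {n} rows"
        )

    def opt(key):
        name = cols[key]
        return obs[name] if name in obs.columns else None

    depth = opt("depth")
    return CellTable(
        counts=counts,
        gene_ids=gene_ids,
        xy=np.column_stack([obs[cols["x"]].to_numpy(float), obs[cols["y"]].to_numpy(float)]),
        brain_id=_as_categorical(obs[cols["brain"]]),
        type_h2=None if opt("type_h2") is None else _as_categorical(opt("type_h2")),
        type_h3=None if opt("type_h3") is None else _as_categorical(opt("type_h3")),
        area_label=None if opt("area") is None else _as_categorical(opt("area")),
        depth=None if depth is None else depth.to_numpy(float),
    )


def _table_to_obs(table: CellTable, column_map=None) -> pd.DataFrame:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    obs = pd.DataFrame(
        {
            cols["x"]: table.xy[:, 0],
            cols["y"]: table.xy[:, 1],
            cols["brain"]: pd.Series(table.brain_id),
        }
    )
    for key, attr in (("type_h2", "type_h2"), ("type_h3", "type_h3"), ("area", "area_label")):
        v = getattr(table, attr)
        if v is not None:
            obs[cols[key]] = pd.Series(v)
    if table.depth is not None:
        obs[cols["depth"]] = table.depth
    obs.index = obs.index.map(str)
    return obs


def read_cell_table(
    path: str | Path,
    format_hint: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> CellTable:
    """Read a :class:`CellTable` from h5ad or a CSV/MTX directory.

    ``format_hint`` is ``"h5ad"`` or ``"csv_mtx"``; inferred from the path
    when omitted (a directory implies ``csv_mtx``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint is None:
        format_hint = "csv_mtx" if path.is_dir() else "h5ad"
    if format_hint == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        if adata.X is None:
            raise FormatError(f"{path}: no counts matrix (X) present")
        return _obs_to_table(adata.X, list(adata.var_names), adata.obs, column_map)
    if format_hint == "csv_mtx":
        from scipy.io import mmread

        mtx = path / "counts.mtx"
        csv = path / "counts.csv"
        if mtx.exists():
            counts = sp.csr_matrix(mmread(mtx))
        elif csv.exists():
            counts = pd.read_csv(csv, header=None).to_numpy()
        else:
            raise FormatError(f"{path}: no counts.mtx or counts.csv found")
        genes_path = path / "genes.txt"
        if not genes_path.exists():
            raise FormatError(f"{path}: missing genes.txt")
        gene_ids = genes_path.read_text().split()
        obs = pd.read_csv(path / "obs.csv", float_precision="round_trip")
        return _obs_to_table(counts, gene_ids, obs, column_map)
    raise ValueError(f"unknown format hint {format_hint!r}")


def write_cell_table(
    table: CellTable,
    path: str | Path,
    format_hint: str | None = None,
    force: bool = False,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write a table readable back by :func:`read_cell_table` losslessly.

    Sparse counts stay sparse on disk. Existing output is refused unless
    ``force`` is set.
    """
    path = Path(path)
    if format_hint is None:
        format_hint = "h5ad" if path.suffix == ".h5ad" else "csv_mtx"
    if path.exists() and not force:
        occupied = any(path.iterdir()) if path.is_dir() else True
        if occupied:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    if format_hint == "h5ad":
        import anndata as ad

        X = table.counts if sp.issparse(table.counts) else table.counts_dense()
        adata = ad.AnnData(
            X=X,
            obs=_table_to_obs(table, column_map),
            var=pd.DataFrame(index=pd.Index(table.gene_ids, name="gene")),
        )
        adata.write_h5ad(path)
        return
    if format_hint == "csv_mtx":
        from scipy.io import mmwrite

        path.mkdir(parents=True, exist_ok=True)
        if sp.issparse(table.counts):
            mmwrite(path / "counts.mtx", table.counts)
        else:
            pd.DataFrame(table.counts_dense()).to_csv(
                path / "counts.csv", header=False, index=False
            )
        (path / "genes.txt").write_text("\n".join(table.gene_ids) + "\n")
        _table_to_obs(table, column_map).to_csv(path / "obs.csv", index=False)
        return
    raise ValueError(f"unknown format hint {format_hint!r}")
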