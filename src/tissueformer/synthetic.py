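"""Synthetic spatial single-cell data with known generative ground truth.

The generator emulates the structure the group-classification task assumes:
a 2D tissue tiled by contiguous labeled areas, where each area draws its
cells from an area-specific cell-type composition and each type expresses a
fixed mean program, with Poisson (or negative-binomial) count noise.  With
``composition_only=True`` the expression programs are shared across areas,
so a single cell carries no information about its area beyond its type —
the regime in which group composition is the only usable signal and the
exact Bayes accuracy of the task is computable.

Areas are vertical strips of equal width: deliberately unrealistic
geometry, chosen so boundary fractions and per-area compositions stay
analytically controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, lgamma

import numpy as np
import pandas as pd
from shapely.geometry import box

from .data import CellTable, ValidationError


@dataclass
class SyntheticAtlas:
    """Generative specification of a synthetic tissue.

    ``composition[a, t]`` is the probability a cell in area ``a`` has type
    ``t`` (rows sum to 1); ``programs[t, g]`` is type ``t``'s mean relative
    expression over genes (rows sum to 1).  Expected counts for a cell of
    type ``t`` are ``library_size * programs[t]``, modulated per area when
    ``composition_only`` is off.
    """

    area_polygons: list  # (label, shapely polygon)
    n_types: int
    composition: np.ndarray  # [n_areas, n_types]
    programs: np.ndarray  # [n_types, n_genes]
    library_size: float = 200.0
    noise_model: str = "poisson"
    nb_dispersion: float | None = None
    composition_only: bool = True
    area_program_scale: np.ndarray | None = None  # [n_areas, n_genes] when not composition_only
    gene_ids: list[str] = field(default_factory=list)
    type_names: list[str] = field(default_factory=list)
    domain: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)

    def __post_init__(self):
        self.composition = np.asarray(self.composition, float)
        self.programs = np.asarray(self.programs, float)
        if not np.allclose(self.composition.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("composition rows must sum to 1")
        if (self.programs < 0).any():
            raise ValidationError("programs must be non-negative")
        if self.noise_model not in ("poisson", "nb"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model == "nb" and not (self.nb_dispersion and self.nb_dispersion > 0):
            raise ValidationError("nb noise requires a positive dispersion")
        areas = [p for _, p in self.area_polygons]
        total = sum(p.area for p in areas)
        x0, y0, x1, y1 = self.domain
        if abs(total - (x1 - x0) * (y1 - y0)) > 1e-6 * total:
            raise ValidationError("area polygons do not tile the domain")

    @property
    def n_areas(self) -> int:
        return len(self.area_polygons)

    @property
    def area_names(self) -> list[str]:
        return [label for label, _ in self.area_polygons]

    def mean_counts(self, area: int, type_idx: int) -> np.ndarray:
        """Expected counts for a cell of the given type in the given area."""
        p = self.programs[type_idx]
        if not self.composition_only and self.area_program_scale is not None:
            p = p * self.area_program_scale[area]
            p = p / p.sum()
        return self.library_size * p


def generate_atlas(
    n_areas: int,
    n_types: int,
    n_genes: int,
    signal_strength: float,
    composition_only: bool = True,
    rng_seed: int = 0,
    library_size: float = 200.0,
    noise_model: str = "poisson",
    nb_dispersion: float | None = None,
) -> SyntheticAtlas:
    """Build an atlas of ``n_areas`` vertical strips on ``[0, n_areas] x [0, 1]``.

    Per-area compositions interpolate between a shared uniform baseline
    (``signal_strength=0``) and disjoint type preferences
    (``signal_strength=1``): types are partitioned round-robin among areas
    and each area's preference is uniform over its own types.
    """
    if min(n_areas, n_types, n_genes) < 2:
        raise ValidationError("n_areas, n_types and n_genes must all be >= 2")
    if not 0.0 <= signal_strength <= 1.0:
        raise ValidationError(f"signal_strength must lie in [0, 1], got {signal_strength}")
    rng = np.random.default_rng(rng_seed)

    baseline = np.full(n_types, 1.0 / n_types)
    prefs = np.zeros((n_areas, n_types))
    owner = np.arange(n_types) % n_areas  # round-robin partition of types
    for a in range(n_areas):
        own = owner == a
        prefs[a, own] = 1.0 / own.sum()
    composition = (1.0 - signal_strength) * baseline + signal_strength * prefs

    programs = rng.lognormal(mean=0.0, sigma=1.0, size=(n_types, n_genes))
    programs /= programs.sum(axis=1, keepdims=True)

    scale = None
    if not composition_only:
        scale = rng.lognormal(mean=0.0, sigma=0.25, size=(n_areas, n_genes))

    polys = [
        (f"A{a}", box(float(a), 0.0, float(a + 1), 1.0)) for a in range(n_areas)
    ]
    return SyntheticAtlas(
        area_polygons=polys,
        n_types=n_types,
        composition=composition,
        programs=programs,
        library_size=library_size,
        noise_model=noise_model,
        nb_dispersion=nb_dispersion,
        composition_only=composition_only,
        area_program_scale=scale,
        gene_ids=[f"g{i:04d}" for i in range(n_genes)],
        type_names=[f"T{t:02d}" for t in range(n_types)],
        domain=(0.0, 0.0, float(n_areas), 1.0),
    )


def generate_mean_matched_atlas(
    n_genes: int = 104,
    rng_seed: int = 0,
    library_size: float = 200.0,
    n_pairs_per_area: int = 4,
    amplitude: float = 0.8,
) -> SyntheticAtlas:
    """Two areas with identical expected pseudobulk but distinct compositions.

    Each area draws uniformly from its own set of ``n_pairs_per_area`` type
    *pairs* ``m ± delta``: the deltas cancel within every pair, so the
    class-conditional mean of a group's average expression is the shared
    baseline ``m`` in both areas.  Because the compositional variance is
    spread over many independent contrast directions, no single linear
    projection of the pseudobulk separates the areas — aggregate features
    are blind — while each cell's type (and hence its area's type alphabet)
    remains identifiable from its full expression pattern.
    """
    rng = np.random.default_rng(rng_seed)
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    m = base / base.sum()
    m = (m + 0.3 / n_genes) / 1.3  # floor keeps perturbed programs positive

    # area 0 contrasts; area 1 reuses the same per-gene magnitudes with
    # scrambled signs, so the per-gene marginal distribution of a group's
    # mean expression is identical across areas (nothing leaks through a
    # nonlinear per-gene transform) while the cross-gene structure differs
    # amplitude is the relative contrast a: paired rates are m*(1 ± a)

    def balanced_pattern() -> np.ndarray:
        """A ±1 sign pattern whose m-weighted sum is near zero (greedy
        partition), so each contrast m*a*sign keeps program rows summing
        to 1 without a re-projection that would distort magnitudes."""
        sign = np.empty(n_genes)
        run = 0.0
        for g in rng.permutation(n_genes):
            s = 1.0 if abs(run + m[g]) <= abs(run - m[g]) else -1.0
            sign[g] = s
            run += s * m[g]
        return sign

    deltas = []
    for _ in range(2 * n_pairs_per_area):
        d = amplitude * m * balanced_pattern()
        deltas.append(d - m * d.sum())  # residual ~ one gene's weight
    programs = []
    for d in deltas:
        programs.append(m + d)
        programs.append(m - d)
    programs = np.asarray(programs)
    n_types = 4 * n_pairs_per_area
    composition = np.zeros((2, n_types))
    half = n_types // 2
    composition[0, :half] = 1.0 / half  # area 0: first n_pairs_per_area pairs
    composition[1, half:] = 1.0 / half
    polys = [("A0", box(0.0, 0.0, 1.0, 1.0)), ("A1", box(1.0, 0.0, 2.0, 1.0))]
    return SyntheticAtlas(
        area_polygons=polys,
        n_types=n_types,
        composition=composition,
        programs=programs,
        library_size=library_size,
        composition_only=True,
        gene_ids=[f"g{i:04d}" for i in range(n_genes)],
        type_names=[f"T{i:02d}" for i in range(n_types)],
        domain=(0.0, 0.0, 2.0, 1.0),
    )


def sample_cells(
    atlas: SyntheticAtlas,
    n_cells: int,
    rng_seed: int = 0,
    brain_id: str = "synthetic-0",
    split_types: bool = False,
) -> CellTable:
    """Sample a :class:`CellTable` from the atlas.

    Positions are uniform over the domain; the area label is the containing
    polygon's label; the type is drawn from the area's composition and the
    counts from the noise model around the library-size-scaled type
    program.  ``split_types`` randomly subdivides each type into two fine
    (H3) subtypes so the coarse/fine level distinction is exercised; both
    levels are equal otherwise.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = np.random.default_rng(rng_seed)
    x0, y0, x1, y1 = atlas.domain
    xy = rng.uniform((x0, y0), (x1, y1), size=(n_cells, 2))
    # strips: area index from x directly (strip width is uniform)
    n_areas = atlas.n_areas
    area_idx = np.minimum(
        ((xy[:, 0] - x0) / (x1 - x0) * n_areas).astype(int), n_areas - 1
    )
    type_idx = np.empty(n_cells, dtype=int)
    for a in range(n_areas):
        sel = area_idx == a
        type_idx[sel] = rng.choice(atlas.n_types, size=sel.sum(), p=atlas.composition[a])

    lam = atlas.library_size * atlas.programs[type_idx]
    if not atlas.composition_only and atlas.area_program_scale is not None:
        mod = atlas.programs[type_idx] * atlas.area_program_scale[area_idx]
        mod /= mod.sum(axis=1, keepdims=True)
        lam = atlas.library_size * mod
    if atlas.noise_model == "nb":
        r = atlas.nb_dispersion
        lam = rng.gamma(shape=r, scale=lam / r)
    counts = rng.poisson(lam)

    h2 = pd.Categorical(np.array(atlas.type_names)[type_idx])
    if split_types:
        sub = rng.integers(0, 2, size=n_cells)
        h3 = pd.Categorical(
            [f"{atlas.type_names[t]}.{s}" for t, s in zip(type_idx, sub)]
        )
    else:
        h3 = pd.Categorical(np.array(atlas.type_names)[type_idx])
    return CellTable(
        counts=counts,
        gene_ids=list(atlas.gene_ids),
        xy=xy,
        brain_id=pd.Categorical([brain_id] * n_cells),
        type_h2=h2,
        type_h3=h3,
        area_label=pd.Categorical(np.array(atlas.area_names)[area_idx]),
    )


def _enumerate_compositions(N: int, T: int):
    """All type-count vectors summing to N over T types (lexicographic)."""
    if T == 1:
        yield (N,)
        return
    for first in range(N + 1):
        for rest in _enumerate_compositions(N - first, T - 1):
            yield (first,) + rest


def analytic_group_bayes_accuracy(
    atlas: SyntheticAtlas,
    N: int,
    rng_seed: int = 0,
    n_samples: int = 200_000,
    enumerate_limit: int = 200_000,
) -> tuple[float, str]:
    """Exact (or Monte-Carlo) Bayes accuracy of MAP area from N type draws.

    Valid only for ``composition_only`` atlases, where a group's multiset of
    cell types is a sufficient statistic for its area.  With equal area
    priors the Bayes decision maximizes the multinomial likelihood of the
    observed type counts; ties resolve to the lowest area index.  Small
    problems are enumerated exactly; larger ones are Monte-Carlo estimated.
    Returns ``(accuracy, method)`` with method ``"enumeration"`` or
    ``"monte_carlo"``.
    """
    if not atlas.composition_only:
        raise ValidationError(
            "Bayes accuracy has no closed sufficient statistic unless "
            "composition_only is set"
        )
    comp = atlas.composition
    A, T = comp.shape
    with np.errstate(divide="ignore"):
        logp = np.where(comp > 0, np.log(np.where(comp > 0, comp, 1.0)), -np.inf)

    n_outcomes = comb(N + T - 1, T - 1)
    if n_outcomes <= enumerate_limit:
        log_nfact = lgamma(N + 1)
        safe = np.where(np.isneginf(logp), 0.0, logp)
        acc = 0.0
        for m in _enumerate_compositions(N, T):
            m_arr = np.array(m)
            coef = log_nfact - sum(lgamma(k + 1) for k in m)
            bad = ((m_arr[None, :] > 0) & np.isneginf(logp)).any(axis=1)
            ll = np.where(bad, -np.inf, m_arr @ safe.T)
            winner = int(np.argmax(ll))
            if np.isneginf(ll[winner]):
                continue
            # P(m | winner's area) contributes only when the winner is the
            # true area; summing max_a P(m|a)/A over multisets is equivalent
            acc += np.exp(coef + ll[winner]) / A
        return float(acc), "enumeration"

    rng = np.random.default_rng(rng_seed)
    per_area = max(1, n_samples // A)
    correct = 0
    total = 0
    for a in range(A):
        draws = rng.multinomial(N, comp[a], size=per_area)
        safe = np.where(np.isneginf(logp), 0.0, logp)
        ll = draws @ safe.T
        impossible = (draws[:, None, :] > 0) & np.isneginf(logp)[None, :, :]
        ll = np.where(impossible.any(axis=2), -np.inf, ll)
        correct += int((np.argmax(ll, axis=1) == a).sum())
        total += per_area
    return correct / total, "monte_carlo"
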