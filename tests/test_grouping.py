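import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from tissueformer.data import CellTable, ValidationError, concat_tables
from tissueformer.grouping import (
    CellGroup,
    GroupSamplerConfig,
    build_column_group,
    build_homogeneous_group,
    fraction_of_groups_containing_boundary,
    group_modal_label,
    sample_group_batches,
)


def brute_force_column(table, seed, N, type_filter=None):
    """All-pairs-distance oracle: same brain (and type), sort by (d2, index)."""
    brains = np.asarray(table.brain_id)
    pool = np.nonzero(brains == brains[seed])[0]
    if type_filter is not None:
        types = np.asarray(table.type_h2)
        pool = pool[types[pool] == types[seed]]
    d2 = ((table.xy[pool] - table.xy[seed]) ** 2).sum(axis=1)
    order = np.lexsort((pool, pool != seed, d2))  # distance, seed-first, index
    return set(pool[order[:N]].tolist())


def random_table(n, rng, n_brains=1, integer_coords=False):
    xy = rng.integers(0, 40, size=(n, 2)).astype(float) if integer_coords else rng.uniform(0, 100, (n, 2))
    return CellTable(
        counts=rng.integers(0, 3, size=(n, 3)),
        gene_ids=["a", "b", "c"],
        xy=xy,
        brain_id=pd.Categorical(rng.choice([f"b{i}" for i in range(n_brains)], n)),
        type_h2=pd.Categorical(rng.choice(["X", "Y", "Z"], n)),
        area_label=pd.Categorical(rng.choice(["A0", "A1"], n)),
    )


class TestColumnGroups:
    def test_n1_is_just_the_seed(self, tiny_table):
        g = build_column_group(tiny_table, 3, N=1)
        assert set(g.member_indices) == {3}

    def test_collinear_example(self):
        t = CellTable(
            counts=np.ones((5, 2), int), gene_ids=["a", "b"],
            xy=np.column_stack([[0.0, 1, 2, 3, 10], np.zeros(5)]),
            brain_id=["b"] * 5,
        )
        g = build_column_group(t, seed_index=2, N=3)
        assert set(g.member_indices) == {1, 2, 3}

    def test_distance_tie_at_boundary_goes_to_lower_index(self):
        # cells 1 and 2 are equidistant from the seed; N=2 must take index 1
        t = CellTable(
            counts=np.ones((4, 2), int), gene_ids=["a", "b"],
            xy=np.array([[0.0, 0], [1.0, 0], [-1.0, 0], [5.0, 0]]),
            brain_id=["b"] * 4,
        )
        g = build_column_group(t, seed_index=0, N=2)
        assert set(g.member_indices) == {0, 1}

    def test_too_small_brain_errors_naming_n(self):
        t = CellTable(
            counts=np.ones((2, 2), int), gene_ids=["a", "b"],
            xy=np.zeros((2, 2)), brain_id=["b", "b"],
        )
        with pytest.raises(ValidationError, match="N=5"):
            build_column_group(t, 0, N=5)

    @pytest.mark.parametrize("N", [1, 2, 16, 101])
    def test_matches_brute_force_oracle(self, N):
        rng = np.random.default_rng(N)
        t = random_table(800, rng, integer_coords=True)  # integer coords force ties
        for seed in rng.integers(0, 800, size=25):
            got = set(build_column_group(t, int(seed), N).member_indices.tolist())
            assert got == brute_force_column(t, int(seed), N)

    def test_groups_never_span_brains(self):
        rng = np.random.default_rng(3)
        t = random_table(400, rng, n_brains=3)
        brains = np.asarray(t.brain_id)
        for seed in rng.integers(0, 400, size=30):
            g = build_column_group(t, int(seed), N=20)
            assert len(set(brains[g.member_indices])) == 1


class TestHomogeneousGroups:
    def test_single_type_reduces_to_column_group(self):
        rng = np.random.default_rng(0)
        t = random_table(200, rng)
        object.__setattr__(t, "type_h2", pd.Categorical(["X"] * 200))
        for seed in (5, 50):
            a = build_column_group(t, seed, 10).member_indices
            b = build_homogeneous_group(t, seed, 10).member_indices
            assert set(a) == set(b)

    def test_nearer_other_type_cells_are_skipped(self):
        t = CellTable(
            counts=np.ones((5, 2), int), gene_ids=["a", "b"],
            xy=np.column_stack([[0.0, 1, 2, 3, 4], np.zeros(5)]),
            brain_id=["b"] * 5,
            type_h2=pd.Categorical(["X", "Y", "Y", "X", "X"]),
        )
        g = build_homogeneous_group(t, seed_index=0, N=2)
        assert set(g.member_indices) == {0, 3}

    def test_insufficient_same_type_cells_error(self):
        rng = np.random.default_rng(1)
        t = random_table(30, rng)
        types = np.asarray(t.type_h2)
        n_same = (types == types[0]).sum()
        with pytest.raises(ValidationError):
            build_homogeneous_group(t, 0, N=int(n_same) + 1)

    @pytest.mark.parametrize("N", [1, 2, 16])
    def test_matches_filter_then_knn_oracle(self, N):
        rng = np.random.default_rng(N + 100)
        t = random_table(600, rng, integer_coords=True)
        for seed in rng.integers(0, 600, size=20):
            got = set(build_homogeneous_group(t, int(seed), N).member_indices.tolist())
            assert got == brute_force_column(t, int(seed), N, type_filter=True)


class TestModalLabel:
    def _group(self, idx):
        return CellGroup(np.asarray(idx), seed_index=idx[0], label=None, brain_id="b")

    def test_majority_wins(self):
        t = CellTable(
            counts=np.ones((3, 2), int), gene_ids=["a", "b"], xy=np.zeros((3, 2)),
            brain_id=["b"] * 3, area_label=pd.Categorical(["A", "A", "B"]),
        )
        assert group_modal_label(self._group([0, 1, 2]), t) == "A"

    def test_tie_breaks_lexicographically(self):
        t = CellTable(
            counts=np.ones((2, 2), int), gene_ids=["a", "b"], xy=np.zeros((2, 2)),
            brain_id=["b"] * 2, area_label=pd.Categorical(["B", "A"]),
        )
        assert group_modal_label(self._group([0, 1]), t) == "A"

    def test_singleton_group_is_its_cells_label(self, tiny_table):
        assert group_modal_label(self._group([4]), tiny_table) == "B"

    def test_permutation_invariant_in_member_order(self, tiny_table):
        rng = np.random.default_rng(0)
        idx = [0, 3, 5, 6]
        base = group_modal_label(self._group(idx), tiny_table)
        for _ in range(5):
            perm = list(rng.permutation(idx))
            assert group_modal_label(self._group(perm), tiny_table) == base


class TestSampler:
    def test_batch_shape(self, small_table):
        cfg = GroupSamplerConfig(group_size=4, total_cells_per_batch=8, rng_seed=0)
        batch = next(sample_group_batches(small_table, cfg, n_batches=1))
        assert len(batch) == 2
        assert all(g.size == 4 for g in batch)

    def test_indivisible_batch_is_config_error(self):
        with pytest.raises(ValidationError, match="divisible"):
            GroupSamplerConfig(group_size=3, total_cells_per_batch=8)

    def test_same_seed_gives_identical_streams(self, small_table):
        cfg = GroupSamplerConfig(group_size=4, total_cells_per_batch=16, rng_seed=9)
        a = [g.member_indices for b in sample_group_batches(small_table, cfg, n_batches=3) for g in b]
        b = [g.member_indices for b in sample_group_batches(small_table, cfg, n_batches=3) for g in b]
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_seed_frequencies_uniform_chi_square(self):
        rng = np.random.default_rng(2)
        t = random_table(50, rng)
        cfg = GroupSamplerConfig(group_size=1, total_cells_per_batch=500, rng_seed=1)
        seeds = [
            g.seed_index
            for batch in sample_group_batches(t, cfg, n_batches=20)
            for g in batch
        ]
        freq = np.bincount(seeds, minlength=50)
        assert len(seeds) == 10_000
        assert chisquare(freq).pvalue > 1e-3

    def test_strict_members_stay_inside_split(self):
        rng = np.random.default_rng(4)
        t = random_table(300, rng)
        mask = np.zeros(300, bool)
        mask[:150] = True
        cfg = GroupSamplerConfig(
            group_size=8, total_cells_per_batch=64, rng_seed=0, split_policy="strict_members"
        )
        for batch in sample_group_batches(t, cfg, mask, n_batches=3):
            for g in batch:
                members = set(g.member_indices) - {g.seed_index}
                assert all(mask[m] for m in members)


def test_boundary_fraction_monotone_in_group_size(small_table):
    rng = np.random.default_rng(0)
    seeds = rng.integers(0, small_table.n_cells, size=150)
    fracs = [
        fraction_of_groups_containing_boundary(small_table, seeds, N)
        for N in (1, 4, 16, 64)
    ]
    assert fracs == sorted(fracs)
    assert fracs[0] == 0.0  # singleton groups cannot straddle a boundary


def test_group_manifest_csv_round_trips(tmp_path, small_table):
    import pandas as pd

    from tissueformer.grouping import export_group_manifest

    cfg = GroupSamplerConfig(group_size=4, total_cells_per_batch=16, rng_seed=0)
    batch = next(sample_group_batches(small_table, cfg, n_batches=1))
    path = tmp_path / "groups.csv"
    export_group_manifest(batch, path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["seed_index", "member_indices", "label", "brain_id"]
    members = {int(i) for i in df["member_indices"].iloc[0].split(";")}
    assert members == set(batch[0].member_indices)
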