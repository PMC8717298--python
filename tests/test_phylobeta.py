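"""Phylogenetic Sørensen decomposition and the partition-shuffle null."""

import numpy as np
import pandas as pd
import pytest

from phylodom.dominance import partition_all_sites
from phylodom.phylobeta import (
    branch_set, empirical_p, multisite_phylosor, pairwise_phylosor,
    partition_shuffle_null, region_sensitivity, run_beta_stage,
)
from phylodom.trees import TreeIndex

from conftest import tree_from


class TestBranchSet:
    def test_t4_subsets(self, t4_index):
        bs = branch_set(t4_index, ["A", "B"])
        assert sum(bs.values()) == pytest.approx(3.0)  # A + B + stem
        assert len(bs) == 3
        single = branch_set(t4_index, ["A"])
        assert sum(single.values()) == pytest.approx(2.0)  # root path kept
        full = branch_set(t4_index, list("ABCD"))
        assert len(full) == 6 and sum(full.values()) == pytest.approx(6.0)


class TestPairwise:
    def test_disjoint_subtrees_fully_dissimilar(self, t4_index):
        sor, sim, sne = pairwise_phylosor(branch_set(t4_index, ["A", "B"]),
                                          branch_set(t4_index, ["C", "D"]))
        assert (sor, sim, sne) == (1.0, 1.0, 0.0)

    def test_identical_sets_zero(self, t4_index):
        b = branch_set(t4_index, ["A", "B"])
        assert pairwise_phylosor(b, b) == (0.0, 0.0, 0.0)

    def test_partial_overlap_derived_values(self, t4_index):
        # {A,B} vs {A,C}: a=2 (A tip + left stem vs ... shared), b=1, c=2
        sor, sim, sne = pairwise_phylosor(branch_set(t4_index, ["A", "B"]),
                                          branch_set(t4_index, ["A", "C"]))
        assert sor == pytest.approx(3 / 7)
        assert sim == pytest.approx(1 / 3)
        assert sne == pytest.approx(2 / 21)

    def test_star_tree_equals_species_sorensen(self, rng):
        # on an equal-branch star tree only pendant edges exist, so the
        # branch-length Sørensen must reduce to the classical species one
        n = 12
        newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        idx = TreeIndex(tree_from(newick))
        for _ in range(20):
            s1 = set(rng.choice(n, size=rng.integers(2, 8), replace=False))
            s2 = set(rng.choice(n, size=rng.integers(2, 8), replace=False))
            sor, sim, sne = pairwise_phylosor(
                branch_set(idx, [f"t{i}" for i in s1]),
                branch_set(idx, [f"t{i}" for i in s2]))
            a, b, c = len(s1 & s2), len(s1 - s2), len(s2 - s1)
            assert sor == pytest.approx((b + c) / (2 * a + b + c), abs=1e-12)
            m = min(b, c)
            assert sim == pytest.approx(m / (a + m) if a + m else 0.0,
                                        abs=1e-12)


class TestMultisite:
    def test_identical_sites_zero(self, t4_index):
        b = branch_set(t4_index, ["A", "B"])
        assert multisite_phylosor([b, b, b]) == (0.0, 0.0, 0.0)

    def test_two_sites_reduces_to_pairwise(self, t4_index):
        b1 = branch_set(t4_index, ["A", "B"])
        b2 = branch_set(t4_index, ["A", "C"])
        np.testing.assert_allclose(multisite_phylosor([b1, b2]),
                                   pairwise_phylosor(b1, b2), atol=1e-14)

    def test_nested_chain_is_pure_nestedness(self, t4_index):
        chain = [branch_set(t4_index, s)
                 for s in (["A"], ["A", "B"], ["A", "B", "C"])]
        sor, sim, sne = multisite_phylosor(chain)
        assert sim == 0.0
        assert sor == pytest.approx(sne)
        assert sor > 0

    def test_decomposition_identity_on_random_communities(self, pool_tree, rng):
        idx = TreeIndex(pool_tree.tree)
        sets = [branch_set(idx, list(rng.choice(idx.tips, size=10,
                                                replace=False)))
                for _ in range(6)]
        sor, sim, sne = multisite_phylosor(sets)
        assert sor == pytest.approx(sim + sne, abs=1e-12)
        assert 0 <= sim <= sor <= 1


class TestEmpiricalP:
    def test_central_observation_capped_at_one(self):
        null = np.arange(101, dtype=float)
        assert empirical_p(50.0, null) == 1.0

    def test_extreme_observation(self):
        null = np.arange(1, 1498, dtype=float)
        assert empirical_p(0.0, null) == pytest.approx(2 / 1498)

    def test_fifth_percentile_rank_arithmetic(self):
        null = np.arange(1, 1000, dtype=float)  # uniform ranks
        obs = 50.0
        # 50 null values <= obs -> p_low = 51/1000 -> two-sided ~0.102
        assert empirical_p(obs, null) == pytest.approx(0.102)


@pytest.fixture(scope="module")
def parts(clustered_ds):
    return partition_all_sites(clustered_ds.table, metric="cover", k=3)


@pytest.fixture(scope="module")
def index(clustered_ds):
    return TreeIndex(clustered_ds.tree.tree)


class TestShuffleNull:
    def test_pooled_null_size(self, parts, index):
        null = partition_shuffle_null(parts, index, n_iter=19, seed=1)
        pooled = null[null["index"] == "multisite_sor"]
        assert len(pooled) == 3 * 19

    def test_seed_determinism(self, parts, index):
        a = partition_shuffle_null(parts, index, n_iter=9, seed=4)
        b = partition_shuffle_null(parts, index, n_iter=9, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_null_partitions_indistinguishable(self):
        # equal thirds (richness divisible by 3): the three partitions'
        # shuffle nulls come from the same distribution
        from scipy import stats
        from phylodom.synthetic import ScenarioConfig, simulate_dataset
        ds = simulate_dataset(ScenarioConfig(
            scenario="clustered_dominants", n_sites=15, n_species_pool=150,
            richness_range=(21, 21), seed=3))
        parts = partition_all_sites(ds.table, metric="cover", k=3)
        index = TreeIndex(ds.tree.tree)
        null = partition_shuffle_null(parts, index, n_iter=99, seed=2)
        sub = null[null["index"] == "multisite_sor"]
        groups = [g["value"].to_numpy() for _, g in sub.groupby("partition")]
        for i in range(3):
            for j in range(i + 1, 3):
                assert stats.ks_2samp(groups[i], groups[j]).pvalue > 0.01

    def test_clustered_dominants_below_null(self, parts, index):
        results, _ = run_beta_stage(parts, index, n_iter=99, seed=3)
        row = results[(results["partition"] == "dominant")
                      & (results["index"] == "multisite_sor")].iloc[0]
        assert row["observed"] < row["null_mean"]
        assert row["p"] < 0.05

    def test_decomposition_identity_everywhere(self, parts, index):
        results, null = run_beta_stage(parts, index, n_iter=29, seed=5)
        wide = results.pivot(index="partition", columns="index",
                             values="observed")
        for kind in ("multisite", "pairwise"):
            np.testing.assert_allclose(
                wide[f"{kind}_sor"],
                wide[f"{kind}_sim"] + wide[f"{kind}_sne"], atol=1e-12)
        nw = null.pivot_table(index=["iteration", "partition"],
                              columns="index", values="value")
        for kind in ("multisite", "pairwise"):
            np.testing.assert_allclose(
                nw[f"{kind}_sor"], nw[f"{kind}_sim"] + nw[f"{kind}_sne"],
                atol=1e-12)


class TestRegionSensitivity:
    def test_exclusion_changes_site_count(self, clustered_ds):
        parts = partition_all_sites(clustered_ds.table, metric="cover", k=3)
        idx = TreeIndex(clustered_ds.tree.tree)
        regions = clustered_ds.table.regions
        excluded = {"Australia"}
        keep = [s for s in parts["site"].unique()
                if regions.get(s) not in excluded]
        res = region_sensitivity(parts, idx, regions, exclude=excluded,
                                 n_iter=9, seed=1)
        assert not res.empty and len(keep) >= 2

    def test_excluding_almost_all_sites_errors(self, clustered_ds):
        parts = partition_all_sites(clustered_ds.table, metric="cover", k=3)
        idx = TreeIndex(clustered_ds.tree.tree)
        regions = {s: "X" for s in parts["site"].unique()}
        with pytest.raises(ValueError):
            region_sensitivity(parts, idx, regions, exclude={"X"}, n_iter=5)
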