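"""Tree I/O, grafting, pruning and summary statistics."""

import math

import numpy as np
import pytest

from phylodom.trees import (
    NewickError, TreeIndex, colless_index, faith_pd, gamma_statistic,
    graft_species, prune_to_site, read_newick, sackin_index,
    topology_indices, total_branch_length,
)

from conftest import T4_NEWICK, random_ultrametric, tree_from


class TestReadNewick:
    def test_reads_four_tip_tree(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text(T4_NEWICK)
        tree = read_newick(p)
        assert len(tree.leaf_nodes()) == 4
        assert total_branch_length(tree) == pytest.approx(6.0)

    def test_single_tip_accepted(self, tmp_path):
        p = tmp_path / "one.nwk"
        p.write_text("(A:1);")
        assert len(read_newick(p).leaf_nodes()) == 1

    def test_duplicate_tips_rejected(self, tmp_path):
        p = tmp_path / "dup.nwk"
        p.write_text("((A:1,A:1):1);")
        with pytest.raises(NewickError, match="duplicate"):
            read_newick(p)

    def test_malformed_newick_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:1;")
        with pytest.raises(NewickError, match="malformed"):
            read_newick(p)


class TestFaithPD:
    @pytest.mark.parametrize("subset, expected", [
        ({"A", "B"}, 3.0),
        ({"A", "C"}, 4.0),
        ({"A", "B", "C", "D"}, 6.0),
    ])
    def test_t4_values(self, t4_index, subset, expected):
        assert faith_pd(t4_index, subset) == pytest.approx(expected)

    def test_all_tips_equals_total_branch_length(self):
        for seed in range(5):
            tree = random_ultrametric(25, seed)
            idx = TreeIndex(tree)
            assert faith_pd(idx, idx.tips) == pytest.approx(
                total_branch_length(tree), rel=1e-12)

    def test_unknown_species_error(self, t4_index):
        with pytest.raises(ValueError, match="Z"):
            faith_pd(t4_index, {"A", "Z"})


class TestPrune:
    def test_pairwise_distances_preserved_on_random_trees(self):
        rng = np.random.default_rng(2)
        for seed in range(8):
            tree = random_ultrametric(30, seed)
            idx = TreeIndex(tree)
            keep = list(rng.choice(idx.tips, size=10, replace=False))
            sub_idx = TreeIndex(prune_to_site(tree, keep))
            full = idx.cophenetic_frame().loc[keep, keep]
            small = sub_idx.cophenetic_frame().loc[keep, keep]
            np.testing.assert_allclose(full.to_numpy(), small.to_numpy(),
                                       atol=1e-9)

    def test_prune_to_all_is_identity(self, t4):
        idx = TreeIndex(t4)
        sub = TreeIndex(prune_to_site(t4, idx.tips))
        np.testing.assert_allclose(
            idx.cophenetic_frame().loc[idx.tips, idx.tips],
            sub.cophenetic_frame().loc[idx.tips, idx.tips])

    def test_empty_set_rejected(self, t4):
        with pytest.raises(ValueError):
            prune_to_site(t4, set())


class TestGamma:
    def test_t4_value(self, t4):
        assert gamma_statistic(t4) == pytest.approx(-0.8165, abs=1e-4)

    def test_matches_direct_formula_on_random_trees(self):
        # independent Pybus-Harvey evaluation from sorted node depths
        for seed in range(30):
            tree = random_ultrametric(np.random.default_rng(seed).integers(5, 40),
                                      seed)
            assert gamma_statistic(tree) == pytest.approx(
                _gamma_oracle(tree), abs=1e-9)

    def test_non_ultrametric_rejected(self):
        tree = tree_from("((A:1.0,B:1.5):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            gamma_statistic(tree)

    def test_three_tip_midpoint_split(self):
        tree = tree_from("((A:1,B:1):1,C:2);")
        assert gamma_statistic(tree) == pytest.approx(_gamma_oracle(tree),
                                                      abs=1e-12)


def _gamma_oracle(tree):
    tree.calc_node_root_distances()
    node_times = sorted(nd.root_distance for nd in tree.preorder_node_iter()
                        if not nd.is_leaf())
    T_depth = max(lf.root_distance for lf in tree.leaf_node_iter())
    n = len(tree.leaf_nodes())
    times = node_times + [T_depth]
    g = [times[i] - times[i - 1] for i in range(1, len(times))]  # g_2..g_n
    T_j = [sum((k + 2) * g[k] for k in range(j - 1)) for j in range(2, n + 1)]
    T = T_j[-1]
    inner = sum(T_j[:-1]) / (n - 2)
    return (inner - T / 2) / (T * math.sqrt(1 / (12 * (n - 2))))


class TestTopology:
    def test_balanced_tree_colless_zero(self, t4):
        assert colless_index(t4) == 0

    def test_caterpillar_colless(self):
        cat = tree_from("(((A:1,B:1):1,C:2):1,D:3);")
        assert colless_index(cat) == 3

    def test_t4_sackin(self, t4):
        assert sackin_index(t4) == 8

    def test_polytomy_resolved_maximally_unbalanced(self):
        # trichotomy of three single tips: caterpillar resolution gives
        # |1-2| + |1-1| = 1
        tri = tree_from("(A:1,B:1,C:1);")
        assert colless_index(tri) == 1

    def test_topology_indices_bundle(self, t4):
        out = topology_indices(t4)
        assert out["colless"] == 0 and out["sackin"] == 8
        assert out["gamma"] == pytest.approx(-0.8165, abs=1e-4)


class TestGraft:
    def test_congener_mrca_graft(self):
        tree = tree_from("((Poa_a:1,Poa_b:1):1,(Festuca_a:1,Bromus_a:1):1);")
        grafted, report = graft_species(tree, ["Poa_c"])
        assert report.loc[0, "level"] == "congener"
        idx = TreeIndex(grafted)
        # attached at MRCA(Poa_a, Poa_b): equidistant from both
        d = idx.cophenetic_frame()
        assert d.loc["Poa_c", "Poa_a"] == pytest.approx(d.loc["Poa_c", "Poa_b"])
        assert d.loc["Poa_c", "Poa_a"] == pytest.approx(2.0)

    def test_single_congener_midpoint_split(self):
        tree = tree_from("((Poa_a:1,Festuca_a:1):1,Bromus_a:2);")
        grafted, report = graft_species(tree, ["Poa_c"])
        assert report.loc[0, "level"] == "congener"
        d = TreeIndex(grafted).cophenetic_frame()
        assert d.loc["Poa_c", "Poa_a"] == pytest.approx(1.0)  # 2 × half edge

    def test_family_level_and_ungraftable(self):
        tree = tree_from("((Poa_a:1,Poa_b:1):1,(Festuca_a:1,Bromus_a:1):1);")
        fam = {g: "Poaceae" for g in ("Poa", "Festuca", "Bromus", "Lolium")}
        grafted, report = graft_species(tree, ["Lolium_x", "Quercus_y"],
                                        family_of=fam)
        levels = dict(zip(report["species"], report["level"]))
        assert levels == {"Lolium_x": "family", "Quercus_y": "ungraftable"}
        assert "Quercus_y" not in TreeIndex(grafted).tip_index

    def test_idempotent_for_present_species(self):
        tree = tree_from("((Poa_a:1,Poa_b:1):1,Bromus_a:2);")
        grafted, report = graft_species(tree, ["Poa_a", "Poa_b"])
        assert set(report["level"]) == {"present"}
        assert len(grafted.leaf_nodes()) == 3

    def test_graft_count_report_on_simulated_tree(self, pool_tree):
        # remove 10 tips that have congeners, then graft them back
        idx = TreeIndex(pool_tree.tree)
        genus_of = pool_tree.genus_of
        by_genus = {}
        for sp, g in genus_of.items():
            by_genus.setdefault(g, []).append(sp)
        removable = [sps[0] for sps in by_genus.values() if len(sps) >= 3][:10]
        kept = [t for t in idx.tips if t not in set(removable)]
        pruned = prune_to_site(pool_tree.tree, kept)
        grafted, report = graft_species(pruned, removable, genus_of=genus_of)
        assert (report["level"] == "congener").sum() == len(removable)
        assert (report["level"] == "family").sum() == 0

    def test_grafting_preserves_near_ultrametricity(self, pool_tree):
        idx = TreeIndex(pool_tree.tree)
        genus_of = dict(pool_tree.genus_of)
        sp = idx.tips[0]
        kept = idx.tips[1:]
        pruned = prune_to_site(pool_tree.tree, kept)
        grafted, _ = graft_species(pruned, [sp], genus_of=genus_of,
                                   family_of=pool_tree.family_of)
        depths = TreeIndex(grafted).depths()
        assert depths.max() - depths.min() < 1e-6 * depths.max()
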