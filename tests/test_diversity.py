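import numpy as np
import pytest

from phylogrid import diversity
from phylogrid.grids import GridSpec
from phylogrid.rasterops import PresenceAbsenceMatrix
from phylogrid.trees import (
    branch_incidence,
    equalize_branches,
    is_ultrametric,
    parse_newick,
    prune_to_taxa,
    total_length,
)

from conftest import brute_force_pd, brute_force_pe, random_pam, random_ultrametric_tree


class TestTrees:
    def test_branch_incidence_micro(self, micro_tree):
        B, L = branch_incidence(micro_tree, ["A", "B", "C"])
        assert B.shape == (4, 3)
        assert L.sum() == pytest.approx(5.0)
        # C's path is a single branch of length 2
        c_col = B[:, 2]
        assert L[c_col].sum() == pytest.approx(2.0)
        # A's path: its pendant edge (1) plus the stem (1)
        assert L[B[:, 0]].sum() == pytest.approx(2.0)

    def test_missing_species_raises(self, micro_tree):
        with pytest.raises(KeyError, match="ghost"):
            branch_incidence(micro_tree, ["A", "ghost"])

    def test_unlengthed_branch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            parse_newick("((A:1,B:1),C:2);")

    def test_equalize_branches_copies(self, micro_tree):
        eq = equalize_branches(micro_tree)
        assert total_length(eq) == pytest.approx(4.0)
        assert total_length(micro_tree) == pytest.approx(5.0)

    def test_prune_to_taxa(self, micro_tree):
        pruned = prune_to_taxa(micro_tree, ["A", "C"])
        labels = {l.taxon.label for l in pruned.leaf_node_iter()}
        assert labels == {"A", "C"}
        assert {l.taxon.label for l in micro_tree.leaf_node_iter()} == {"A", "B", "C"}

    def test_is_ultrametric(self, micro_tree):
        assert is_ultrametric(micro_tree)
        assert not is_ultrametric(parse_newick("((A:1,B:3):1,C:2);"))


class TestSimpleIndices:
    def test_td_and_we(self, micro_pam):
        np.testing.assert_array_equal(
            diversity.taxonomic_diversity(micro_pam), [2.0, 1.0]
        )
        # every species has range 1 here, so WE == TD
        np.testing.assert_allclose(
            diversity.weighted_endemism(micro_pam), [2.0, 1.0]
        )

    def test_we_sums_to_species_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pam = random_pam(rng, int(rng.integers(3, 12)), int(rng.integers(2, 9)))
            assert diversity.weighted_endemism(pam).sum() == pytest.approx(
                pam.n_species, abs=1e-9
            )

    def test_we_rejects_empty_ranges(self, micro_pam):
        bad = PresenceAbsenceMatrix(
            np.zeros_like(micro_pam.matrix),
            micro_pam.species,
            micro_pam.rows,
            micro_pam.cols,
            micro_pam.grid,
        )
        with pytest.raises(ValueError, match="empty ranges"):
            diversity.weighted_endemism(bad)


class TestPhyloIndices:
    def test_micro_pd_pe(self, micro_tree, micro_pam):
        np.testing.assert_allclose(
            diversity.pd_per_cell(micro_tree, micro_pam), [0.6, 0.4], atol=1e-12
        )
        # single-cell ranges: PE == PD here
        np.testing.assert_allclose(
            diversity.pe_per_cell(micro_tree, micro_pam), [0.6, 0.4], atol=1e-12
        )
        np.testing.assert_allclose(
            diversity.rpd_per_cell(micro_tree, micro_pam), [0.8, 1.6], atol=1e-12
        )

    def test_pd_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(1)
        for rep in range(10):
            labels = [f"t{i}" for i in range(6)]
            tree = random_ultrametric_tree(rng, labels)
            pam = random_pam(rng, 8, 6)
            pam.species = labels
            got = diversity.pd_per_cell(tree, pam)
            for c in range(pam.n_cells):
                tips = {labels[j] for j in np.flatnonzero(pam.matrix[c])}
                expect = brute_force_pd(tree, tips) / total_length(tree)
                assert got[c] == pytest.approx(expect, abs=1e-12)

    def test_pe_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for rep in range(10):
            labels = [f"t{i}" for i in range(5)]
            tree = random_ultrametric_tree(rng, labels)
            pam = random_pam(rng, 7, 5)
            pam.species = labels
            np.testing.assert_allclose(
                diversity.pe_per_cell(tree, pam),
                brute_force_pe(tree, pam),
                atol=1e-12,
            )

    def test_pe_sums_to_pool_pd(self):
        rng = np.random.default_rng(3)
        for rep in range(20):
            labels = [f"t{i}" for i in range(int(rng.integers(3, 9)))]
            tree = random_ultrametric_tree(rng, labels)
            pam = random_pam(rng, int(rng.integers(3, 12)), len(labels))
            pam.species = labels
            pool = np.ones((1, len(labels)), dtype=np.uint8)
            pool_pd = diversity._PhyloIndexEngine(tree, labels).pd(pool)[0]
            assert diversity.pe_per_cell(tree, pam).sum() == pytest.approx(
                pool_pd, abs=1e-9
            )

    def test_rpd_rpe_nan_on_empty_cells(self, micro_tree):
        grid = GridSpec(0.0, 3.0, 1.0, 1, 3)
        pam = PresenceAbsenceMatrix(
            np.array([[1, 1, 0], [0, 0, 1], [0, 0, 0]]),
            ["A", "B", "C"],
            [0, 0, 0],
            [0, 1, 2],
            grid,
        )
        rpd = diversity.rpd_per_cell(micro_tree, pam)
        assert np.isnan(rpd[2]) and np.isfinite(rpd[:2]).all()
        assert diversity.pd_per_cell(micro_tree, pam)[2] == 0.0

    def test_equal_length_tree_gives_unit_ratios(self):
        rng = np.random.default_rng(4)
        labels = [f"t{i}" for i in range(6)]
        tree = random_ultrametric_tree(rng, labels)
        eq = equalize_branches(tree)
        pam = random_pam(rng, 10, 6)
        pam.species = labels
        np.testing.assert_allclose(diversity.rpd_per_cell(eq, pam), 1.0, atol=1e-12)
        np.testing.assert_allclose(diversity.rpe_per_cell(eq, pam), 1.0, atol=1e-12)

    def test_cell_indices_table(self, micro_tree, micro_pam):
        df = diversity.cell_indices(micro_tree, micro_pam)
        assert list(df.columns) == [
            "cell_id", "row", "col", "lon", "lat", "td", "we", "pd", "pe", "rpd", "rpe",
        ]
        np.testing.assert_allclose(df["pd"], [0.6, 0.4])
        np.testing.assert_allclose(df["rpe"], [0.8, 1.6])


class TestRandomization:
    def test_margins_preserved(self):
        rng = np.random.default_rng(5)
        pam = random_pam(rng, 12, 8)
        ens = diversity.randomize_pam(pam, n_iter=50, seed=6)
        assert ens.shape == (50, 12, 8)
        for r in range(50):
            np.testing.assert_array_equal(ens[r].sum(axis=0), pam.range_sizes)
            np.testing.assert_array_equal(ens[r].sum(axis=1), pam.richness)

    def test_replicates_actually_move(self):
        rng = np.random.default_rng(7)
        pam = random_pam(rng, 15, 10)
        ens = diversity.randomize_pam(pam, n_iter=20, seed=8)
        changed = sum(not np.array_equal(ens[r], pam.matrix) for r in range(20))
        assert changed >= 18

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        pam = random_pam(rng, 10, 6)
        a = diversity.randomize_pam(pam, n_iter=5, seed=10)
        b = diversity.randomize_pam(pam, n_iter=5, seed=10)
        np.testing.assert_array_equal(a, b)

    def test_swapless_matrix_warns_and_repeats(self):
        grid = GridSpec(0.0, 2.0, 1.0, 2, 1)
        # nested: species b's range contains a's -> no checkerboard
        pam = PresenceAbsenceMatrix(
            np.array([[1, 1], [0, 1]]), ["a", "b"], [0, 1], [0, 0], grid
        )
        with pytest.warns(UserWarning, match="identical"):
            ens = diversity.randomize_pam(pam, n_iter=3, seed=0)
        for r in range(3):
            np.testing.assert_array_equal(ens[r], pam.matrix)

    def test_too_small_rejected(self, micro_pam):
        grid = GridSpec(0.0, 1.0, 1.0, 1, 1)
        one = PresenceAbsenceMatrix(np.array([[1]]), ["a"], [0], [0], grid)
        with pytest.raises(ValueError):
            diversity.randomize_pam(one, n_iter=2, seed=0)


class TestNullPercentiles:
    def test_identical_nulls_give_midrank_fifty(self, micro_tree):
        grid = GridSpec(0.0, 2.0, 1.0, 2, 1)
        pam = PresenceAbsenceMatrix(
            np.array([[1, 1, 0], [0, 1, 1]]), ["A", "B", "C"], [0, 1], [0, 0], grid
        )
        ens = np.repeat(pam.matrix[None], 10, axis=0)
        out = diversity.null_percentiles(micro_tree, pam, ens)
        np.testing.assert_allclose(out["pd_pctl"], 50.0)
        assert not out["pd_high"].any() and not out["pd_low"].any()

    def test_flags_fire_at_extremes(self, micro_tree):
        grid = GridSpec(0.0, 2.0, 1.0, 2, 1)
        obs = PresenceAbsenceMatrix(
            np.array([[1, 0, 1], [1, 1, 0]]), ["A", "B", "C"], [0, 1], [0, 0], grid
        )
        # nulls always put {A,B} (short spanning path) in cell 0
        null_m = np.array([[1, 1, 0], [1, 0, 1]], np.uint8)
        ens = np.repeat(null_m[None], 100, axis=0)
        out = diversity.null_percentiles(micro_tree, obs, ens)
        # observed cell 0 = {A,C}: PD 1.0 vs null 0.6 -> percentile 100
        assert out["pd_pctl"][0] == 100.0
        assert bool(out["pd_high"][0])
        assert out["pd_pctl"][1] == 0.0
        assert bool(out["pd_low"][1])

    def test_empty_cell_percentile_is_nan(self, micro_tree):
        grid = GridSpec(0.0, 2.0, 1.0, 2, 1)
        pam = PresenceAbsenceMatrix(
            np.array([[1, 1, 1], [0, 0, 0]]), ["A", "B", "C"], [0, 1], [0, 0], grid
        )
        ens = np.repeat(pam.matrix[None], 5, axis=0)
        out = diversity.null_percentiles(micro_tree, pam, ens)
        assert np.isnan(out["pd_pctl"][1])
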