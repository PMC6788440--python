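"""Beta-diversity partition and neighbor-joining clustering."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import dice
from skbio import DistanceMatrix, TreeNode

import elevdiv as ed
from elevdiv.exceptions import ValidationError
from conftest import random_incidence


def incidence(sets, species):
    rows = [[sp in s for sp in species] for s in sets]
    idx = pd.MultiIndex.from_tuples(
        [("M", f"s{i}") for i in range(len(sets))], names=["mountain", "location"]
    )
    return pd.DataFrame(rows, index=idx, columns=species)


class TestPairwise:
    def test_identical_sites_have_zero_dissimilarity(self):
        m = incidence([{"a", "b"}, {"a", "b"}], ["a", "b"])
        pw = ed.pairwise_partition(m)
        assert pw.sor.iloc[0, 1] == 0
        assert pw.sim.iloc[0, 1] == 0
        assert pw.sne.iloc[0, 1] == 0

    def test_disjoint_sites_are_pure_turnover(self):
        m = incidence([{"a", "b"}, {"c", "d"}], ["a", "b", "c", "d"])
        pw = ed.pairwise_partition(m)
        assert pw.sor.iloc[0, 1] == 1
        assert pw.sim.iloc[0, 1] == 1
        assert pw.sne.iloc[0, 1] == 0

    def test_nested_pair_hand_evaluation(self):
        # site1 = {A,B,C}, site2 = {A}: a=1, b=2, c=0
        m = incidence([{"A", "B", "C"}, {"A"}], ["A", "B", "C"])
        pw = ed.pairwise_partition(m)
        assert pw.sim.iloc[0, 1] == pytest.approx(0.0)
        assert pw.sor.iloc[0, 1] == pytest.approx(0.5)
        assert pw.sne.iloc[0, 1] == pytest.approx(0.5)

    def test_single_site_rejected(self):
        m = incidence([{"a"}], ["a"])
        with pytest.raises(ValidationError):
            ed.pairwise_partition(m)

    def test_sorensen_equals_scipy_dice(self, rng):
        m = random_incidence(rng, n_sites=7, n_species=20)
        pw = ed.pairwise_partition(m)
        x = m.to_numpy()
        for i in range(7):
            for j in range(i + 1, 7):
                assert pw.sor.iloc[i, j] == pytest.approx(
                    dice(x[i], x[j]), abs=1e-12
                )

    def test_additivity_on_random_matrices(self, rng):
        for _ in range(50):
            m = random_incidence(
                rng,
                n_sites=int(rng.integers(2, 8)),
                n_species=int(rng.integers(3, 25)),
            )
            pw = ed.pairwise_partition(m)
            np.testing.assert_allclose(
                pw.sor.to_numpy(), (pw.sim + pw.sne).to_numpy(), atol=1e-12
            )

    def test_adding_shared_species_never_increases_sor(self, rng):
        for _ in range(25):
            m = random_incidence(rng, n_sites=2, n_species=12)
            before = ed.pairwise_partition(m).sor.iloc[0, 1]
            m2 = m.copy()
            m2["shared_extra"] = True
            after = ed.pairwise_partition(m2).sor.iloc[0, 1]
            assert after <= before + 1e-12

    def test_two_empty_sites_flagged_undefined(self):
        m = incidence([set(), set(), {"a"}], ["a"])
        pw = ed.pairwise_partition(m)
        assert np.isnan(pw.sor.iloc[0, 1])


class TestMultisite:
    def test_identical_sites(self):
        m = incidence([{"a", "b"}] * 3, ["a", "b"])
        part = ed.multisite_partition(m)
        assert part.beta_sor == 0

    def test_pairwise_disjoint_sites(self):
        m = incidence([{"a"}, {"b"}, {"c"}], ["a", "b", "c"])
        part = ed.multisite_partition(m)
        assert part.beta_sor == pytest.approx(1.0)
        assert part.beta_sim == pytest.approx(1.0)
        assert part.beta_sne == pytest.approx(0.0)

    def test_perfectly_nested_chain_is_pure_nestedness(self):
        m = incidence([{"A", "B", "C"}, {"A", "B"}, {"A"}], ["A", "B", "C"])
        part = ed.multisite_partition(m)
        assert part.beta_sim == 0
        assert part.beta_sne == pytest.approx(part.beta_sor)
        assert part.beta_sor > 0

    def test_two_sites_reduce_to_pairwise(self, rng):
        for _ in range(20):
            m = random_incidence(rng, n_sites=2, n_species=15)
            multi = ed.multisite_partition(m)
            pw = ed.pairwise_partition(m)
            assert multi.beta_sor == pytest.approx(pw.sor.iloc[0, 1], abs=1e-12)
            assert multi.beta_sim == pytest.approx(pw.sim.iloc[0, 1], abs=1e-12)

    def test_additivity(self, rng):
        for _ in range(50):
            m = random_incidence(
                rng,
                n_sites=int(rng.integers(2, 9)),
                n_species=int(rng.integers(3, 25)),
            )
            part = ed.multisite_partition(m)
            assert part.beta_sor == pytest.approx(
                part.beta_sim + part.beta_sne, abs=1e-12
            )
            assert 0 <= part.beta_sim <= part.beta_sor <= 1 + 1e-12

    def test_empty_site_excluded_with_warning(self):
        m = incidence([{"a", "b"}, set(), {"b", "c"}], ["a", "b", "c"])
        with pytest.warns(UserWarning, match="zero species"):
            part = ed.multisite_partition(m)
        assert part.n_sites == 2


def random_additive_tree(rng, n_leaves):
    """Random binary tree with uniform branch lengths, as Newick text."""
    labels = [f"t{i}" for i in range(n_leaves)]

    def build(group):
        if len(group) == 1:
            return group[0]
        k = int(rng.integers(1, len(group)))
        idx = rng.permutation(len(group))
        left = [group[i] for i in idx[:k]]
        right = [group[i] for i in idx[k:]]
        bl, br = rng.uniform(0.1, 1.0, size=2)
        return f"({build(left)}:{bl:.6f},{build(right)}:{br:.6f})"

    return TreeNode.read(io.StringIO(build(labels) + ";")), labels


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float), ["A", "B", "C"]
        )
        tree = ed.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                           "C": pytest.approx(3.0)}

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8])
    def test_recovers_additive_distances_exactly(self, n_leaves, rng):
        tree, labels = random_additive_tree(rng, n_leaves)
        dm = tree.tip_tip_distances(labels)
        rec = ed.nj_tree(DistanceMatrix(dm.data, labels))
        back = rec.tip_tip_distances(labels)
        # an additive metric has a unique tree: exact path-length recovery
        # certifies both topology and branch lengths
        np.testing.assert_allclose(back.data, dm.data, atol=1e-8)

    def test_equal_distances_run_deterministically(self):
        n = 5
        arr = np.ones((n, n)) - np.eye(n)
        ids = [f"s{i}" for i in range(n)]
        t1 = ed.write_newick(ed.nj_tree(DistanceMatrix(arr, ids)))
        t2 = ed.write_newick(ed.nj_tree(DistanceMatrix(arr, ids)))
        assert t1 == t2

    def test_asymmetric_input_rejected(self):
        bad = pd.DataFrame(
            [[0, 1.0, 2.0], [1.5, 0, 1.0], [2.0, 1.0, 0]],
            index=list("abc"),
            columns=list("abc"),
        )
        with pytest.raises(ValidationError):
            ed.to_distance_matrix(bad)

    def test_nan_distances_rejected(self):
        bad = pd.DataFrame(
            [[0, np.nan], [np.nan, 0]], index=list("ab"), columns=list("ab")
        )
        with pytest.raises(ValidationError):
            ed.to_distance_matrix(bad)

    def test_negative_branches_clamped_with_warning(self):
        # non-additive configuration known to produce a negative NJ branch
        arr = np.array(
            [
                [0.0, 0.86910777, 0.65684695, 0.38976458],
                [0.86910777, 0.0, 0.6095986, 0.25695663],
                [0.65684695, 0.6095986, 0.0, 0.16424846],
                [0.38976458, 0.25695663, 0.16424846, 0.0],
            ]
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = ed.nj_tree(DistanceMatrix(arr, list("abcd")))
        for node in tree.traverse(include_self=False):
            if node.length is not None:
                assert node.length >= 0
        assert any(
            getattr(n, "raw_length", 0) is not None and getattr(n, "raw_length", 0) < 0
            for n in tree.traverse(include_self=False)
        )

    def test_newick_round_trip(self, rng):
        tree, labels = random_additive_tree(rng, 6)
        dm = tree.tip_tip_distances(labels)
        built = ed.nj_tree(DistanceMatrix(dm.data, labels))
        text = ed.write_newick(built)
        back = TreeNode.read(io.StringIO(text))
        assert sorted(t.name for t in back.tips()) == sorted(labels)
        np.testing.assert_allclose(
            back.tip_tip_distances(labels).data,
            built.tip_tip_distances(labels).data,
            atol=1e-8,
        )
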