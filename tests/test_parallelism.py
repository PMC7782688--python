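"""IBS distances, NJ trees, bootstrap supports, clustering verdicts,
and the region divergence contrast."""

import io

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from islandsweep import parallelism as par

from conftest import make_matrix


def newick(s):
    return TreeNode.read(io.StringIO(s))


class TestIBS:
    def test_identical_individuals_zero(self):
        H = np.tile(np.array([[0], [1], [0]], dtype=np.int8), (1, 3))
        dm = par.ibs_distance(make_matrix(H))
        assert np.allclose(dm.data, 0.0)

    def test_fully_opposite_haploids_one(self):
        H = np.array([[0, 1], [0, 1], [1, 0]], dtype=np.int8)
        dm = par.ibs_distance(make_matrix(H))
        assert dm.data[0, 1] == pytest.approx(1.0)

    def test_three_of_ten_mismatch(self):
        H = np.zeros((10, 2), dtype=np.int8)
        H[:3, 1] = 1
        dm = par.ibs_distance(make_matrix(H))
        assert dm.data[0, 1] == pytest.approx(0.3)

    def test_pairwise_deletion_and_empty_pair_error(self):
        H = np.array([[0, -1], [-1, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="no co-called"):
            par.ibs_distance(make_matrix(H))

    def test_needs_two_individuals(self):
        with pytest.raises(ValueError):
            par.ibs_distance(make_matrix(np.zeros((3, 1), dtype=np.int8)))


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=["A", "B", "C"]
        )
        tree = par.nj_tree(dm)
        pendant = {t.name: t.length for t in tree.tips()}
        assert pendant["A"] == pytest.approx(1.0)
        assert pendant["B"] == pytest.approx(1.0)
        assert pendant["C"] == pytest.approx(3.0)

    def test_recovers_additive_topologies(self):
        # oracle: build random trees, take their path-length matrices,
        # check NJ returns the generating bipartitions
        rng = np.random.default_rng(15)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            ids = [f"t{i}" for i in range(n)]
            source = _random_tree(ids, rng)
            dm = source.tip_tip_distances()
            dm = DistanceMatrix(dm.data, ids=list(dm.ids))
            got = par.nj_tree(dm)
            tipset = frozenset(ids)
            assert par._bipartitions(got, tipset) == par._bipartitions(source, tipset)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            par.nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


def _random_tree(ids, rng):
    nodes = [TreeNode(name=i, length=float(rng.uniform(0.5, 2))) for i in ids]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.uniform(0.5, 2)), children=[left, right])
        nodes.append(parent)
    return TreeNode(children=nodes)


class TestBootstrap:
    def test_single_replicate_supports_100(self):
        rng = np.random.default_rng(16)
        H = rng.integers(0, 2, size=(60, 6)).astype(np.int8)
        _, support = par.bootstrap_consensus(
            make_matrix(H), [f"ind_{i}" for i in range(6)], n_bootstrap=1, seed=0
        )
        assert all(v == 100.0 for v in support.values())

    def test_diverged_demes_have_strong_support(self):
        rng = np.random.default_rng(17)
        base_a = rng.integers(0, 2, size=40)
        base_b = 1 - base_a
        cols = [
            np.where(rng.random(40) < 0.05, 1 - b, b)
            for b in [base_a] * 4 + [base_b] * 4
        ]
        H = np.stack(cols, axis=1).astype(np.int8)
        tree, support = par.bootstrap_consensus(
            make_matrix(H), [f"ind_{i}" for i in range(8)], n_bootstrap=100, seed=1
        )
        key = frozenset({"ind_0", "ind_1", "ind_2", "ind_3"})
        assert support[key] >= 95

    def test_pure_noise_has_weak_support(self):
        rng = np.random.default_rng(18)
        H = rng.integers(0, 2, size=(80, 8)).astype(np.int8)
        _, support = par.bootstrap_consensus(
            make_matrix(H), [f"ind_{i}" for i in range(8)], n_bootstrap=100, seed=2
        )
        assert all(v < 95 for v in support.values())


class TestFitchScore:
    def test_perfect_segregation_one_change(self):
        t = newick("((a1,a2,a3),(b1,b2,b3));")
        labels = {n: n[0] for n in "a1 a2 a3 b1 b2 b3".split()}
        assert par.fitch_score(t, labels) == 1

    def test_interleaved_labels_cost_more(self):
        t = newick("((a1,b1),(a2,b2),(a3,b3));")
        labels = {n: n[0] for n in "a1 a2 a3 b1 b2 b3".split()}
        assert par.fitch_score(t, labels) == 3

    def test_rooting_invariance(self):
        t = newick("((a1,b1),((a2,b2),(a3,(b3,a4))));")
        labels = {n: n[0] for n in "a1 a2 a3 a4 b1 b2 b3".split()}
        base = par.fitch_score(t, labels)
        for tip in ("a1", "b3", "a3"):
            c = t.copy()
            rerooted = c.root_at(c.find(tip).parent)
            assert par.fitch_score(rerooted, labels) == base


class TestClusteringVerdict:
    MORPHS = {
        "fwK": "flatwing", "fwO": "flatwing", "fwH": "flatwing",
        "nwK": "normal", "nwO": "normal", "nwH": "normal",
    }

    def test_monophyletic_flatwing_consistent_with_introgression(self):
        t = newick("((fwK,fwO,fwH),(nwK,nwO,nwH));")
        v = par.flatwing_clustering_test(t, self.MORPHS)
        assert v.monophyletic and v.mixing_score == 1
        assert v.introgression_consistent

    def test_population_wise_clades_not_monophyletic(self):
        t = newick("((fwK,nwK),((fwO,nwO),(fwH,nwH)));")
        v = par.flatwing_clustering_test(t, self.MORPHS)
        assert not v.monophyletic and v.mixing_score >= 3
        assert not v.introgression_consistent

    def test_low_support_blocks_introgression_verdict(self):
        t = newick("((fwK,fwO,fwH),(nwK,nwO,nwH));")
        key = frozenset({"fwK", "fwO", "fwH"})
        v = par.flatwing_clustering_test(t, self.MORPHS, support={key: 50.0})
        assert v.monophyletic and not v.introgression_consistent

    def test_needs_two_flatwing_tips(self):
        t = newick("((fwK,nwO),(nwK,nwH));")
        with pytest.raises(ValueError):
            par.flatwing_clustering_test(
                t, {"fwK": "flatwing", "nwO": "normal", "nwK": "normal", "nwH": "normal"}
            )


class TestRegionContrast:
    def _windows(self, values):
        import pandas as pd

        return pd.DataFrame({"d": values, "dxy": values})

    def test_no_signal_not_significant(self):
        rng = np.random.default_rng(19)
        w = self._windows(rng.normal(1.0, 0.1, size=200))
        mask = np.zeros(200, bool)
        mask[50:70] = True
        res = par.region_divergence_contrast(w, mask, columns=("d",), seed=3)
        assert res["d"].p_empirical > 0.05

    def test_forced_extreme_floor_p(self):
        rng = np.random.default_rng(20)
        vals = rng.normal(1.0, 0.1, size=200)
        mask = np.zeros(200, bool)
        mask[10:30] = True
        vals[mask] += 10 * 0.1 * 10  # +10 sigma and then some
        res = par.region_divergence_contrast(
            self._windows(vals), mask, columns=("d",), seed=4
        )
        assert res["d"].p_empirical == pytest.approx(1 / 1001)

    def test_block_mode_also_detects_strong_signal(self):
        rng = np.random.default_rng(21)
        vals = rng.normal(1.0, 0.05, size=300)
        mask = np.zeros(300, bool)
        mask[100:130] = True
        vals[mask] += 5.0
        res = par.region_divergence_contrast(
            self._windows(vals), mask, columns=("d",), mode="block", seed=5
        )
        assert res["d"].p_empirical < 0.05

    def test_empirical_and_ttest_agree_in_direction(self):
        rng = np.random.default_rng(22)
        vals = rng.normal(0.0, 1.0, size=100)
        mask = np.zeros(100, bool)
        mask[:20] = True
        vals[mask] += 2.0
        res = par.region_divergence_contrast(
            self._windows(vals), mask, columns=("d",), seed=6
        )
        assert res["d"].observed_diff > 0
        assert res["d"].p_empirical < 0.05 and res["d"].p_ttest < 0.05

    def test_region_covering_everything_rejected(self):
        w = self._windows(np.ones(30))
        with pytest.raises(ValueError):
            par.region_divergence_contrast(w, np.ones(30, bool))
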