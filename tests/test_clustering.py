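"""UPGMA agglomeration, hotspot search and the max-statistic permutation null."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

import tcravidity as tv


def random_distance_matrix(rng, n, ids=None):
    a = rng.random((n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = ids or [f"t{i:02d}" for i in range(n)]
    return tv.TcrDistanceMatrix(ids=ids, values=d)


class TestUpgma:
    def test_two_leaves_merge_at_half_distance(self):
        m = tv.TcrDistanceMatrix(ids=["a", "b"], values=np.array([[0, 0.3], [0.3, 0]]))
        tree = tv.upgma(m)
        assert tree.root.height == pytest.approx(0.15)
        assert set(tree.leaf_ids) == {"a", "b"}

    def test_three_leaf_worked_example(self):
        # d(a,b)=0.1, d(a,c)=0.4, d(b,c)=0.5: (a,b) at 0.05, then c at 0.225
        m = tv.TcrDistanceMatrix(
            ids=["a", "b", "c"],
            values=np.array([[0, 0.1, 0.4], [0.1, 0, 0.5], [0.4, 0.5, 0]]),
        )
        tree = tv.upgma(m)
        assert tree.root.height == pytest.approx(0.225)
        inner = [c for c in tree.root.children if not c.is_leaf]
        assert len(inner) == 1 and inner[0].height == pytest.approx(0.05)
        assert set(inner[0].leaf_ids) == {"a", "b"}

    @pytest.mark.parametrize("n", [4, 6, 9, 12])
    def test_cophenetic_matches_scipy_average_linkage(self, rng, n):
        m = random_distance_matrix(rng, n)
        tree = tv.upgma(m)
        ids, coph = tree.cophenetic_matrix()
        pos = {t: i for i, t in enumerate(ids)}
        mine = np.array(
            [[coph[pos[a], pos[b]] for b in m.ids] for a in m.ids]
        )
        reference = squareform(cophenet(linkage(squareform(m.values), method="average")))
        assert np.allclose(mine, reference, atol=1e-12)

    def test_ultrametric_three_point_condition(self, rng):
        m = random_distance_matrix(rng, 10)
        _, coph = tv.upgma(m).cophenetic_matrix()
        for i, j, k in itertools.combinations(range(10), 3):
            a, b, c = sorted([coph[i, j], coph[i, k], coph[j, k]])
            assert b == pytest.approx(c, abs=1e-12)  # two largest equal

    def test_heights_nondecreasing_rootward(self, rng):
        tree = tv.upgma(random_distance_matrix(rng, 8))

        def walk(node):
            if node.is_leaf:
                return
            for child in node.children:
                assert child.height <= node.height + 1e-12
                walk(child)

        walk(tree.root)

    def test_rejects_asymmetric_and_negative(self):
        bad = tv.TcrDistanceMatrix(ids=["a", "b"], values=np.array([[0, 0.2], [0.3, 0]]))
        with pytest.raises(ValueError, match="symmetric"):
            tv.upgma(bad)
        neg = tv.TcrDistanceMatrix(ids=["a", "b"], values=np.array([[0, -0.1], [-0.1, 0]]))
        with pytest.raises(ValueError, match="negative"):
            tv.upgma(neg)

    def test_single_leaf_rejected(self):
        m = tv.TcrDistanceMatrix(ids=["a"], values=np.zeros((1, 1)))
        with pytest.raises(ValueError, match="at least 2"):
            tv.upgma(m)

    def test_tied_distances_merge_lexicographically_smallest_pair(self):
        # d(a,b) == d(c,d) == 0.1: (a,b) must merge first
        d = np.full((4, 4), 0.8)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        tree = tv.upgma(tv.TcrDistanceMatrix(ids=list("abcd"), values=d))
        first_merges = [
            n for n in tree.internal_nodes() if n.size == 2
        ]
        pair_sets = [set(n.leaf_ids) for n in first_merges]
        assert {"a", "b"} in pair_sets and {"c", "d"} in pair_sets
        # deterministic newick across repeated runs
        assert tree.to_newick() == tv.upgma(
            tv.TcrDistanceMatrix(ids=list("abcd"), values=d)
        ).to_newick()

    def test_newick_roundtrip_leaf_set(self, rng):
        tree = tv.upgma(random_distance_matrix(rng, 6))
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for leaf in tree.leaf_ids:
            assert leaf in nwk


class TestHotspot:
    def test_all_high_returns_whole_tree(self, rng):
        m = random_distance_matrix(rng, 6)
        tree = tv.upgma(m)
        hl = {t: 100.0 for t in tree.leaf_ids}
        hs = tv.find_hotspot(tree, hl, threshold_s=10.0, min_size=2)
        assert set(hs.member_ids) == set(tree.leaf_ids)
        assert hs.purity == 1.0 and hs.inside_high_fraction == 1.0

    def test_unique_all_high_clade_found(self):
        # leaves a-e tight cluster (all high), f-j diffuse (all low)
        n = 10
        d = np.full((n, n), 0.9)
        np.fill_diagonal(d, 0.0)
        for i, j in itertools.combinations(range(5), 2):
            d[i, j] = d[j, i] = 0.05
        ids = list("abcdefghij")
        tree = tv.upgma(tv.TcrDistanceMatrix(ids=ids, values=d))
        hl = {t: (50.0 if t in "abcde" else 2.0) for t in ids}
        hs = tv.find_hotspot(tree, hl, threshold_s=10.0, min_size=5)
        assert set(hs.member_ids) == set("abcde")
        assert hs.purity == 1.0
        assert hs.inside_high_fraction == 1.0
        assert hs.outside_low_fraction == 1.0

    def test_agrees_with_exhaustive_clade_enumeration(self, rng):
        for seed in range(8):
            local = np.random.default_rng(seed)
            m = random_distance_matrix(local, 12)
            tree = tv.upgma(m)
            hl = {t: float(local.uniform(0, 30)) for t in tree.leaf_ids}
            min_size = 3
            hs = tv.find_hotspot(tree, hl, threshold_s=10.0, min_size=min_size)
            # independent enumeration over every internal node
            best = None
            for node in tree.internal_nodes():
                members = [t for t in node.leaf_ids if hl[t] is not None]
                if len(members) < min_size:
                    continue
                frac = np.mean([hl[t] > 10.0 for t in members])
                key = (-frac, -len(members), node.height)
                if best is None or key < best[0]:
                    best = (key, node)
            assert set(hs.member_ids) == set(best[1].leaf_ids)
            assert hs.purity == pytest.approx(-best[0][0])

    def test_planted_clade_recovered(self):
        hits = 0
        for seed in range(30):
            panel, _ = tv.generate_panel(
                tv.PanelSpec(
                    n_tcrs=40, seed=seed, motif="NEIK", motif_rate=1.0,
                    high_fraction=0.25,
                    halflife_ranges=((2.0, 8.0), (65.0, 180.0)),
                )
            )
            planted = {c.tcr_id for c in panel if c.is_high_avidity}
            tree = tv.upgma(tv.distance_matrix(panel))
            hl = {c.tcr_id: c.halflife_s for c in panel}
            hs = tv.find_hotspot(tree, hl, threshold_s=10.0, min_size=5)
            hits += set(hs.member_ids) == planted
        assert hits >= 29  # >= 95% of seeds

    def test_all_halflives_missing_rejected(self, rng):
        tree = tv.upgma(random_distance_matrix(rng, 4))
        with pytest.raises(ValueError, match="missing"):
            tv.find_hotspot(tree, {t: None for t in tree.leaf_ids})


class TestClusterNull:
    def _tree_and_halflives(self, seed, n=20):
        local = np.random.default_rng(seed)
        m = random_distance_matrix(local, n)
        tree = tv.upgma(m)
        hl = {t: float(local.uniform(2, 180)) for t in tree.leaf_ids}
        return tree, hl

    def test_p_bounds_and_add_one_convention(self):
        tree, hl = self._tree_and_halflives(0)
        b = 99
        # observed purity above any achievable replicate -> smallest p
        p_min = tv.cluster_enrichment_null(tree, hl, observed_purity=2.0, b=b, seed=1)
        assert p_min == pytest.approx(1.0 / (b + 1))
        # observed below every replicate max -> p = 1
        p_max = tv.cluster_enrichment_null(tree, hl, observed_purity=-1.0, b=b, seed=1)
        assert p_max == 1.0

    def test_monotone_nonincreasing_in_observed(self):
        tree, hl = self._tree_and_halflives(1)
        ps = [
            tv.cluster_enrichment_null(tree, hl, observed_purity=o, b=199, seed=7)
            for o in (0.2, 0.5, 0.8, 1.0)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_planted_clade_significant(self):
        panel, _ = tv.generate_panel(
            tv.PanelSpec(
                n_tcrs=40, seed=0, motif="NEIK", motif_rate=1.0, high_fraction=0.25,
                halflife_ranges=((2.0, 8.0), (65.0, 180.0)),
            )
        )
        tree = tv.upgma(tv.distance_matrix(panel))
        hl = {c.tcr_id: c.halflife_s for c in panel}
        hs = tv.find_hotspot(tree, hl, threshold_s=10.0, min_size=5)
        p = tv.cluster_enrichment_null(
            tree, hl, hs.purity, threshold_s=10.0, min_size=5, b=999, seed=3
        )
        assert p <= 0.01

    def test_requires_at_least_one_replicate(self):
        tree, hl = self._tree_and_halflives(2)
        with pytest.raises(ValueError):
            tv.cluster_enrichment_null(tree, hl, 0.5, b=0)
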