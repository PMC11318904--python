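"""PhyloSor / Sorensen decomposition, COMDIST and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import dendropy
from commphylo import (
    CommunityMatrix,
    beta_matrices,
    cluster_dendrogram,
    comdist,
    comdist_matrix,
    cophenetic_distances,
    phylosor_pair,
    sorensen_pair,
)
from commphylo.errors import DomainError, ValidationError
from commphylo.trees import tree_from_newick


def _matrix_from(tree, communities: dict):
    species = sorted({sp for taxa in communities.values() for sp in taxa})
    rows = [[1 if sp in taxa else 0 for sp in species] for taxa in communities.values()]
    return CommunityMatrix(pd.DataFrame(rows, index=list(communities), columns=species))


class TestPhyloSor:
    def test_identical_communities(self, four_tip_tree):
        _, dec = phylosor_pair(["A", "B"], ["A", "B"], four_tip_tree)
        assert dec.beta_sor == 0.0 and dec.similarity == 1.0
        assert dec.beta_sim == 0.0 and dec.beta_sne == 0.0

    def test_worked_pair(self, four_tip_tree):
        comp, dec = phylosor_pair(["A", "B"], ["A", "C"], four_tip_tree)
        assert (comp.a, comp.b, comp.c) == (2.0, 1.0, 2.0)
        assert dec.beta_sor == pytest.approx(3 / 7)
        assert dec.beta_sim == pytest.approx(1 / 3)
        assert dec.beta_sne == pytest.approx(2 / 21)

    def test_symmetric_pair_is_pure_turnover(self, four_tip_tree):
        _, dec = phylosor_pair(["A", "B"], ["C", "D"], four_tip_tree)
        assert dec.beta_sne == pytest.approx(0.0, abs=1e-12)
        assert dec.beta_sim == pytest.approx(dec.beta_sor)

    def test_components_sum_to_pd(self, random_tree_factory):
        tree = random_tree_factory(20, seed=14)
        rng = np.random.default_rng(14)
        for _ in range(20):
            t1 = list(rng.choice(tree.tip_labels, size=6, replace=False))
            t2 = list(rng.choice(tree.tip_labels, size=4, replace=False))
            comp, _ = phylosor_pair(t1, t2, tree)
            assert comp.a + comp.b == pytest.approx(tree.faith_pd(t1), abs=1e-9)
            assert comp.a + comp.c == pytest.approx(tree.faith_pd(t2), abs=1e-9)

    def test_empty_community_rejected(self, four_tip_tree):
        with pytest.raises(DomainError):
            phylosor_pair([], ["A"], four_tip_tree)


class TestSorensen:
    def test_worked_examples(self):
        _, dec = sorensen_pair(["A", "B"], ["A", "C"])
        assert dec.beta_sor == pytest.approx(0.5)
        assert dec.beta_sim == pytest.approx(0.5)
        assert dec.beta_sne == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_sets(self):
        _, dec = sorensen_pair(["A", "B"], ["C", "D"])
        assert dec.beta_sor == 1.0

    def test_nested_sets_pure_nestedness(self):
        _, dec = sorensen_pair(["A", "B", "C"], ["A", "B"])
        assert dec.beta_sim == 0.0
        assert dec.beta_sne == pytest.approx(1 / 5)
        assert dec.beta_sor == pytest.approx(1 / 5)

    def test_star_tree_phylosor_degenerates_to_species(self):
        star = tree_from_newick("(A:1,B:1,C:1,D:1,E:1);")
        taxa = list("ABCDE")
        rng = np.random.default_rng(3)
        for _ in range(15):
            t1 = list(rng.choice(taxa, size=rng.integers(1, 5), replace=False))
            t2 = list(rng.choice(taxa, size=rng.integers(1, 5), replace=False))
            _, phylo = phylosor_pair(t1, t2, star)
            _, spec = sorensen_pair(t1, t2)
            assert phylo.beta_sor == pytest.approx(spec.beta_sor, abs=1e-12)
            assert phylo.beta_sim == pytest.approx(spec.beta_sim, abs=1e-12)


class TestBetaMatrices:
    def test_identical_sites_all_zero(self, four_tip_tree):
        m = _matrix_from(four_tip_tree, {"100": ["A", "B"], "200": ["A", "B"]})
        mats = beta_matrices(m, four_tip_tree)
        assert np.allclose(mats.sor.data, 0) and np.allclose(mats.sne.data, 0)

    def test_decomposition_identity_elementwise(self, random_tree_factory,
                                                random_matrix_factory):
        tree = random_tree_factory(25, seed=6)
        m = random_matrix_factory(tree, n_sites=6, richness=7, seed=6)
        for mats in (beta_matrices(m, tree), beta_matrices(m, tree=None)):
            assert np.allclose(mats.sor.data, mats.sim.data + mats.sne.data, atol=1e-12)
            assert (mats.sor.data >= -1e-12).all() and (mats.sor.data <= 1 + 1e-12).all()

    def test_nested_gradient_is_pure_nestedness(self, random_tree_factory):
        tree = random_tree_factory(30, seed=7)
        taxa = tree.tip_labels
        m = _matrix_from(
            tree, {"100": taxa[:12], "200": taxa[:8], "300": taxa[:4]}
        )
        mats = beta_matrices(m, tree=None)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(mats.sim.data[off], 0.0, atol=1e-12)
        assert (mats.sne.data[off] > 0).all()


class TestComdist:
    def test_cross_pairs(self, four_tip_tree, four_tip_dist):
        assert comdist(["A", "B"], ["C", "D"], four_tip_dist) == pytest.approx(4.0)
        assert comdist(["A"], ["A"], four_tip_dist) == 0.0

    def test_symmetry_and_oracle(self, random_tree_factory):
        tree = random_tree_factory(15, seed=19)
        D = cophenetic_distances(tree)
        rng = np.random.default_rng(19)
        t1 = list(rng.choice(tree.tip_labels, size=5, replace=False))
        t2 = list(rng.choice(tree.tip_labels, size=6, replace=False))
        brute = np.mean([[D[a, b] for b in t2] for a in t1])
        assert comdist(t1, t2, D) == pytest.approx(brute)
        assert comdist(t1, t2, D) == pytest.approx(comdist(t2, t1, D))

    def test_matrix_shape(self, random_tree_factory, random_matrix_factory):
        tree = random_tree_factory(20, seed=1)
        m = random_matrix_factory(tree, n_sites=5, richness=4, seed=2)
        cd = comdist_matrix(m, tree)
        assert cd.shape == (5, 5)
        assert np.allclose(cd.data, cd.data.T)


def _agglomerative_oracle(D, method):
    """Textbook agglomerative clustering: merge orders only."""
    clusters = {i: [i] for i in range(D.shape[0])}
    merges = []
    nxt = D.shape[0]
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            dists = [D[a, b] for a in clusters[i] for b in clusters[j]]
            d = {"average": np.mean, "complete": np.max, "single": np.min}[method](dists)
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        clusters[nxt] = clusters.pop(i) + clusters.pop(j)
        merges.append((frozenset([i, j]), d))
        nxt += 1
    return merges


class TestDendrogram:
    def test_forced_topology(self):
        dm = DistanceMatrix(
            np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], float), ids=["1", "2", "3"]
        )
        dg = cluster_dendrogram(dm, method="average")
        assert dg.merges[0][2] == pytest.approx(1.0)  # raw merge height
        assert set(dg.merges[0][:2].astype(int)) == {0, 1}  # sisters 1 and 2
        nwk = dg.to_newick()
        t = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(t.leaf_nodes()) == 3

    def test_all_equal_distances_merge_at_same_height(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
        dg = cluster_dendrogram(dm, method="single")
        assert np.allclose(dg.merges[:, 2], 1.0)

    @pytest.mark.parametrize("method", ["average", "complete", "single"])
    def test_matches_textbook_oracle(self, method):
        rng = np.random.default_rng(23)
        pts = rng.normal(size=(6, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(D, ids=[str(i) for i in range(6)])
        dg = cluster_dendrogram(dm, method=method)
        oracle = _agglomerative_oracle(D, method)
        for k, (pair, d) in enumerate(oracle):
            assert dg.merges[k][2] == pytest.approx(d, abs=1e-9)

    def test_asymmetric_input_rejected(self):
        bad_data = np.zeros((3, 3))
        bad_data[0, 1], bad_data[1, 0] = 1.0, 2.0
        fake = type("FakeDM", (), {"data": bad_data, "ids": list("abc")})()
        with pytest.raises(ValidationError, match="symmetric"):
            cluster_dendrogram(fake, "average")
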