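import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from divpulse.distmodels import DistanceMatrix
from divpulse.errors import RootingError, TreeError
from divpulse.treebuild import (
    nj_build,
    node_ages,
    pairwise_mrca_ages,
    read_newick,
    root_with_outgroup,
    upgma_build,
    write_newick,
)


def _dm(labels, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(labels), d, np.full_like(d, 100.0))


def _random_tree_matrix(rng, n):
    """A random rooted binary tree with positive branch lengths and its
    additive (patristic) distance matrix."""
    nodes = [dendropy.Node() for _ in range(n)]
    tns = dendropy.TaxonNamespace()
    for i, nd in enumerate(nodes):
        nd.taxon = tns.require_taxon(label=f"L{i}")
    pool = list(nodes)
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[i], pool[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = rng.uniform(0.1, 1.0)
        b.edge.length = rng.uniform(0.1, 1.0)
        pool[i] = parent
        del pool[j]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = pool[0]
    tree.is_rooted = True
    pdm = tree.phylogenetic_distance_matrix()
    labels = [f"L{i}" for i in range(n)]
    taxa = {t.label: t for t in tns}
    D = np.array(
        [[pdm.patristic_distance(taxa[a], taxa[b]) if a != b else 0.0 for b in labels] for a in labels]
    )
    return tree, _dm(labels, D)


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return out


class TestNeighbourJoining:
    def test_three_taxa_closed_form(self):
        dm = _dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = nj_build(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_matrix_reproduced_exactly(self, rng):
        for _ in range(5):
            true_tree, dm = _random_tree_matrix(rng, 7)
            est = nj_build(dm)
            order = sorted(dm.taxon_ids)
            idx = [dm.taxon_ids.index(t) for t in order]
            assert np.allclose(_patristic(est), dm.d[np.ix_(idx, idx)], atol=1e-9)

    def test_matches_dendropy_nj_topology(self, rng):
        # independent implementation cross-check on noisy (non-additive) input
        for _ in range(5):
            _, dm = _random_tree_matrix(rng, 8)
            noisy = dm.d + rng.uniform(0, 0.02, dm.d.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0)
            dm_noisy = _dm(dm.taxon_ids, noisy)
            ours = nj_build(dm_noisy)
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=_to_csv(dm_noisy), delimiter=","
            )
            ref = pdm.nj_tree()
            tns = ref.taxon_namespace
            ours2 = dendropy.Tree.get(
                data=write_newick(ours), schema="newick", taxon_namespace=tns
            )
            for t in (ref, ours2):
                t.encode_bipartitions()
            assert treecompare.symmetric_difference(ref, ours2) == 0

    def test_atteson_noise_tolerance(self, rng):
        # perturbations below half the smallest internal branch keep topology
        for _ in range(5):
            true_tree, dm = _random_tree_matrix(rng, 8)
            internal = [
                nd.edge.length
                for nd in true_tree.preorder_node_iter()
                if nd.edge.length and not nd.is_leaf()
            ]
            eps = min(internal) / 2.0
            noise = rng.uniform(-eps / 2, eps / 2, dm.d.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            est = nj_build(_dm(dm.taxon_ids, dm.d + noise))
            tns = true_tree.taxon_namespace
            est2 = dendropy.Tree.get(
                data=write_newick(est), schema="newick", taxon_namespace=tns
            )
            ref = true_tree.clone(depth=1)
            ref.is_rooted = False
            for t in (ref, est2):
                t.encode_bipartitions()
            assert treecompare.symmetric_difference(ref, est2) == 0

    def test_undefined_entries_rejected(self):
        d = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(TreeError, match="undefined"):
            nj_build(_dm("ABC", d))

    def test_needs_three_taxa(self):
        with pytest.raises(TreeError):
            nj_build(_dm("AB", [[0, 1], [1, 0]]))


def _to_csv(dm):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(dm.taxon_ids) + "\n")
    for t, row in zip(dm.taxon_ids, dm.d):
        buf.write(t + "," + ",".join(f"{v:.10f}" for v in row) + "\n")
    buf.seek(0)
    return buf


class TestUpgma:
    def test_two_taxa(self):
        tree = upgma_build(_dm("AB", [[0, 0.4], [0.4, 0]]))
        ages = node_ages(tree)
        assert ages.crown_age == pytest.approx(0.2)

    def test_recovers_ultrametric_tree(self, rng):
        from divpulse.bd_null import BDParams, simulate_bd_tree

        true = simulate_bd_tree(BDParams(0.3), 12, seed=rng)
        labels = sorted(lf.taxon.label for lf in true.leaf_node_iter())
        idx = {t: i for i, t in enumerate(labels)}
        pd = _patristic(true)
        est = upgma_build(_dm(labels, pd))
        assert np.allclose(_patristic(est), pd, atol=1e-9)
        true_ages = node_ages(true).ages
        est_ages = node_ages(est).ages
        assert np.allclose(np.sort(true_ages), np.sort(est_ages), atol=1e-9)

    def test_undefined_entries_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(TreeError):
            upgma_build(_dm("AB", d))


class TestRooting:
    def test_quartet_single_outgroup(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=False)
        rooted = root_with_outgroup(t, {"A"})
        kids = rooted.seed_node.child_nodes()
        sides = [{lf.taxon.label for lf in k.leaf_iter()} for k in kids]
        assert {"A"} in sides

    def test_non_adjacent_outgroup_rejected(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=False)
        with pytest.raises(RootingError, match="monophyletic"):
            root_with_outgroup(t, {"A", "C"})

    def test_midpoint_split_of_outgroup_branch(self):
        t = read_newick("((A:1,B:2):0.5,(C:1,D:1):0.5,E:3);", rooted=False)
        rooted = root_with_outgroup(t, {"E"})
        e_leaf = next(lf for lf in rooted.leaf_node_iter() if lf.taxon.label == "E")
        assert e_leaf.edge.length == pytest.approx(1.5)

    def test_recovers_true_root_on_simulated_tree(self, rng):
        from divpulse.bd_null import BDParams, simulate_bd_tree
        from divpulse.synthgen import graft_outgroup

        ingroup = simulate_bd_tree(BDParams(0.3), 10, seed=rng)
        crown = node_ages(ingroup).crown_age
        full = graft_outgroup(ingroup, label="OG", stem_age=crown * 1.5)
        unrooted = read_newick(write_newick(full), rooted=False)
        rerooted = root_with_outgroup(unrooted, {"OG"})
        sides = [
            {lf.taxon.label for lf in k.leaf_iter()}
            for k in rerooted.seed_node.child_nodes()
        ]
        assert {"OG"} in sides
        # rooted topology equals the truth (same ingroup clades)
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=write_newick(full), schema="newick", taxon_namespace=tns)
        b = dendropy.Tree.get(data=write_newick(rerooted), schema="newick", taxon_namespace=tns)
        for t in (a, b):
            t.is_rooted = False
            t.encode_bipartitions()
        assert treecompare.symmetric_difference(a, b) == 0


class TestNodeAges:
    def test_cherry_under_root(self):
        t = read_newick("((A:5,B:5):5,C:10);", rooted=True)
        bt = node_ages(t)
        assert bt.n_tips == 3
        assert np.allclose(bt.ages, [10.0, 5.0])

    def test_non_ultrametric_rejected(self):
        t = read_newick("((A:1,B:3):1,C:10);", rooted=True)
        with pytest.raises(TreeError, match="ultrametric"):
            node_ages(t)

    def test_simulator_bookkeeping_matches(self, rng):
        from divpulse.bd_null import BDParams, simulate_bd_tree

        tree = simulate_bd_tree(BDParams(0.2), 15, seed=rng)
        bt = node_ages(tree)
        assert bt.ages.size == 14
        assert bt.ages[0] == bt.crown_age
        assert np.all(np.diff(bt.ages) <= 1e-12)

    def test_pairwise_mrca_ages_against_patristic(self, rng):
        from divpulse.bd_null import BDParams, simulate_bd_tree

        tree = simulate_bd_tree(BDParams(0.3), 10, seed=rng)
        ages = np.sort(pairwise_mrca_ages(tree))
        brute = np.sort(_patristic(tree)[np.triu_indices(10, 1)] / 2.0)
        assert np.allclose(ages, brute, atol=1e-9)
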