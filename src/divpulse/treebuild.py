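"""Distance-based tree building on dendropy trees.

Neighbour-joining (Saitou-Nei agglomeration with the Studier-Keppler
Q-matrix) supplies the rooted-by-outgroup tree for the clock screen; UPGMA
supplies the ultrametric tree whose node ages feed the birth-death fit.
Trees are plain :class:`dendropy.Tree` objects throughout, so newick I/O and
traversal come for free.

Determinism: ties in the Q-matrix (and in UPGMA merges) are broken by the
lowest index pair in current matrix order, which is the original taxon order
followed by cluster-creation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .distmodels import DistanceMatrix
from .errors import RootingError, TreeError


_TRIU_CACHE: dict = {}


def _triu_cache(k: int):
    if k not in _TRIU_CACHE:
        _TRIU_CACHE[k] = np.triu_indices(k, 1)
    return _TRIU_CACHE[k]


def _check_defined(dm: DistanceMatrix) -> None:
    if np.isnan(dm.d).any():
        pairs = dm.undefined_pairs
        raise TreeError(f"distance matrix has undefined (saturated) entries: {pairs[:5]}")


def _leaf_nodes(taxon_ids, tns):
    nodes = []
    for t in taxon_ids:
        taxon = tns.require_taxon(label=t)
        nd = dendropy.Node(taxon=taxon)
        nodes.append(nd)
    return nodes


def nj_build(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbour-joining tree (unrooted, trifurcating at the seed node).

    Negative limb estimates are clamped to zero with the deficit moved to the
    sister limb, so the joined pair's path length is preserved.
    """
    n = dm.n_taxa
    if n < 3:
        raise TreeError("neighbour-joining needs >= 3 taxa")
    _check_defined(dm)
    tns = dendropy.TaxonNamespace()
    nodes = _leaf_nodes(dm.taxon_ids, tns)
    D = np.zeros((2 * n, 2 * n))  # preallocated; grows by one row per join
    D[:n, :n] = dm.d
    active = list(range(n))  # indices into `nodes`
    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (k - 2) * sub - R[:, None] - R[None, :]
        iu = _triu_cache(k)
        flat = Q[iu]
        best = int(np.argmin(flat))  # first minimum = lowest (i, j) pair
        i, j = iu[0][best], iu[1][best]
        dij = sub[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        ni, nj = nodes[active[i]], nodes[active[j]]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        # distances from the new node to the remaining clusters
        others = [a for idx, a in enumerate(active) if idx not in (i, j)]
        newd = 0.5 * (D[active[i], others] + D[active[j], others] - dij)
        u = len(nodes)
        nodes.append(parent)
        D[u, others] = newd
        D[others, u] = newd
        active = [a for idx, a in enumerate(active) if idx not in (i, j)] + [u]
    # resolve the final three clusters around a central node
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    center = dendropy.Node()
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def upgma_build(dm: DistanceMatrix) -> dendropy.Tree:
    """UPGMA (average linkage) tree: rooted and ultrametric by construction,
    node heights equal to half the merge distance."""
    n = dm.n_taxa
    if n < 2:
        raise TreeError("UPGMA needs >= 2 taxa")
    _check_defined(dm)
    tns = dendropy.TaxonNamespace()
    nodes = _leaf_nodes(dm.taxon_ids, tns)
    heights = [0.0] * n
    sizes = [1] * n
    D = np.zeros((2 * n, 2 * n))
    D[:n, :n] = dm.d
    active = list(range(n))
    while len(active) > 1:
        k = len(active)
        sub = D[np.ix_(active, active)]
        iu = _triu_cache(k)
        best = int(np.argmin(sub[iu]))
        i, j = iu[0][best], iu[1][best]
        ai, aj = active[i], active[j]
        h = 0.5 * sub[i, j]
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        nodes[ai].edge.length = max(h - heights[ai], 0.0)
        nodes[aj].edge.length = max(h - heights[aj], 0.0)
        others = [a for idx, a in enumerate(active) if idx not in (i, j)]
        wi, wj = sizes[ai], sizes[aj]
        newd = (wi * D[ai, others] + wj * D[aj, others]) / (wi + wj)
        u = len(nodes)
        nodes.append(parent)
        heights.append(h)
        sizes.append(wi + wj)
        D[u, others] = newd
        D[others, u] = newd
        active = others + [u]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[active[0]]
    tree.is_rooted = True
    return tree


def _leafset_masks(tree: dendropy.Tree) -> dict:
    """Bitmask of leaf labels below each node (under the current orientation)."""
    order = {lf.taxon.label: i for i, lf in enumerate(tree.leaf_node_iter())}
    masks: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            masks[nd] = 1 << order[nd.taxon.label]
        else:
            m = 0
            for ch in nd.child_nodes():
                m |= masks[ch]
            masks[nd] = m
    return masks, order


def root_with_outgroup(tree: dendropy.Tree, outgroup, clone: bool = True) -> dendropy.Tree:
    """Root on the branch separating the outgroup from the ingroup, splitting
    that branch at its midpoint.

    The outgroup must be a proper non-empty subset of the leaves and must be
    monophyletic in the unrooted tree.  ``clone=False`` reroots in place
    (used in hot loops on freshly built trees).
    """
    outgroup = set(outgroup)
    if clone:
        tree = tree.clone(depth=1)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not outgroup or not outgroup < leaves:
        missing = outgroup - leaves
        raise RootingError(
            f"outgroup must be a proper nonempty leaf subset; missing={sorted(missing)}"
        )
    masks, order = _leafset_masks(tree)
    og_mask = 0
    for t in outgroup:
        og_mask |= 1 << order[t]
    full = masks[tree.seed_node]
    target = None
    for nd in tree.postorder_node_iter():
        if nd is tree.seed_node:
            continue
        if masks[nd] == og_mask or masks[nd] == full ^ og_mask:
            target = nd
            break
    if target is None:
        raise RootingError(
            f"outgroup {sorted(outgroup)} is not monophyletic in the unrooted tree"
        )
    edge_len = target.edge.length or 0.0
    half = 0.5 * edge_len
    tree.reroot_at_edge(target.edge, length1=half, length2=half, update_bipartitions=False)
    tree.is_rooted = True
    return tree


@dataclass
class BranchingTimes:
    """Internal node ages (Ma), sorted descending; ages[0] is the crown age."""

    ages: np.ndarray
    n_tips: int

    def __post_init__(self) -> None:
        self.ages = np.sort(np.asarray(self.ages, dtype=float))[::-1]
        if (self.ages < 0).any():
            raise ValueError("node ages must be >= 0")
        if self.ages.size != self.n_tips - 1:
            raise ValueError(
                f"expected n_tips - 1 = {self.n_tips - 1} ages, got {self.ages.size}"
            )

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])


def node_depths(tree: dendropy.Tree) -> dict:
    depths = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
    return depths


def node_ages(tree: dendropy.Tree, tol: float = 1e-6) -> BranchingTimes:
    """Ages of the internal nodes of a rooted ultrametric tree.

    Age = crown age minus root-to-node depth.  Leaves must all sit at the
    same depth within ``tol`` (relative to the crown depth).
    """
    depths = node_depths(tree)
    leaf_d = np.array([depths[lf] for lf in tree.leaf_node_iter()])
    crown = leaf_d.mean()
    scale = max(crown, 1.0)
    if np.ptp(leaf_d) > tol * scale:
        raise TreeError(
            f"tree is not ultrametric: leaf depth spread {np.ptp(leaf_d):.3g} "
            f"exceeds tolerance"
        )
    ages = [
        crown - depths[nd]
        for nd in tree.preorder_internal_node_iter()
    ]
    return BranchingTimes(np.clip(ages, 0.0, None), n_tips=len(leaf_d))


def pairwise_mrca_ages(tree: dendropy.Tree) -> np.ndarray:
    """All (tip choose 2) MRCA ages of a rooted ultrametric tree.

    In an ultrametric tree the patristic distance between two tips is twice
    their MRCA age, so these are the tip-pair ages the null ensemble needs.
    """
    depths = node_depths(tree)
    leaf_d = [depths[lf] for lf in tree.leaf_node_iter()]
    crown = float(np.mean(leaf_d))
    counts: dict = {}
    vals = []
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            counts[nd] = 1
            continue
        sizes = [counts[ch] for ch in nd.child_nodes()]
        counts[nd] = sum(sizes)
        cross = (sum(sizes) ** 2 - sum(s * s for s in sizes)) // 2
        vals.extend([crown - depths[nd]] * cross)
    return np.clip(np.asarray(vals, dtype=float), 0.0, None)


def read_newick(path_or_str, rooted: bool | None = None) -> dendropy.Tree:
    src = str(path_or_str)
    kwargs = dict(schema="newick", preserve_underscores=True)
    if "(" in src:
        tree = dendropy.Tree.get(data=src, **kwargs)
    else:
        tree = dendropy.Tree.get(path=src, **kwargs)
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s
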