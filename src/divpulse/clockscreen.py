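"""Molecular-clock screening by the root-to-tip branch-length test.

Each ingroup tip's root-to-tip path length on an outgroup-rooted
neighbour-joining tree is compared with the mean over the other ingroup
tips.  The standard error of that deviation is estimated by a bootstrap over
alignment columns (resample columns, recompute distances, NJ, rooting,
root-to-tip), which keeps the test model-agnostic.  Tips whose two-sided
normal p-value falls below alpha are flagged as clock-deviant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .distmodels import PairTally, distances_from_tallies
from .errors import RootingError, TreeError
from .seqdata import AlignedSeqSet, PartitionScheme
from .treebuild import nj_build, node_depths, root_with_outgroup
from scipy.spatial.distance import squareform
from .distmodels import DistanceMatrix


def root_to_tip(tree, taxon: str) -> float:
    """Sum of branch lengths on the root-to-leaf path."""
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == taxon:
            d = 0.0
            nd = lf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            return d
    raise KeyError(f"taxon {taxon!r} is not a leaf of the tree")


def _root_to_tip_all(tree) -> dict[str, float]:
    depths = node_depths(tree)
    return {lf.taxon.label: depths[lf] for lf in tree.leaf_node_iter()}


@dataclass
class ClockScreenReport:
    frame: pd.DataFrame  # taxon, root_to_tip, deviation, z, p, flagged
    mean_root_to_tip: float
    outgroup: list[str]
    alpha: float
    n_boot: int
    n_boot_effective: int
    seed: int | None

    @property
    def flagged(self) -> list[str]:
        return self.frame.loc[self.frame["flagged"], "taxon"].tolist()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


class _DistanceRecomputer:
    """Weighted-column recomputation of the combined distance matrix."""

    def __init__(self, aln: AlignedSeqSet, scheme: PartitionScheme):
        self.n_taxa = aln.n_taxa
        self.n_sites = aln.n_sites
        self.taxon_ids = list(aln.taxon_ids)
        self.parts = []
        for p in scheme.partitions:
            if p.model is None:
                raise ValueError(f"partition {p.name!r} has no model")
            if p.model.family == "GTR" or p.model.prop_invariant:
                raise ValueError(
                    "the bootstrap clock test needs a closed-form distance model "
                    f"(partition {p.name!r} is GTR/+I); use JC69/K2P/TN93"
                )
            sub = AlignedSeqSet(
                self.taxon_ids, aln.codes[:, p.columns], aln.partition_of[p.columns]
            )
            self.parts.append((PairTally(sub), p.model, p.columns))

    def matrix(self, weights: np.ndarray | None = None) -> DistanceMatrix:
        n = self.n_taxa
        num = None
        den = None
        sup = None
        for tally, model, cols in self.parts:
            w = None if weights is None else weights[cols]
            t = tally.tallies(w)
            d, s = distances_from_tallies(t, model)
            defined = ~np.isnan(d)
            contrib = np.where(defined, d * s, 0.0)
            dd = np.where(defined, s, 0.0)
            if num is None:
                num, den, sup = contrib, dd, s.copy()
            else:
                num = num + contrib
                den = den + dd
                sup = sup + s
        with np.errstate(invalid="ignore", divide="ignore"):
            dvec = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
        return DistanceMatrix(self.taxon_ids, squareform(dvec), squareform(sup))


def branch_length_test(
    aln: AlignedSeqSet,
    scheme: PartitionScheme,
    outgroup,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | None = None,
) -> ClockScreenReport:
    """Flag tips whose substitution rate deviates from the ingroup average.

    Single-pass (no sequential re-testing): the flagged set is decided from
    one round of p-values, mirroring a one-shot removal of rate-deviant
    sequences before distance-based dating.
    """
    outgroup = list(outgroup)
    missing = [t for t in outgroup if t not in aln.taxon_ids]
    if missing:
        raise KeyError(f"outgroup taxa not in alignment: {missing}")
    ingroup = [t for t in aln.taxon_ids if t not in outgroup]
    if len(ingroup) < 4:
        raise ValueError("need >= 4 ingroup taxa for the branch length test")
    if n_boot < 50:
        warnings.warn(
            f"n_boot={n_boot} is small; standard errors will be noisy", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    recomputer = _DistanceRecomputer(aln, scheme)

    def deviations(weights=None) -> np.ndarray | None:
        dm = recomputer.matrix(weights)
        if np.isnan(dm.d).any():
            return None
        tree = nj_build(dm)
        try:
            rooted = root_with_outgroup(tree, outgroup, clone=False)
        except RootingError:
            if weights is None:
                raise
            rooted = root_with_outgroup(tree, [outgroup[0]], clone=False)
        rtt = _root_to_tip_all(rooted)
        D = np.array([rtt[t] for t in ingroup])
        m = len(D)
        mean_others = (D.sum() - D) / (m - 1)
        return np.column_stack([D, D - mean_others])

    obs = deviations()
    if obs is None:
        raise TreeError("distance matrix has undefined entries; cannot run clock test")
    D_obs, dev_obs = obs[:, 0], obs[:, 1]

    boot_devs = []
    for _ in range(n_boot):
        counts = rng.multinomial(aln.n_sites, np.full(aln.n_sites, 1.0 / aln.n_sites))
        res = deviations(counts.astype(float))
        if res is not None:
            boot_devs.append(res[:, 1])
    n_eff = len(boot_devs)
    if n_eff < max(2, n_boot // 2):
        raise TreeError(
            f"only {n_eff}/{n_boot} bootstrap replicates produced defined distances"
        )
    se = np.std(np.asarray(boot_devs), axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, dev_obs / np.maximum(se, 1e-300), 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    frame = pd.DataFrame(
        {
            "taxon": ingroup,
            "root_to_tip": D_obs,
            "deviation": dev_obs,
            "z": z,
            "p": p,
            "flagged": p < alpha,
        }
    )
    return ClockScreenReport(
        frame=frame,
        mean_root_to_tip=float(D_obs.mean()),
        outgroup=outgroup,
        alpha=alpha,
        n_boot=n_boot,
        n_boot_effective=n_eff,
        seed=seed,
    )
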