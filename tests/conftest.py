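import numpy as np
import pytest

from divpulse.bd_null import BDParams, simulate_bd_tree
from divpulse.distmodels import ModelSpec
from divpulse.seqdata import Partition, PartitionScheme
from divpulse.synthgen import default_scheme, evolve_sequences, graft_outgroup
from divpulse.treebuild import node_ages


def homogeneous_schemes():
    """(simulation scheme, estimation scheme) without codon-rate substructure,
    so the TN93 distance model is correctly specified (HKY is nested in it)."""
    sim = default_scheme()
    for p in sim.partitions:
        p.codon_rate_mult = None
    est = PartitionScheme(
        [Partition(p.name, p.columns, model=ModelSpec.tn93()) for p in sim.partitions]
    )
    return sim, est


def clock_dataset(seed, n_tips=40, birth=0.05, tip_rate_mult=None):
    """A strict-clock two-gene alignment on a birth-death ingroup plus outgroup."""
    sim_scheme, est_scheme = homogeneous_schemes()
    ss = np.random.SeedSequence(seed)
    s_tree, s_seq = ss.spawn(2)
    tree = simulate_bd_tree(BDParams(birth), n_tips, seed=np.random.default_rng(s_tree))
    full = graft_outgroup(tree, stem_age=node_ages(tree).crown_age * 1.3)
    aln = evolve_sequences(
        full, sim_scheme, clock_sigma=0.0, seed=s_seq, tip_rate_mult=tip_rate_mult
    )
    return aln, est_scheme, tree


def longest_terminal_leaf(tree):
    return max(
        ((lf.taxon.label, lf.edge.length) for lf in tree.leaf_node_iter()),
        key=lambda x: x[1],
    )[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
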