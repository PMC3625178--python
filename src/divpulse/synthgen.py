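"""Synthetic data with known ground truth: pulsed birth-death trees and
clock(ish) sequence alignments.

The generator emulates the study shape every pipeline stage expects: an
ingroup clade whose diversification includes short high-rate episodes
(pulses) that concentrate node ages in narrow windows, an outgroup grafted
below the crown, and a two-partition alignment (a codon-structured
COI-like gene and a slower 28S-like gene) evolved along the tree in absolute
time.  Branch-rate noise is lognormal with a mean-one correction
(exp(eta), eta ~ N(-sigma^2/2, sigma^2)); sigma = 0 gives a strict clock.

Randomness flows through three named streams spawned from one seed, in this
order: tree, rates (branch noise), sites (root states, site categories,
substitutions, mask columns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .bd_null import (
    MAX_REJECTED_RUNS,
    BDParams,
    _gillespie,
    _reconstructed_tree,
    simulate_bd_tree,
)
from .distmodels import ModelSpec, rate_matrix, site_rate_mixture, transition_probs
from .errors import FeasibilityError, TreeError
from .seqdata import AlignedSeqSet, Partition, PartitionScheme
from .treebuild import node_ages, node_depths, write_newick


@dataclass
class PulseSpec:
    """A birth-death history with episodic birth-rate multipliers.

    Episodes are (older age, younger age, multiplier) in Ma before present
    and must not overlap.  When episodes (or ``crown_age``) are given the
    crown is anchored at ``crown_age`` and the process runs forward to the
    present, so episode windows are exact; without them the simulation
    falls back to the stop-at-n rule of the plain birth-death simulator.
    """

    base: BDParams
    episodes: list[tuple[float, float, float]] = field(default_factory=list)
    n_tips: int = 40
    crown_age: float | None = None
    seed: int | None = None
    #: accepted relative deviation of the extant count from n_tips in
    #: crown-anchored runs (conditioned simulation); None disables
    tip_tolerance: float | None = 0.25

    def __post_init__(self) -> None:
        eps = []
        for (a, b, m) in self.episodes:
            older, younger = max(a, b), min(a, b)
            if younger < 0 or not m > 0:
                raise ValueError("episodes must lie in [0, inf) with multiplier > 0")
            eps.append((older, younger, float(m)))
        eps.sort(key=lambda e: -e[0])
        for (o1, y1, _), (o2, y2, _) in zip(eps[:-1], eps[1:]):
            if o2 > y1:
                raise ValueError("episodes must not overlap")
        self.episodes = eps
        if self.episodes and self.crown_age is None:
            raise ValueError("episodes need a crown_age anchor")
        if self.crown_age is not None and self.episodes:
            if self.episodes[0][0] >= self.crown_age:
                raise ValueError("episodes must be younger than the crown age")


@dataclass
class SyntheticTruth:
    """Ground truth for a generated dataset; round-trips through JSON."""

    newick: str
    node_ages: list[float]
    episodes: list[tuple[float, float, float]]
    crown_age: float
    partitions: list[dict]
    clock_sigma: float
    seed: int | None
    outgroup: list[str] = field(default_factory=list)

    @property
    def pulse_ages(self) -> list[float]:
        return [0.5 * (o + y) for o, y, _ in self.episodes]

    def nodes_in_episodes(self) -> int:
        return sum(
            1
            for a in self.node_ages
            if any(y <= a <= o for o, y, _ in self.episodes)
        )

    def to_json(self, path=None) -> str:
        d = {
            "newick": self.newick,
            "node_ages": list(map(float, self.node_ages)),
            "episodes": [list(e) for e in self.episodes],
            "crown_age": self.crown_age,
            "partitions": self.partitions,
            "clock_sigma": self.clock_sigma,
            "seed": self.seed,
            "outgroup": self.outgroup,
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, path_or_str) -> "SyntheticTruth":
        s = Path(path_or_str).read_text() if Path(str(path_or_str)).exists() else str(path_or_str)
        d = json.loads(s)
        return cls(
            newick=d["newick"],
            node_ages=d["node_ages"],
            episodes=[tuple(e) for e in d["episodes"]],
            crown_age=d["crown_age"],
            partitions=d["partitions"],
            clock_sigma=d["clock_sigma"],
            seed=d["seed"],
            outgroup=d.get("outgroup", []),
        )


def simulate_pulsed_tree(spec: PulseSpec, seed=None):
    """Forward birth-death with piecewise-constant birth rate b*m(age).

    Returns (rooted ultrametric tree in Ma, SyntheticTruth).  The truth
    records the realised node ages and the episode windows.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed if seed is not None else spec.seed)
    )
    if not spec.episodes and spec.crown_age is None:
        tree = simulate_bd_tree(spec.base, spec.n_tips, seed=rng)
        bt = node_ages(tree, tol=1e-6)
        truth = SyntheticTruth(
            newick=write_newick(tree).strip(),
            node_ages=bt.ages.tolist(),
            episodes=[],
            crown_age=bt.crown_age,
            partitions=[],
            clock_sigma=0.0,
            seed=spec.seed,
        )
        return tree, truth

    crown = spec.crown_age
    breaks: list[float] = []
    for older, younger, _ in spec.episodes:
        breaks.extend([crown - older, crown - younger])

    def birth_rate(t: float) -> float:
        age = crown - t
        for older, younger, mult in spec.episodes:
            if younger < age <= older:
                return spec.base.b * mult
        return spec.base.b

    for _ in range(MAX_REJECTED_RUNS):
        out = _gillespie(
            rng,
            birth_rate,
            spec.base.d,
            duration=crown,
            rate_breaks=tuple(breaks),
        )
        if out is None:
            continue
        tree = _reconstructed_tree(*out)
        if tree is None:
            continue
        n_leaves = sum(1 for _ in tree.leaf_node_iter())
        if spec.tip_tolerance is not None:
            lo = max(4, int(np.floor(spec.n_tips * (1 - spec.tip_tolerance))))
            hi = int(np.ceil(spec.n_tips * (1 + spec.tip_tolerance)))
            ok = lo <= n_leaves <= hi
        else:
            ok = n_leaves >= 4
        if ok:
            bt = node_ages(tree, tol=1e-6)
            truth = SyntheticTruth(
                newick=write_newick(tree).strip(),
                node_ages=bt.ages.tolist(),
                episodes=list(spec.episodes),
                crown_age=bt.crown_age,
                partitions=[],
                clock_sigma=0.0,
                seed=spec.seed,
            )
            return tree, truth
    raise FeasibilityError(
        f"persistent extinction: no run with >= 4 survivors in {MAX_REJECTED_RUNS} tries"
    )


def graft_outgroup(
    tree: dendropy.Tree, label: str = "OUT", stem_age: float = 75.0
) -> dendropy.Tree:
    """Attach an outgroup tip splitting from the ingroup stem at ``stem_age``."""
    bt = node_ages(tree, tol=1e-4)
    if stem_age <= bt.crown_age:
        raise ValueError("outgroup stem age must predate the ingroup crown age")
    tree = tree.clone(depth=1)
    old_root = tree.seed_node
    new_root = dendropy.Node()
    og = dendropy.Node(taxon=tree.taxon_namespace.require_taxon(label=label))
    og.edge.length = stem_age
    new_root.add_child(og)
    new_root.add_child(old_root)
    old_root.edge.length = stem_age - bt.crown_age
    tree.seed_node = new_root
    tree.is_rooted = True
    return tree


def evolve_sequences(
    tree: dendropy.Tree,
    scheme: PartitionScheme,
    clock_sigma: float = 0.0,
    seed=None,
    tip_rate_mult: dict[str, float] | None = None,
) -> AlignedSeqSet:
    """Evolve a multi-partition alignment along a rooted tree in Ma.

    Per branch, the expected substitutions/site in partition p are
    ``rate_p * duration * exp(eta)`` with eta ~ N(-sigma^2/2, sigma^2)
    drawn once per branch; ``tip_rate_mult`` additionally scales named
    terminal branches (for planting rate-deviant tips).  Site evolution uses
    the partition model's transition-probability matrices; +G models use 4
    discrete categories sampled once per site.
    """
    if not tree.is_rooted:
        raise TreeError("sequence evolution needs a rooted tree")
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    rng_rates, rng_sites = [np.random.default_rng(s) for s in ss.spawn(2)]
    tip_rate_mult = tip_rate_mult or {}

    parts = []
    offset = 0
    total = 0
    for p in scheme.partitions:
        if p.model is None or p.rate is None:
            raise ValueError(f"partition {p.name!r} needs a model and a rate")
        L = p.columns.size
        Q, pi = rate_matrix(p.model)
        rates, weights = site_rate_mixture(p.model)
        cat = rng_sites.choice(rates.size, size=L, p=weights)
        factors = rates[cat]
        if p.codon_rate_mult is not None:
            mult = np.asarray(p.codon_rate_mult, dtype=float)
            factors = factors * mult[np.arange(L) % 3]
        parts.append(
            {
                "name": p.name,
                "L": L,
                "Q": Q,
                "pi": pi,
                "rate": p.rate,
                "factors": factors,
                "offset": offset,
            }
        )
        offset += L
        total += L

    seqs: dict[int, np.ndarray] = {}
    root_seq = np.empty(total, dtype=np.uint8)
    for pt in parts:
        root_seq[pt["offset"] : pt["offset"] + pt["L"]] = rng_sites.choice(
            4, size=pt["L"], p=pt["pi"]
        )
    seqs[id(tree.seed_node)] = root_seq

    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        parent_seq = seqs[id(nd.parent_node)]
        duration = nd.edge.length or 0.0
        eta = (
            rng_rates.normal(-0.5 * clock_sigma**2, clock_sigma)
            if clock_sigma > 0
            else 0.0
        )
        mult = 1.0
        if nd.is_leaf() and nd.taxon.label in tip_rate_mult:
            mult = tip_rate_mult[nd.taxon.label]
        child_seq = parent_seq.copy()
        if duration > 0:
            for pt in parts:
                d_branch = pt["rate"] * duration * np.exp(eta) * mult
                sl = slice(pt["offset"], pt["offset"] + pt["L"])
                pseq = parent_seq[sl]
                out = child_seq[sl]
                for fval in np.unique(pt["factors"]):
                    sel = pt["factors"] == fval
                    if fval <= 0:
                        continue  # invariant sites copy through
                    P = transition_probs(pt["Q"], d_branch * fval, pt["pi"])
                    cum = np.cumsum(P, axis=1)
                    states = pseq[sel]
                    u = rng_sites.random(states.size)
                    out[sel] = (u[:, None] > cum[states]).sum(axis=1).astype(np.uint8)
        seqs[id(nd)] = child_seq

    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    codes = np.vstack([seqs[id(lf)] for lf in tree.leaf_node_iter()])
    partition_of = np.concatenate(
        [np.full(pt["L"], pt["name"], dtype=object) for pt in parts]
    )
    return AlignedSeqSet(taxa, codes, partition_of)


# ---------------------------------------------------------------------------
# Study-shaped dataset
# ---------------------------------------------------------------------------

#: Default two-pulse history: ~40 ingroup tips over a 60-Ma crown with short
#: x8 birth-rate episodes centred on 50 and 20 Ma.
DEFAULT_PULSE_SPEC = dict(
    b=0.035,
    d=0.0,
    episodes=[(51.0, 49.0, 8.0), (21.0, 19.0, 8.0)],
    n_tips=40,
    crown_age=60.0,
)

#: Default partition shapes and models: a codon-structured, faster COI-like
#: gene and a slower 28S-like gene (rates in subst/site/Ma).
DEFAULT_PARTITIONS = [
    dict(
        name="coi",
        n_sites=657,
        rate=5.0e-3,
        kappa=4.0,
        base_freqs=(0.28, 0.18, 0.22, 0.32),
        codon_rate_mult=(1.0, 0.5, 1.5),
        n_noisy=50,
    ),
    dict(
        name="r28s",
        n_sites=1013,
        rate=3.0e-3,
        kappa=3.0,
        base_freqs=(0.24, 0.25, 0.30, 0.21),
        codon_rate_mult=None,
        n_noisy=125,
    ),
]

OUTGROUP_LABEL = "OUT"
OUTGROUP_STEM_AGE = 75.0


def default_scheme(partitions=None) -> PartitionScheme:
    parts = []
    offset = 0
    for cfg in partitions or DEFAULT_PARTITIONS:
        model = ModelSpec.hky(cfg["kappa"], cfg["base_freqs"])
        parts.append(
            Partition(
                cfg["name"],
                np.arange(offset, offset + cfg["n_sites"]),
                model=model,
                rate=cfg["rate"],
                codon_rate_mult=cfg.get("codon_rate_mult"),
            )
        )
        offset += cfg["n_sites"]
    return PartitionScheme(parts)


@dataclass
class SyntheticDataset:
    out_dir: Path
    fasta_paths: dict[str, Path]
    mask_paths: dict[str, Path]
    truth_json: Path
    truth_newick: Path
    truth: SyntheticTruth


def make_dataset(
    out_dir,
    seed: int | None = 0,
    n_tips: int = 40,
    clock_sigma: float = 0.0,
    episodes=None,
    crown_age: float | None = 60.0,
    tip_rate_mult: dict[str, float] | None = None,
    partitions=None,
) -> SyntheticDataset:
    """Write a study-shaped two-gene dataset plus ground truth.

    Produces per-gene aligned FASTA files on the same taxa (ingroup plus one
    outgroup), per-gene "noisy column" mask files (random columns, 1-based),
    a truth newick (Ma) and a truth JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    ss_tree, ss_seq, ss_mask = ss.spawn(3)
    part_cfgs = partitions or DEFAULT_PARTITIONS

    eps = DEFAULT_PULSE_SPEC["episodes"] if episodes is None else episodes
    spec = PulseSpec(
        base=BDParams(DEFAULT_PULSE_SPEC["b"], DEFAULT_PULSE_SPEC["d"]),
        episodes=eps,
        n_tips=n_tips,
        crown_age=crown_age,
        seed=seed,
    )
    ingroup_tree, truth = simulate_pulsed_tree(spec, seed=np.random.default_rng(ss_tree))
    full_tree = graft_outgroup(
        ingroup_tree, label=OUTGROUP_LABEL, stem_age=OUTGROUP_STEM_AGE
    )

    scheme = default_scheme(part_cfgs)
    aln = evolve_sequences(
        full_tree,
        scheme,
        clock_sigma=clock_sigma,
        seed=ss_seq,
        tip_rate_mult=tip_rate_mult,
    )
    truth.clock_sigma = clock_sigma
    truth.outgroup = [OUTGROUP_LABEL]
    truth.partitions = [
        {
            "name": cfg["name"],
            "n_sites": cfg["n_sites"],
            "rate": cfg["rate"],
            "kappa": cfg["kappa"],
            "base_freqs": list(cfg["base_freqs"]),
            "codon_rate_mult": list(cfg["codon_rate_mult"])
            if cfg.get("codon_rate_mult")
            else None,
        }
        for cfg in part_cfgs
    ]

    rng_mask = np.random.default_rng(ss_mask)
    fasta_paths: dict[str, Path] = {}
    mask_paths: dict[str, Path] = {}
    for p, cfg in zip(scheme.partitions, part_cfgs):
        sub = AlignedSeqSet(
            list(aln.taxon_ids), aln.codes[:, p.columns], aln.partition_of[p.columns]
        )
        fp = out_dir / f"{p.name}.fasta"
        sub.write_fasta(fp)
        fasta_paths[p.name] = fp
        n_noisy = cfg.get("n_noisy", 0)
        mp = out_dir / f"{p.name}_mask.txt"
        cols = np.sort(rng_mask.choice(cfg["n_sites"], size=n_noisy, replace=False)) + 1
        mp.write_text(
            "# synthetic noisy columns (1-based)\n" + "\n".join(map(str, cols)) + "\n"
        )
        mask_paths[p.name] = mp

    truth_json = out_dir / "truth.json"
    truth.to_json(truth_json)
    truth_newick = out_dir / "truth.nwk"
    truth_newick.write_text(write_newick(full_tree))
    return SyntheticDataset(
        out_dir=out_dir,
        fasta_paths=fasta_paths,
        mask_paths=mask_paths,
        truth_json=truth_json,
        truth_newick=truth_newick,
        truth=truth,
    )


def analysis_config_dict(
    ds: SyntheticDataset,
    clock_seed: int = 11,
    null_seed: int = 13,
    n_boot: int = 200,
    n_sims: int = 199,
    out_dir=None,
    use_masks: bool = True,
    distance_family: str = "TN93",
) -> dict:
    """A ready-to-run analysis config for a generated dataset.

    The calibration rate is the truth's site-weighted mean substitution rate
    (the combined distance is a support-weighted mean across genes, so this
    is the rate the concatenated distances accrue at under a strict clock).
    """
    total = sum(p["n_sites"] for p in ds.truth.partitions)
    rate = sum(p["rate"] * p["n_sites"] for p in ds.truth.partitions) / total
    genes = []
    for p in ds.truth.partitions:
        g = {
            "name": p["name"],
            "fasta": str(Path(ds.fasta_paths[p["name"]]).resolve()),
            "model": {"family": distance_family},
        }
        if use_masks:
            g["mask"] = str(Path(ds.mask_paths[p["name"]]).resolve())
        genes.append(g)
    return {
        "genes": genes,
        "outgroup": ds.truth.outgroup or [OUTGROUP_LABEL],
        "out_dir": str(
            Path(out_dir if out_dir is not None else ds.out_dir / "analysis").resolve()
        ),
        "clock": {"alpha": 0.05, "n_boot": n_boot, "seed": clock_seed},
        "calibration": {"rate": rate, "divisor": 2},
        "kde": {"bandwidth": "nrd0", "grid_n": 512, "cut": 3},
        "null": {"n_sims": n_sims, "seed": null_seed, "statistic": "l1"},
    }
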