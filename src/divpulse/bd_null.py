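"""Constant-rate birth-death null model for the pairwise-distance test.

The null hypothesis is that the observed clade diversified under a simple
birth-death process with constant per-lineage speciation (b) and extinction
(d) rates.  Rates are estimated from the branching times of the reconstructed
(ultrametric) tree by maximising the Nee-style reconstructed-process
likelihood; the null pairwise-age density p_H0 is the mean KDE over trees
simulated forward under the fitted rates; and the observed density is tested
against p_H0 with a Monte-Carlo discrepancy statistic (L1 distance by
default, two-sample Kolmogorov-Smirnov as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize

from .errors import FeasibilityError, FitError, GridMismatchError
from .pulse_detect import DensityCurve, nrd0_bandwidth
from .treebuild import BranchingTimes, pairwise_mrca_ages


@dataclass(frozen=True)
class BDParams:
    """Birth-death rates (events/lineage/Ma)."""

    b: float
    d: float = 0.0

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("birth rate must be > 0")
        if not 0 <= self.d < self.b:
            raise ValueError("death rate must satisfy 0 <= d < b")

    @property
    def r_net(self) -> float:
        return self.b - self.d

    @property
    def eps(self) -> float:
        return self.d / self.b


def _loglik_r_eps(ages: np.ndarray, r: float, eps: float) -> float:
    """Reconstructed-process log-likelihood of crown branching times.

    ln L = (n-2) ln r + r * sum_{i>=3} x_i + n ln(1-eps)
           - 2 * sum_{i>=2} ln(e^{r x_i} - eps),
    up to an additive constant; ages are x_2 >= ... >= x_n.
    """
    if not r > 0:
        raise ValueError("net diversification rate must be > 0")
    if not 0 <= eps < 1:
        raise ValueError("relative extinction eps must be in [0, 1)")
    n = ages.size + 1
    # stable: ln(e^{rx} - eps) = r x + ln(1 - eps e^{-r x})
    log_terms = r * ages + np.log1p(-eps * np.exp(-r * ages))
    return float(
        (n - 2) * np.log(r)
        + r * ages[1:].sum()
        + n * np.log1p(-eps)
        - 2.0 * log_terms.sum()
    )


def bd_loglik(bt: BranchingTimes, params: BDParams) -> float:
    """Log-likelihood of the branching times under constant birth-death rates,
    conditioned on the crown (additive constant omitted)."""
    if bt.n_tips < 3:
        raise ValueError("need >= 3 tips")
    return _loglik_r_eps(bt.ages, params.r_net, params.eps)


def fit_bd(bt: BranchingTimes) -> BDParams:
    """Maximum-likelihood (b, d) from branching times.

    Optimises over (ln r, logit eps) by quasi-Newton from several starting
    points; a boundary solution eps -> 0 is returned as d = 0.
    """
    if bt.n_tips < 4:
        raise ValueError("need >= 4 tips to fit a birth-death model")
    ages = bt.ages
    # Yule closed form as the anchor start
    r_yule = (bt.n_tips - 2) / (2.0 * ages[0] + ages[1:].sum())

    def neg_ll(u):
        r = np.exp(np.clip(u[0], -50.0, 50.0))
        eps = 1.0 / (1.0 + np.exp(-np.clip(u[1], -30.0, 30.0)))
        eps = min(eps, 1.0 - 1e-12)
        try:
            return -_loglik_r_eps(ages, r, eps)
        except (ValueError, FloatingPointError):
            return 1e300

    starts = [
        (np.log(r_yule), -8.0),
        (np.log(r_yule), 0.0),
        (np.log(r_yule * 0.5), 1.0),
        (np.log(r_yule * 2.0), -2.0),
        (np.log(r_yule), 2.0),
    ]
    best = None
    for s in starts:
        res = minimize(neg_ll, np.asarray(s), method="L-BFGS-B")
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("birth-death fit failed to converge from all restarts")
    r = float(np.exp(best.x[0]))
    eps = float(1.0 / (1.0 + np.exp(-best.x[1])))
    if eps < 1e-6:
        return BDParams(b=r, d=0.0)
    b = r / (1.0 - eps)
    return BDParams(b=b, d=b * eps)


# ---------------------------------------------------------------------------
# Forward (Gillespie) simulation of the birth-death process
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("idx", "t_birth", "t_end", "children")

    def __init__(self, idx: int, t_birth: float):
        self.idx = idx
        self.t_birth = t_birth
        self.t_end: float | None = None
        self.children: list["_Lineage"] = []


def _gillespie(
    rng: np.random.Generator,
    birth_rate,
    death_rate: float,
    stop_n: int | None = None,
    duration: float | None = None,
    rate_breaks: tuple[float, ...] = (),
):
    """One forward run from 2 crown lineages.

    ``birth_rate`` is either a constant or a callable b(t) of elapsed time,
    piecewise constant between ``rate_breaks``.  Returns (crown lineages,
    stop time) or None on total extinction.
    """
    b_of = birth_rate if callable(birth_rate) else (lambda t: birth_rate)
    crown = [_Lineage(0, 0.0), _Lineage(1, 0.0)]
    active = list(crown)
    next_idx = 2
    t = 0.0
    breaks = sorted(bp for bp in rate_breaks if bp > 0)
    while True:
        if stop_n is not None and len(active) >= stop_n:
            break
        if not active:
            return None
        if len(active) > 100_000:
            raise FeasibilityError("runaway simulation: >1e5 extant lineages")
        b = b_of(t)
        total = len(active) * (b + death_rate)
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        nxt_break = next((bp for bp in breaks if bp > t), None)
        t_event = t + wait
        if duration is not None and t_event >= duration:
            if nxt_break is not None and nxt_break < duration:
                t = nxt_break
                continue
            t = duration
            break
        if nxt_break is not None and t_event >= nxt_break:
            t = nxt_break  # rate changes before the event; redraw
            continue
        t = t_event
        lin = active[rng.integers(len(active))]
        if rng.random() < b / (b + death_rate):
            lin.t_end = t
            c1, c2 = _Lineage(next_idx, t), _Lineage(next_idx + 1, t)
            next_idx += 2
            lin.children = [c1, c2]
            active.remove(lin)
            active.extend([c1, c2])
        else:
            lin.t_end = t
            active.remove(lin)
    for lin in active:
        lin.t_end = t
    return crown, t


def _reconstructed_tree(crown, t_stop: float) -> dendropy.Tree | None:
    """Prune extinct lineages, suppress unifurcations, build a dendropy tree."""
    tns = dendropy.TaxonNamespace()

    def build(lin: _Lineage):
        span = (lin.t_end if lin.t_end is not None else t_stop) - lin.t_birth
        if not lin.children:
            if lin.t_end is not None and lin.t_end < t_stop:
                return None  # extinct
            nd = dendropy.Node(taxon=tns.require_taxon(label=f"T{lin.idx}"))
            nd.edge.length = span
            return nd
        kids = [k for k in (build(c) for c in lin.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].edge.length += span
            return kids[0]
        nd = dendropy.Node()
        nd.edge.length = span
        for k in kids:
            nd.add_child(k)
        return nd

    sides = [s for s in (build(c) for c in crown) if s is not None]
    if not sides:
        return None
    if len(sides) == 1:
        root = sides[0]
        root.edge.length = None
    else:
        root = dendropy.Node()
        for s in sides:
            root.add_child(s)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def conditioned_branching_ages(
    params: BDParams, n_tips: int, crown_age: float, rng: np.random.Generator
) -> np.ndarray:
    """Branching ages of the reconstructed constant-rate process conditioned
    on ``n_tips`` extant tips and the crown age.

    Besides the crown itself, the n - 2 branching ages are i.i.d. with CDF
    F(s) = q(s) / q(t), q(s) = (1 - e^{-r s}) / (b - d e^{-r s}), inverted in
    closed form (the "conditioned reconstructed process" construction).
    """
    b, d, r = params.b, params.d, params.r_net
    t = crown_age
    u = rng.random(n_tips - 2)
    qt = (1.0 - np.exp(-r * t)) / (b - d * np.exp(-r * t))
    A = u * qt
    s = -np.log((1.0 - A * b) / (1.0 - A * d)) / r
    return np.concatenate(([t], np.sort(s)[::-1]))


def simulate_bd_tree_conditioned(
    params: BDParams, n_tips: int, crown_age: float, seed=None
) -> dendropy.Tree:
    """Ultrametric reconstructed-process tree conditioned on tip count and
    crown age: conditioned branching ages plus a uniform-random-join
    (Yule-type) ranked topology."""
    if n_tips < 3:
        raise ValueError("need >= 3 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ages = conditioned_branching_ages(params, n_tips, crown_age, rng)
    tns = dendropy.TaxonNamespace()
    lineages = []
    for i in range(n_tips):
        nd = dendropy.Node(taxon=tns.require_taxon(label=f"T{i}"))
        lineages.append((nd, 0.0))  # (node, age at its top)
    for age in ages[::-1]:  # youngest first
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (n1, a1), (n2, a2) = lineages[i], lineages[j]
        parent = dendropy.Node()
        n1.edge.length = age - a1
        n2.edge.length = age - a2
        parent.add_child(n1)
        parent.add_child(n2)
        lineages[i] = (parent, age)
        del lineages[j]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = lineages[0][0]
    tree.is_rooted = True
    return tree


MAX_REJECTED_RUNS = 100_000


def simulate_bd_tree(
    params: BDParams, n_tips: int, seed=None
) -> dendropy.Tree:
    """Forward Gillespie from 2 crown lineages until the extant count reaches
    ``n_tips``, with the present sampled inside the ``n_tips``-lineage window;
    extinct lineages pruned; reruns on total extinction.

    Stopping exactly at the n-th birth would pin the youngest branching age
    at zero, which mimics extinction's pull-of-the-present and badly inflates
    fitted extinction (hence birth) rates downstream.  Instead the present is
    placed uniformly within a length-biased draw of the window during which
    ``n_tips`` lineages exist (the general-sampling-approach rule, exact for
    pure birth; first-window approximation when extinction can drop the count
    back below n).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(MAX_REJECTED_RUNS):
        out = _gillespie(rng, params.b, params.d, stop_n=n_tips)
        if out is None:
            continue
        crown, t_reach = out
        # length-biased window (Gamma(2)) x uniform position within it
        window = rng.gamma(2.0, 1.0 / (n_tips * (params.b + params.d)))
        t_stop = t_reach + window * rng.random()
        for lin in _iter_lineages(crown):
            if not lin.children and lin.t_end == t_reach:
                lin.t_end = t_stop
        tree = _reconstructed_tree(crown, t_stop)
        if tree is not None and sum(1 for _ in tree.leaf_node_iter()) == n_tips:
            return tree
    raise FeasibilityError(
        f"no surviving simulation in {MAX_REJECTED_RUNS} runs (b={params.b}, d={params.d})"
    )


def _iter_lineages(crown):
    stack = list(crown)
    while stack:
        lin = stack.pop()
        yield lin
        stack.extend(lin.children)


def extant_count_at(params: BDParams, duration: float, seed=None) -> int:
    """Free-run variant: number of extant lineages after ``duration`` (0 on
    total extinction).  Mean over seeds approaches 2*exp((b-d)*duration)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = _gillespie(rng, params.b, params.d, duration=duration)
    if out is None:
        return 0
    crown, t_stop = out

    def count(lin):
        if not lin.children:
            return int(lin.t_end >= t_stop)
        return sum(count(c) for c in lin.children)

    return sum(count(c) for c in crown)


# ---------------------------------------------------------------------------
# Null ensemble and the Monte-Carlo discrepancy test
# ---------------------------------------------------------------------------


def kde_on_grid(values: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    """Gaussian KDE evaluated on a fixed grid, renormalised over the grid."""
    z = (grid[:, None] - values[None, :]) / h
    f = np.exp(-0.5 * z * z).sum(axis=1) / (values.size * h * np.sqrt(2.0 * np.pi))
    mass = np.trapezoid(f, grid)
    return f / mass if mass > 0 else f


@dataclass
class NullEnsemble:
    """Simulated null pairwise-age densities on the observed curve's grid."""

    grid: np.ndarray
    curves: np.ndarray  # (n_sims, grid_n)
    samples: list  # per-sim pairwise-age samples (for the KS statistic)
    n_sims: int
    seed: int | None
    newicks: list[str] | None = None  # kept only on request (--keep-sims)

    @property
    def mean(self) -> np.ndarray:
        """p_H0: the mean null density."""
        return self.curves.mean(axis=0)


def null_density_ensemble(
    params: BDParams,
    n_tips: int,
    n_sims: int,
    grid: np.ndarray,
    seed=None,
    bandwidth: float | None = None,
    keep_trees: bool = False,
    crown_age: float | None = None,
) -> NullEnsemble:
    """Simulate ``n_sims`` constant-rate trees and estimate p_H0.

    Per tree, all pairwise tip MRCA ages (patristic time / 2) are collected
    and smoothed on the observed curve's grid, with the observed curve's
    ``bandwidth`` (falling back to the per-sample rule-of-thumb when none is
    given).  When ``crown_age`` is given the trees are drawn from the
    reconstructed process conditioned on tip count and crown age, so every
    null curve shares the observed support (without it, free-running
    stop-at-n trees have widely varying crown ages, which inflates the
    curve-to-curve spread and starves the discrepancy test of power).
    """
    if n_sims < 99:
        raise ValueError("need >= 99 simulations for a stable Monte-Carlo p-value")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    curves = np.empty((n_sims, grid.size))
    samples = []
    newicks: list[str] | None = [] if keep_trees else None
    for i in range(n_sims):
        if crown_age is not None:
            tree = simulate_bd_tree_conditioned(params, n_tips, crown_age, seed=rng)
        else:
            tree = simulate_bd_tree(params, n_tips, seed=rng)
        if newicks is not None:
            from .treebuild import write_newick

            newicks.append(write_newick(tree).strip())
        ages = pairwise_mrca_ages(tree)
        h = bandwidth if bandwidth is not None else nrd0_bandwidth(ages)
        if not h > 0:
            raise FeasibilityError(
                "degenerate null sample bandwidth; pass an explicit bandwidth"
            )
        curves[i] = kde_on_grid(ages, grid, h)
        samples.append(ages)
    return NullEnsemble(
        grid=grid,
        curves=curves,
        samples=samples,
        n_sims=n_sims,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
        newicks=newicks,
    )


@dataclass
class NullTestResult:
    t_obs: float
    t_sim: np.ndarray
    p_value: float
    n_sims: int
    alpha: float
    reject: bool
    statistic: str

    def to_json_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "T_obs": self.t_obs,
            "p_value": self.p_value,
            "n_sims": self.n_sims,
            "alpha": self.alpha,
            "reject_H0": self.reject,
        }


def h0_test(
    f_obs: DensityCurve,
    ens: NullEnsemble,
    alpha: float = 0.05,
    statistic: str = "l1",
    obs_sample: np.ndarray | None = None,
) -> NullTestResult:
    """Monte-Carlo test of the observed density against the birth-death null.

    ``l1``: T(curve) = sum |curve - p_H0| * delta, with each simulated curve
    compared against the leave-one-in ensemble mean.  ``ks``: two-sample
    Kolmogorov-Smirnov distance between raw samples and the pooled null
    sample (requires ``obs_sample``).  p = (1 + #{T_sim >= T_obs}) /
    (n_sims + 1).
    """
    if f_obs.x.size != ens.grid.size or not np.allclose(f_obs.x, ens.grid):
        raise GridMismatchError("observed curve and null ensemble grids differ")
    if statistic == "l1":
        delta = f_obs.delta
        mean = ens.mean
        t_obs = float(np.abs(f_obs.f - mean).sum() * delta)
        t_sim = np.abs(ens.curves - mean[None, :]).sum(axis=1) * delta
    elif statistic == "ks":
        if obs_sample is None:
            raise ValueError("the KS statistic needs the raw observed sample")
        from scipy.stats import ks_2samp

        pooled = np.concatenate(ens.samples)
        t_obs = float(ks_2samp(obs_sample, pooled).statistic)
        t_sim = np.array(
            [ks_2samp(s, pooled).statistic for s in ens.samples]
        )
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    p = (1.0 + int((t_sim >= t_obs).sum())) / (ens.n_sims + 1.0)
    return NullTestResult(
        t_obs=t_obs,
        t_sim=t_sim,
        p_value=float(p),
        n_sims=ens.n_sims,
        alpha=alpha,
        reject=p < alpha,
        statistic=statistic,
    )
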