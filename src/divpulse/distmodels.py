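"""Model-corrected pairwise genetic distances.

Distances are expected substitutions per site between two aligned sequences,
inverted from observed site-pattern proportions under a nucleotide
substitution model.  Closed forms are used for JC69, K2P and TN93 (with the
standard gamma-corrected analogues); GTR and any model with a proportion of
invariant sites is handled by numerically maximising the two-sequence
likelihood over the branch length.

Sites where either residue is a gap or an ambiguity code are dropped pair by
pair (pairwise deletion); the number of jointly unambiguous sites is reported
as the pair's *support*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .errors import DistanceError
from .seqdata import AlignedSeqSet, PartitionScheme, encode

CLOSED_FORM_FAMILIES = ("P", "JC69", "K2P", "TN93")
FAMILIES = CLOSED_FORM_FAMILIES + ("GTR",)

#: exchangeability parameter order for GTR models
EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass(frozen=True)
class ModelSpec:
    """A nucleotide substitution model.

    ``base_freqs`` are in A, C, G, T order; ``exchangeabilities`` follow
    :data:`EXCH_ORDER`.  ``gamma_shape`` adds discrete-gamma rate variation
    across sites (+G); ``prop_invariant`` adds a class of invariant sites (+I,
    GTR-parameterised models only).
    """

    family: str
    gamma_shape: float | None = None
    prop_invariant: float | None = None
    base_freqs: tuple[float, float, float, float] | None = None
    exchangeabilities: tuple[float, float, float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.gamma_shape is not None and not self.gamma_shape > 0:
            raise ValueError("gamma_shape must be > 0")
        if self.prop_invariant is not None and not 0 <= self.prop_invariant < 1:
            raise ValueError("prop_invariant must be in [0, 1)")
        if self.base_freqs is not None:
            f = np.asarray(self.base_freqs, dtype=float)
            if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("base_freqs must be 4 non-negative reals summing to 1")
        if self.exchangeabilities is not None:
            s = np.asarray(self.exchangeabilities, dtype=float)
            if s.shape != (6,) or (s < 0).any():
                raise ValueError("exchangeabilities must be 6 non-negative reals")
        if self.family == "GTR" and (
            self.base_freqs is None or self.exchangeabilities is None
        ):
            raise ValueError("GTR requires base_freqs and exchangeabilities")
        if self.prop_invariant and self.family != "GTR":
            raise ValueError(
                "prop_invariant requires the numerical GTR route; "
                "re-express the model with family='GTR'"
            )

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def p_distance(cls) -> "ModelSpec":
        return cls("P")

    @classmethod
    def jc69(cls, gamma_shape: float | None = None) -> "ModelSpec":
        return cls("JC69", gamma_shape=gamma_shape)

    @classmethod
    def k2p(cls, gamma_shape: float | None = None) -> "ModelSpec":
        return cls("K2P", gamma_shape=gamma_shape)

    @classmethod
    def tn93(cls, gamma_shape: float | None = None) -> "ModelSpec":
        return cls("TN93", gamma_shape=gamma_shape)

    @classmethod
    def gtr(
        cls,
        base_freqs,
        exchangeabilities,
        gamma_shape: float | None = None,
        prop_invariant: float | None = None,
    ) -> "ModelSpec":
        return cls(
            "GTR",
            gamma_shape=gamma_shape,
            prop_invariant=prop_invariant,
            base_freqs=tuple(base_freqs),
            exchangeabilities=tuple(exchangeabilities),
        )

    @classmethod
    def hky(cls, kappa: float, base_freqs=(0.25, 0.25, 0.25, 0.25), **kw) -> "ModelSpec":
        """HKY85 expressed as a GTR special case (kappa = ts/tv rate ratio)."""
        return cls.gtr(base_freqs, (1.0, kappa, 1.0, 1.0, kappa, 1.0), **kw)


# ---------------------------------------------------------------------------
# Rate matrices and transition probabilities (shared with the simulator)
# ---------------------------------------------------------------------------


def rate_matrix(model: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """(Q, pi) for a GTR-parameterised model, scaled to one expected
    substitution per site per unit time at stationarity."""
    if model.base_freqs is None or model.exchangeabilities is None:
        if model.family == "JC69":
            pi = np.full(4, 0.25)
            s = np.ones(6)
        else:
            raise ValueError(
                f"model {model.family} lacks the rate-matrix parameters needed here"
            )
    else:
        pi = np.asarray(model.base_freqs, dtype=float)
        s = np.asarray(model.exchangeabilities, dtype=float)
    S = np.zeros((4, 4))
    iu = np.triu_indices(4, k=1)
    S[iu] = s
    S = S + S.T
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu, pi


def discrete_gamma_rates(shape: float, n_cat: int = 4) -> np.ndarray:
    """Mean rates of ``n_cat`` equal-probability discrete gamma categories
    (mean-one gamma with the given shape)."""
    q = gamma_dist.ppf(np.arange(1, n_cat) / n_cat, shape, scale=1.0 / shape)
    bounds = np.concatenate(([0.0], q * shape, [np.inf]))
    cum = gammainc(shape + 1.0, bounds)
    return n_cat * np.diff(cum)


def site_rate_mixture(model: ModelSpec, n_cat: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """(rates, weights) of the across-site rate mixture implied by +G/+I,
    normalised to mean rate one."""
    if model.gamma_shape is not None:
        rates = discrete_gamma_rates(model.gamma_shape, n_cat)
        weights = np.full(n_cat, 1.0 / n_cat)
    else:
        rates = np.array([1.0])
        weights = np.array([1.0])
    pinv = model.prop_invariant or 0.0
    if pinv > 0:
        rates = np.concatenate(([0.0], rates / (1.0 - pinv)))
        weights = np.concatenate(([pinv], weights * (1.0 - pinv)))
    return rates, weights


def transition_probs(Q: np.ndarray, t: float, pi: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) via symmetric eigendecomposition (exact for GTR)."""
    if t <= 0:
        return np.eye(4)
    d_half = np.sqrt(pi)
    B = (Q * d_half[:, None]) / d_half[None, :]
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    P = (V * np.exp(w * t)) @ V.T
    P = P / d_half[:, None] * d_half[None, :]
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Pairwise site-pattern tallies
# ---------------------------------------------------------------------------


class PairTally:
    """Per-pair site-pattern tallies over all unordered taxon pairs.

    Built once per alignment; :meth:`tallies` then recomputes the counts for
    arbitrary non-negative column weights, which is what makes the column
    bootstrap of the clock test cheap.
    """

    def __init__(self, aln: AlignedSeqSet):
        codes = aln.codes
        self.taxon_ids = list(aln.taxon_ids)
        n = codes.shape[0]
        self.i_idx, self.j_idx = np.triu_indices(n, k=1)
        A = codes[self.i_idx]
        B = codes[self.j_idx]
        self.valid = (A < 4) & (B < 4)
        diff = self.valid & (A != B)
        self.ts_ag = diff & (((A == 0) & (B == 2)) | ((A == 2) & (B == 0)))
        self.ts_ct = diff & (((A == 1) & (B == 3)) | ((A == 3) & (B == 1)))
        self.tv = diff & ~self.ts_ag & ~self.ts_ct
        # per-pair, per-base residue counts restricted to valid columns
        # (float32 so the weighted recount is a single matmul)
        S = np.empty((A.shape[0], 4, A.shape[1]), dtype=np.float32)
        for b in range(4):
            S[:, b, :] = ((A == b) & self.valid).astype(np.float32) + (
                (B == b) & self.valid
            )
        self._base_ind = S
        self.n_taxa = n
        self.n_sites = codes.shape[1]

    def tallies(self, weights: np.ndarray | None = None) -> dict[str, np.ndarray]:
        if weights is None:
            w = np.ones(self.n_sites)
        else:
            w = np.asarray(weights, dtype=float)
        n = self.valid @ w
        P = self._base_ind.shape[0]
        base_counts = (
            self._base_ind.reshape(P * 4, -1) @ w.astype(np.float32)
        ).reshape(P, 4)
        return {
            "n": n,
            "n_ts_ag": self.ts_ag @ w,
            "n_ts_ct": self.ts_ct @ w,
            "n_tv": self.tv @ w,
            "base_counts": base_counts.astype(float),
        }


def _gamma_log(w: np.ndarray, shape: float | None) -> np.ndarray:
    """-ln(w), or its discrete-free gamma analogue a*(w^(-1/a) - 1)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        if shape is None:
            return -np.log(w)
        return shape * (np.power(w, -1.0 / shape) - 1.0)


def distances_from_tallies(t: dict[str, np.ndarray], model: ModelSpec):
    """Vectorised closed-form distances from pair tallies.

    Returns ``(d, support)``; saturated pairs (correction argument <= 0) get
    ``d = nan``.
    """
    n = t["n"]
    support = n
    with np.errstate(invalid="ignore", divide="ignore"):
        P1 = np.where(n > 0, t["n_ts_ag"] / n, np.nan)
        P2 = np.where(n > 0, t["n_ts_ct"] / n, np.nan)
        Q = np.where(n > 0, t["n_tv"] / n, np.nan)
    p = P1 + P2 + Q
    a = model.gamma_shape
    if model.family == "P":
        d = p
    elif model.family == "JC69":
        w = 1.0 - 4.0 * p / 3.0
        d = np.where(w > 0, 0.75 * _gamma_log(np.maximum(w, 1e-300), a), np.nan)
    elif model.family == "K2P":
        P = P1 + P2
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        ok = (w1 > 0) & (w2 > 0)
        d = np.where(
            ok,
            0.5 * _gamma_log(np.maximum(w1, 1e-300), a)
            + 0.25 * _gamma_log(np.maximum(w2, 1e-300), a),
            np.nan,
        )
    elif model.family == "TN93":
        bc = t["base_counts"]
        with np.errstate(invalid="ignore", divide="ignore"):
            g = bc / bc.sum(axis=1, keepdims=True)
        gA, gC, gG, gT = g[..., 0], g[..., 1], g[..., 2], g[..., 3]
        gR = gA + gG
        gY = gC + gT
        k1 = np.where(gR > 0, 2.0 * gA * gG / np.maximum(gR, 1e-300), 0.0)
        k2 = np.where(gY > 0, 2.0 * gT * gC / np.maximum(gY, 1e-300), 0.0)
        k3 = 2.0 * (
            gR * gY
            - np.where(gR > 0, gA * gG * gY / np.maximum(gR, 1e-300), 0.0)
            - np.where(gY > 0, gT * gC * gR / np.maximum(gY, 1e-300), 0.0)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            w1 = np.where(k1 > 0, 1.0 - P1 / np.maximum(k1, 1e-300) - Q / (2.0 * gR), 1.0)
            w2 = np.where(k2 > 0, 1.0 - P2 / np.maximum(k2, 1e-300) - Q / (2.0 * gY), 1.0)
            w3 = np.where(
                gR * gY > 0, 1.0 - Q / np.maximum(2.0 * gR * gY, 1e-300), 1.0
            )
        ok = (w1 > 0) & (w2 > 0) & (w3 > 0)
        d = np.where(
            ok,
            k1 * _gamma_log(np.maximum(w1, 1e-300), a)
            + k2 * _gamma_log(np.maximum(w2, 1e-300), a)
            + k3 * _gamma_log(np.maximum(w3, 1e-300), a),
            np.nan,
        )
    else:
        raise ValueError(f"no closed form for family {model.family}")
    d = np.where(n > 0, d, np.nan)
    d = np.where(p == 0, 0.0, d)  # identical pairs are exactly 0
    return d, support


# ---------------------------------------------------------------------------
# Two-sequence maximum likelihood (GTR and +I variants)
# ---------------------------------------------------------------------------

MAX_BRANCH_LENGTH = 20.0  # subst/site; search bracket for the ML distance


def _pattern_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ok = (a < 4) & (b < 4)
    counts = np.zeros((4, 4))
    np.add.at(counts, (a[ok], b[ok]), 1.0)
    return counts


def gtr_ml_distance(a: np.ndarray, b: np.ndarray, model: ModelSpec) -> tuple[float, int]:
    """ML branch length between two sequences under a fixed GTR(+G+I) model."""
    counts = _pattern_counts(a, b)
    support = int(counts.sum())
    if support == 0:
        raise DistanceError("no jointly unambiguous sites between the two sequences")
    if counts.sum() == np.trace(counts):
        return 0.0, support
    Q, pi = rate_matrix(model)
    rates, weights = site_rate_mixture(model)

    def neg_ll(t: float) -> float:
        mix = np.zeros((4, 4))
        for r, w in zip(rates, weights):
            mix += w * (transition_probs(Q, t * r, pi) if r > 0 else np.eye(4))
        joint = pi[:, None] * mix
        with np.errstate(divide="ignore"):
            lj = np.log(np.maximum(joint, 1e-300))
        return -float((counts * lj).sum())

    res = minimize_scalar(
        neg_ll,
        bounds=(1e-9, MAX_BRANCH_LENGTH),
        method="bounded",
        options={"xatol": 1e-10},
    )
    # refuse to report a distance pinned at the saturation bracket
    if res.x > MAX_BRANCH_LENGTH * 0.999:
        return float("nan"), support
    return float(res.x), support


# ---------------------------------------------------------------------------
# Public pairwise API
# ---------------------------------------------------------------------------


def pairwise_distance(a, b, model: ModelSpec) -> tuple[float, int]:
    """Model-corrected distance (substitutions/site) and support between two
    aligned sequences (strings or code arrays).

    Saturated corrections return ``nan``; a pair with zero overlap raises
    :class:`DistanceError`.
    """
    a = encode(a) if isinstance(a, str) else np.asarray(a, dtype=np.uint8)
    b = encode(b) if isinstance(b, str) else np.asarray(b, dtype=np.uint8)
    if a.shape != b.shape:
        raise DistanceError("sequences differ in aligned length")
    if model.family == "GTR" or model.prop_invariant:
        return gtr_ml_distance(a, b, model)
    aln = AlignedSeqSet(["a", "b"], np.vstack([a, b]), np.full(a.size, "all", dtype=object))
    t = PairTally(aln).tallies()
    if t["n"][0] == 0:
        raise DistanceError("no jointly unambiguous sites between the two sequences")
    d, support = distances_from_tallies(t, model)
    return float(d[0]), int(support[0])


@dataclass
class DistanceMatrix:
    """Symmetric matrix of corrected distances with per-pair support.

    Undefined (saturated) entries are ``nan`` and never silently zeroed.
    """

    taxon_ids: list[str]
    d: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxon_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        np.fill_diagonal(self.d, 0.0)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(np.isnan(np.triu(self.d, k=1)))
        return [
            (self.taxon_ids[a], self.taxon_ids[b])
            for a, b in zip(i, j)
            if a < b and np.isnan(self.d[a, b])
        ]

    def submatrix(self, taxa) -> "DistanceMatrix":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return DistanceMatrix(
            list(taxa), self.d[np.ix_(idx, idx)], self.support[np.ix_(idx, idx)]
        )

    def scaled(self, factor: float) -> "DistanceMatrix":
        return DistanceMatrix(list(self.taxon_ids), self.d * factor, self.support.copy())

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa}\n")
            for t, row in zip(self.taxon_ids, self.d):
                vals = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{t}  {vals}\n")

    def to_long_frame(self):
        import pandas as pd

        rows = []
        for i in range(self.n_taxa):
            for j in range(i + 1, self.n_taxa):
                rows.append(
                    (
                        self.taxon_ids[i],
                        self.taxon_ids[j],
                        self.d[i, j],
                        int(self.support[i, j]),
                        "saturated" if np.isnan(self.d[i, j]) else "",
                    )
                )
        return pd.DataFrame(
            rows, columns=["taxon_i", "taxon_j", "distance", "support", "flags"]
        )


def distance_matrix(
    aln: AlignedSeqSet,
    scheme: PartitionScheme | None = None,
    combine: str = "weighted",
    concat_model: ModelSpec | None = None,
) -> DistanceMatrix:
    """Pairwise distances per partition, combined per pair.

    ``combine='weighted'`` (default): support-weighted average of the
    per-partition distances, skipping saturated partitions for that pair
    (with a warning).  ``combine='concat'``: a single model (``concat_model``)
    applied to the whole alignment.
    """
    n = aln.n_taxa
    if scheme is None:
        scheme = PartitionScheme.single(aln)
    if combine == "concat":
        model = concat_model or scheme.partitions[0].model
        if model is None:
            raise ValueError("combine='concat' needs a model")
        return _single_partition_matrix(aln, np.arange(aln.n_sites), model)

    num = np.zeros((n, n))
    den = np.zeros((n, n))
    support_total = np.zeros((n, n))
    any_saturated = False
    for part in scheme.partitions:
        if part.model is None:
            raise ValueError(f"partition {part.name!r} has no model")
        dm = _single_partition_matrix(aln, part.columns, part.model)
        defined = ~np.isnan(dm.d)
        if not defined.all():
            any_saturated = True
        num += np.where(defined, dm.d * dm.support, 0.0)
        den += np.where(defined, dm.support, 0.0)
        support_total += dm.support
    if any_saturated:
        warnings.warn(
            "saturated partitions excluded from the support-weighted average "
            "for some pairs",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return DistanceMatrix(list(aln.taxon_ids), d, support_total)


def _single_partition_matrix(
    aln: AlignedSeqSet, columns: np.ndarray, model: ModelSpec
) -> DistanceMatrix:
    from scipy.spatial.distance import squareform

    sub = AlignedSeqSet(
        list(aln.taxon_ids), aln.codes[:, columns], aln.partition_of[columns]
    )
    n = sub.n_taxa
    if model.family == "GTR" or model.prop_invariant:
        d = np.zeros((n, n))
        support = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dij, sij = gtr_ml_distance(sub.codes[i], sub.codes[j], model)
                d[i, j] = d[j, i] = dij
                support[i, j] = support[j, i] = sij
        return DistanceMatrix(list(sub.taxon_ids), d, support)
    tal = PairTally(sub).tallies()
    dvec, svec = distances_from_tallies(tal, model)
    d = squareform(dvec)
    # squareform maps nan through fine but zeroes the diagonal, which is what we want
    support = squareform(svec)
    return DistanceMatrix(list(sub.taxon_ids), d, support)
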