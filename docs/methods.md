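# Methods

This note documents the statistical model behind `divpulse`, the numerical
choices made where several were defensible, what the synthetic-data
generator does and does not emulate, and the known limitations of the
method. Scientific claims below are either mathematical properties of the
procedures or are measured by the test suite / acceptance script.

## Pairwise distances

Distances are expected substitutions per site, inverted from observed
site-pattern proportions under a substitution model. Sites where either
residue is a gap or IUPAC ambiguity code are dropped pair by pair (pairwise
deletion); the per-pair count of jointly unambiguous sites is the pair's
*support* and is carried through every downstream computation.

* Closed forms: JC69 `−(3/4)·ln(1 − 4p/3)`; K2P
  `−½ln(1−2P−Q) − ¼ln(1−2Q)` with transition/transversion proportions
  `P`, `Q`; TN93 with the standard three-class formula using base
  frequencies observed in the pair. With a gamma shape `a`, every `−ln w`
  is replaced by its rate-mixture analogue `a·(w^(−1/a) − 1)`.
* GTR, and any model with a proportion of invariant sites, is handled by
  numerically maximising the two-sequence likelihood over the branch length
  (bounded search on [0, 20] subst/site, `xatol = 1e-10`, transition
  probabilities by symmetric eigendecomposition of the normalised GTR rate
  matrix, 4 discrete gamma categories). Closed-form families do not accept
  `+I` directly — re-express the model as GTR; this keeps the invariant-site
  likelihood exact rather than bolting an ad-hoc correction onto a formula
  that has none.
* Saturation (a logarithm argument ≤ 0, or an ML distance pinned at the
  search bound) yields an *undefined* entry (`NaN`), never a silent zero.
* Multi-partition alignments combine per-partition distances by
  support-weighted averaging; saturated partitions are excluded from a
  pair's average with a warning. A concatenated single-model alternative is
  available (`combine="concat"`). The weighted mean is used because a
  clock-proportional distance per gene stays clock-proportional after
  support weighting, and it degrades gracefully when one gene saturates.

## Clock screen (root-to-tip branch-length test)

The screen builds an NJ tree from the combined distances, roots it on the
outgroup (midpoint of the separating branch), and forms
`dev_i = D_i − D̄₋ᵢ` for each ingroup tip. The standard error of `dev_i`
is estimated by a nonparametric bootstrap over alignment columns — each
replicate redraws column weights, recomputes distances (via cached per-pair
site-pattern tallies, so a replicate is a handful of matrix products),
rebuilds and re-roots the tree — and `p_i` is two-sided normal. Default
`n_boot = 1000`, `α = 0.05`, single-pass flagging (no sequential
re-testing), mirroring a one-shot removal of rate-deviant sequences.

The bootstrap was chosen over an analytic variance because the latter is
model-specific; the cost is a mild, structural conservatism: the deviation
and its bootstrap SE are positively correlated across datasets (replicates
that happen to land in noisier topological neighbourhoods inflate both), so
the studentised `z` has slightly light tails. The acceptance suite measures
per-taxon calibration on a fixed tree and the detection of a planted
3×-rate tip; detectability of a rate-deviant tip scales with the length of
its terminal branch (a deviation spanning ~1 Ma of history is invisible to
any sequence-based test at these rates), so the planted-deviant check uses
the tip with the longest terminal branch.

## Density estimation and mode detection

The pairwise sample is smoothed with a Gaussian KDE using the rule-of-thumb
bandwidth `0.9·min(σ̂, IQR/1.34)·n^(−1/5)` on a 512-point grid spanning
[min − 3h, max + 3h]. Distances and ages cannot be negative, so the grid is
truncated at zero and the curve renormalised to unit mass over the grid. A
degenerate automatic bandwidth (all observations equal) is an error that
asks for an explicit `h`.

Modes are grid points whose finite differences rise on the left and fall on
the right; plateaus (exactly equal neighbouring values) collapse to their
midpoint. Grid endpoints count as modes when the curve falls away from
them — the finite-difference rule cannot evaluate endpoints, and discarding
them would hide a youngest-event peak piled up at zero. Event intervals are
delimited by the minima between consecutive modes and by the grid ends, so
the intervals tile the grid with shared boundaries.

Note the `n` entering the bandwidth is the number of *pairs*, which are
strongly dependent (all pairs through one ancestral node share its age);
the KDE is a descriptive smoother here, not an efficiency-optimal density
estimate.

## Time calibration

`t = x/(divisor·r)` with `divisor = 2` by default: a pairwise distance
accrues along two lineages, so pairwise time equals MRCA age. `divisor = 1`
is retained for the raw `d/r` convention. The rate `r` (subst/site/Ma) is a
mandatory explicit input — no default is provided — or is solved from a
named-split calibration so that the mean cross-split pairwise time equals a
given age. Node ages for the birth–death fit come from a UPGMA tree built
on the distance matrix divided by `r` (patristic time): UPGMA heights are
half the merge distance, hence directly MRCA ages, and the tree is
ultrametric by construction, which the reconstructed-process likelihood
requires. (NJ trees are not ultrametric, so they cannot supply branching
times directly.)

## Birth–death null model

Rates are estimated by maximising the reconstructed-process log-likelihood
of the branching times conditioned on the crown (see README for the
formula) over `(ln r, logit ε)` with L-BFGS-B from five starting points; a
boundary solution `ε → 0` is returned as `d = 0`. At `n ≈ 50` tips `ε` is
weakly identified and the joint MLE of `b = r/(1−ε)` carries a few-percent
median bias; the acceptance suite measures the recovery on 200 simulated
trees.

Two tree simulators are provided:

* `simulate_bd_tree` — forward Gillespie from two crown lineages. The naive
  rule "stop at the instant the n-th lineage appears" pins the youngest
  branching age at exactly zero; that mimics extinction's pull of the
  present and badly inflates fitted extinction (hence birth) rates. The
  present is therefore sampled uniformly within a length-biased draw of the
  window during which n lineages exist — the general-sampling-approach rule,
  exact for pure birth and a first-window approximation when extinction can
  drop the count back below n.
* `simulate_bd_tree_conditioned` — exact draws from the reconstructed
  process conditioned on the tip count *and the crown age*: the non-crown
  branching ages are i.i.d. with closed-form CDF
  `F(s) = q(s)/q(t)`, `q(s) = (1−e^{−rs})/(b − d·e^{−rs})`, inverted
  analytically, combined with a uniform-random-join ranked topology.

The null ensemble uses the conditioned sampler with the observed crown age.
This matters: with free-running simulations the crown age varies so much
between null trees that every simulated curve sits on its own support, the
curve-to-ensemble-mean distances `T_sim` are dominated by support mismatch,
and the discrepancy test loses essentially all power (while appearing very
conservative). Conditioning on the observed crown age puts all null curves
on the observed support, and the test is then calibrated (type-I ≈ α,
measured by the acceptance suite and script).

The discrepancy statistic is the L1 distance between density curves on the
shared grid, against the ensemble mean `p_H0`; each simulated curve is
scored against the mean that includes it, and the Monte-Carlo p-value uses
the add-one rule. A two-sample Kolmogorov–Smirnov alternative on the raw
pairwise samples is available via configuration. Simulated curves share the
observed curve's grid and bandwidth.

**Power is limited by design at study scale.** The pairwise-age density is
dominated by the few deepest nodes, whose pair multiplicities are O(n²);
the extra nodes contributed by a short diversification pulse carry
comparatively few pairs, and the fitted null absorbs part of the signal.
The acceptance suite includes a power check against ×8 birth-rate pulses at
the generator's default study shape and measures rejection rates far below
common power targets — an honest property of the method, and consistent
with reporting the mode table *regardless* of the global test's outcome
(the pipeline flags a non-rejection prominently rather than suppressing the
modes).

## Synthetic data generator

`synthgen` provides ground-truthed inputs for every stage:

* **Pulsed trees.** Birth–death with piecewise-constant birth rate
  `b·m(age)`. Episodes are specified in absolute age, so runs with episodes
  anchor the crown at a given age and run forward to the present; episode
  windows in the truth file are exact. Without episodes the simulator takes
  the same code path as `simulate_bd_tree` (identical output for the same
  seed). Crown-anchored runs are conditioned on the extant count landing
  within ±25% of the target `n_tips` (rejection sampling), so the generator
  realises its declared study shape instead of a heavy-tailed tip count.
* **Sequences.** Per branch, expected substitutions in partition p are
  `rate_p · duration · e^η` with `η ~ N(−σ²/2, σ²)` drawn once per branch
  (mean-one lognormal rate noise; `σ = 0` is a strict clock). Site
  evolution uses the partition model's transition-probability matrices,
  4 discrete gamma categories when a shape is set, optional codon-position
  rate multipliers, and a stationary-frequency root draw. Named tips can
  carry a terminal-branch rate multiplier (for planting clock violations).
  One seed feeds three named streams — tree, branch rates, sites — in that
  order.
* **Study-shaped dataset.** Two genes on ~40 ingroup taxa plus an outgroup
  grafted at 75 Ma: a 657-column codon-structured, faster gene (HKY-like,
  rate 5·10⁻³ subst/site/Ma, codon-position multipliers 1/0.5/1.5) and a
  1013-column slower gene (rate 3·10⁻³), with per-gene "noisy column" mask
  files (50 and 125 random 1-based columns) emulating an external
  heterogeneity screen; applying both masks leaves 1495 columns. Default
  history: crown 60 Ma, base birth rate 0.035/Ma, no extinction, two ×8
  pulses on [51, 49] and [21, 19] Ma.

What the generator does **not** emulate: indels and alignment error (masks
remove ordinary columns, not genuinely misaligned ones), selection and
codon models, rate autocorrelation along the tree, saturation-level
third-position rates, lineage sorting and gene-tree/species-tree conflict,
and contamination/pseudogenes. Passing tests therefore demonstrate the
pipeline's internal correctness and its behaviour under clock-like,
well-modelled data — not robustness to the full messiness of real
multi-gene datasets.

## Numerical and determinism choices

* NJ: Studier–Keppler Q-matrix; ties broken by the lowest index pair in
  current matrix order; negative limb estimates clamped to zero with the
  deficit moved to the sister limb (pair path length preserved).
* UPGMA: average linkage, merge ties broken the same way.
* Ultrametricity tolerance: 1e-6 (relative to crown depth) for node ages;
  KDE/grid arithmetic in double precision; MC p-values use the add-one rule
  so `p ∈ (0, 1]`.
* Every stochastic stage requires an explicit seed; a pipeline run is
  bit-for-bit reproducible on one platform, and the report records all
  seeds and a configuration hash.
* Degenerate inputs fail loudly: empty masks are identity, full-column
  masks, empty taxon intersections, non-monophyletic outgroups, undefined
  distance entries, and empty event sets are all typed errors.

## Problem sizes in the test suite

The suite exercises the stages at the sizes the statistics need while
staying desk-scale: distance consistency at 10⁵ sites; NJ optimality
against exhaustive least-squares enumeration on 6 taxa (105 topologies ×
50 matrices); clock-screen calibration on 100 strict-clock alignments
(200-replicate bootstraps) on a fixed 40-taxon tree plus 50 planted-deviant
datasets; birth–death recovery on 200 trees of 50 tips; null-test
calibration on 50 replicates of 99 simulations; end-to-end pulse recovery
on 20 two-pulse datasets. These sizes are the package's own trade-off
between statistical resolution and a test suite that runs in minutes.

## Known limitations

* The method presumes a molecular clock after screening; systematic rate
  variation that survives the screen shifts mode ages.
* The calibration rate is a single global constant; per-partition rates
  enter only through the support-weighted combination.
* Mode counts depend on the bandwidth rule; the rule-of-thumb bandwidth on
  dependent pairwise samples over-smooths sharp pulses and can merge close
  events (interval boundaries, by inter-mode minima, shift accordingly).
* The global birth–death test has low power against short pulses at
  realistic sample sizes (see above); absence of rejection is weak evidence
  of rate constancy.
* The UPGMA branching times inherit any distance-matrix noise; no
  uncertainty is propagated into the node–event assignment beyond the
  shared-boundary tolerance.
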