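# divpulse

Detect and date episodes of rapid diversification (pulses) in a clade from
the **distribution of pairwise genetic distances** between aligned DNA
sequences — without committing to any particular phylogenetic topology.

The idea: under a molecular clock, the pairwise distance between two
sequences is proportional to twice the age of their most recent common
ancestor. A burst of speciation therefore leaves a *mode* in the
distribution of all pairwise distances, while steady diversification
produces a smooth distribution. `divpulse` turns that observation into a
reproducible pipeline for multi-gene alignments, aimed at molecular
systematists dating radiations (the package ships a synthetic-data generator
shaped like a two-gene marine-zooplankton dataset, so every stage can be
exercised without downloads).

## Method

Given a concatenated, partitioned alignment:

1. **Clock screen.** A neighbour-joining tree is built from model-corrected
   distances and rooted on the outgroup; each ingroup tip's root-to-tip
   length `D_i` is compared with the mean of the others,
   `z_i = (D_i − D̄₋ᵢ)/SE_i`, with `SE_i` from a bootstrap over alignment
   columns. Tips with two-sided normal `p < α` are removed.
2. **Pairwise sample and density.** All pairwise distances `x_i` among the
   retained ingroup taxa are smoothed with a Gaussian kernel,

   `f(x) = (1/nh) Σᵢ K((x − xᵢ)/h)`, `h = 0.9·min(σ̂, IQR/1.34)·n^(−1/5)`,

   on a 512-point grid (the classic defaults of R's `density`).
3. **Time calibration.** `t = x/(2r)` with a substitution rate `r`
   (subst/site/Ma) or a named-split age; a pairwise distance accrues along
   two lineages, so pairwise time equals MRCA age.
4. **Mode detection.** Modes are grid points where
   `f(x) − f(x−Δ) > 0` and `f(x) − f(x+Δ) > 0` (plateaus collapse to their
   midpoint; grid ends may be modes). Event intervals are delimited by the
   inter-mode minima.
5. **Birth–death null.** Constant birth/death rates `(b, d)` are fitted to
   the branching times of a UPGMA tree on time-calibrated distances by
   maximising the reconstructed-process likelihood

   `ln L = (n−2)·ln r + r·Σ_{i≥3} x_i + n·ln(1−ε) − 2·Σ_{i≥2} ln(e^{r x_i} − ε)`,

   with `r = b − d`, `ε = d/b`. The observed density is tested against the
   mean density `p_H0` of simulated constant-rate trees with the Monte-Carlo
   statistic `T = Σ|f − p_H0|·Δ`; `p = (1 + #{T_sim ≥ T_obs})/(n_sims + 1)`.
   Modes are reported **even when the null is not rejected** (the rejection
   status is flagged prominently in the report).
6. **Node–event map.** Internal node ages are assigned to the event whose
   interval contains them; nodes near a shared boundary count for both
   adjacent events.

## Worked example

Generate a synthetic two-gene dataset with diversification pulses planted at
50 and 20 Ma (strict clock, ~40 ingroup taxa plus an outgroup), then run the
whole pipeline:

```bash
divpulse simulate --out demo --seed 7
divpulse run --config demo/config.yaml
```

which prints

```
report: demo/analysis/report.json
modes: 6 | H0 p-value: 0.345
```

and `demo/analysis/report.json` contains (abridged):

```
retained: 46 taxa   clock-flagged: T68, T79, T74, T53
events:
  peak 58.0 Ma, interval [38.8, 69.4]   nodes: 10
  peak 34.8 Ma, interval [32.0, 38.8]   nodes: 1
  peak 26.6 Ma, interval [24.4, 32.0]   nodes: 2
  peak 19.3 Ma, interval [14.0, 24.4]   nodes: 16
  peak 11.3 Ma, interval [ 5.6, 14.0]   nodes: 8
  peak  1.5 Ma, interval [ 0.0,  5.6]   nodes: 9
birth-death fit: b = 0.0424, d = 0 /lineage/Ma
null test: T_obs = 0.628, p = 0.345 (H0 not rejected)
```

Reading the output: the two largest node clusters sit at 19.3 Ma (16 nodes)
and at the old end (peak 58.0 Ma) — the detected traces of the planted 20 Ma
and 50 Ma pulses. Smaller modes are sampling structure; the global
birth–death test cannot reject a constant-rate history at this sample size,
which is exactly why the per-mode table is always reported alongside the
test. The clock screen removed 4 of 50 ingroup sequences (false positives at
`α = 0.05` under this strict-clock simulation).

Stages can also be run separately (`divpulse stats`, `distances`,
`clocktest`, `detect`, `nulltest`), and everything is importable as a
library (`divpulse.run_pipeline`, `divpulse.gaussian_kde`, ...).

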