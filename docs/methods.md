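# Methods

## Model and procedure

rankmeta treats each study's differential-expression analysis as a noisy
ranking of a shared gene universe and asks which genes are consistently
near the top.  The pipeline is: per-study two-sample testing →
directional full rankings → normalized-rank aggregation with exact
order-statistic p-values → multiplicity adjustment → over-representation
analysis of the robust set → centrality-based hub selection on a PPI
graph → hub re-testing in a held-out cohort → logistic panel classifier.

### Per-study differential expression

Each gene is tested with a two-sided Welch t-test on log2 values;
log2 fold change is case mean minus control mean.  Welch's test is used
rather than a moderated (empirical-Bayes) t: with the group sizes this
pipeline targets (≥ 5 per arm) the moderation mainly stabilises the
variance ranking, and the aggregation step downstream is itself the
robustness device.  A pooled-variance t is available via `equal_var=True`.
Genes with zero variance in both groups get p = 1 when means are equal
(no evidence) and p = 0 otherwise (infinite t).  Significant DEGs use
strict p < 0.05 and |log2FC| > 1.

### Directional rankings and the full-list requirement

Aggregation operates on one *complete* ranking of the intersection
universe per study and direction.  A sign-split DEG list covers only the
genes of its sign, so each directional list is extended to a full
permutation: sign-matching genes ordered by (p ascending, |log2FC|
descending, gene id), then zero-log2FC genes by id, then opposite-sign
genes in reversed significance order.  This is a one-sided evidence
ordering — a gene strongly *down* is ranked last in the *up* analysis —
and under the null hypothesis it is a uniform random permutation, which
is exactly the assumption the exact p-value needs.  The deterministic
tie-break chain (p → |log2FC| → id) makes every output reproducible.

### The aggregation statistic

Normalized ranks r_j = position/m; β_{k,n}(x) is the binomial tail
P(at least k of n uniforms ≤ x), identical to the Beta(k, n−k+1) CDF;
ρ(r) = min_k β_{k,n}(r_(k)).  The public `beta_score` evaluates the
binomial sum literally; the vectorized aggregation path uses the
regularized incomplete beta function, and a test pins the two to 1e-12.

The exact p-value P(ρ_null ≤ ρ) is computed as
1 − P(U_(1) ≤ b_1, …, U_(n) ≤ b_n) with b_j = 1 − BetaQuantile(ρ; n−j+1, j).
The joint order-statistic probability is evaluated by a dynamic program
over the counts N_k = #{uniforms ≤ b_k}: the event is {N_k ≥ k ∀k}, and
stepping through the (nondecreasing) bounds one interval at a time gives
an O(n³) recursion per gene, vectorized across genes and accumulated in
extended (long double) precision.  For the smallest attainable scores
(ρ ≈ m⁻ⁿ) the complement 1 − P is still well inside long-double
resolution for the n ≤ 8 this package targets.  Properties enforced by
tests: monotonicity in ρ, exact_p ≥ ρ, reduction to the identity at
n = 1, uniformity under a simulated null, and agreement with a 10⁶-draw
Monte-Carlo null within 3 binomial SE.

Adjustment is Bonferroni by default (m = intersection-universe size),
applied separately within the up and the down analyses; BH is available.
Robust DEGs use adjusted p < 0.05; the PPI-input set uses exact p < 0.01
(a switch selects adjusted p instead, since both conventions appear in
practice).  Note that separate two-direction Bonferroni control gives a
combined per-run family-wise error near 2 × 0.049 ≈ 0.095 on null data;
the null-calibration tests account for this.

### Enrichment

One-sided hypergeometric (Fisher exact) over-representation of the query
set against a GMT collection, restricted to the tested universe (the
intersection universe by default — only measured genes are observable),
term-size eligibility window 5–2000, BH q-values over eligible terms.
No GO DAG propagation or pathway topology.

### Network centralities and hub genes

Edge lists are confidence-filtered at 0.7 (STRING's 0–1000 scale is
auto-detected and rescaled).  Centralities follow the cytoHubba
conventions: MCC sums (|C|−1)! over maximal cliques (Bron–Kerbosch via
networkx) of size ≥ 2 — which makes a node with an edgeless neighborhood
score exactly its degree, and an isolated node 0; DMNC is
|E|/|V|^1.7 of the largest connected component of the open neighborhood
(largest by nodes, ties by edges then ids); EPC averages, over 1000
Bernoulli(keep = 0.5) edge-percolated copies, the number of other nodes
in the node's component.  The percolation scheme, realization count and
keep probability are not standardized anywhere, so they are explicit,
seeded parameters here.  Hub genes are the 5-way intersection of the
top-100 lists of the four centralities and the top-100 aggregated genes
(up and down pooled by exact p).  DMNC deliberately rewards membership
in small dense modules rather than raw degree, so the intersection is
a conservative filter — on sparse random graphs it can be empty.

### Diagnostic classifier

Samples of the validation cohort are split 60/40 (round-half-up on the
training size, so 48 samples give 29/19; plain randomization, no
stratification).  The panel is the hub genes that re-validate
(p < 0.05) in that cohort.  The model is maximum-likelihood logistic
regression fitted by Newton/IRLS with an L2 ridge of 1e-4 on the
standardized features (intercept unpenalized): with tens of samples and
several genes the classes are typically separable and the unridged MLE
diverges; 1e-4 is small enough that on non-separable data the fit agrees
with the unpenalized MLE to ~1e-4 (tested against an independent
implementation).  Evaluation reports confusion counts at a 0.5
probability cutoff and the Mann–Whitney AUC with ties counted 1/2.
Seeded splits are internally deterministic; no claim is made of
reproducing any other software's RNG stream.

## Synthetic data: what it emulates and what it does not

`simulate_multistudy` emulates several case/control cohorts on different
platforms: per-gene baselines drawn once from N(8, 1.5²) log2 units and
shared across studies; each platform measures a seeded random subset
(default 90%) of the 2000-gene universe, always including the DE genes
so the intersection contains all evaluable signal; 5% of genes are DE
(half up, half down) with |log2FC| = 2 attenuated by a per-study factor
(default 0.8); i.i.d. Gaussian noise with SD 0.5 log2 units; 10 cases vs
10 controls per study.  These defaults are chosen as a realistic
moderate-effect microarray regime — a planted gene has a per-study
t-statistic around 7, large enough that a well-calibrated aggregator
should recover ≥ 90% of the signal, which is what the recovery tests
check.  `run-all --simulate` generates one extra study held out as the
validation cohort.

Not modeled: probe-level structure, correlated genes, batch effects,
heavy-tailed or intensity-dependent noise, platform-specific dynamic
ranges, or missing values.  Passing tests therefore demonstrate
calibration and recovery of the *method* under its own null and a clean
planted-signal alternative — not performance on any real cohort.
`simulate_null_rank_matrix` provides the exact aggregation null
(independent uniform permutation columns); `simulate_network` provides
Erdős–Rényi graphs with optionally boosted planted hubs.

## Numerical choices and degenerate inputs

- Exact p-value DP in `np.longdouble`; Beta quantiles from scipy's
  `betaincinv` (tolerance inherited, ~1e-14); bounds clipped to [0, 1]
  and forced nondecreasing before the recursion.
- ρ is floored at the smallest positive float before inversion.
- Ties everywhere break deterministically (documented chains ending in
  gene/node id).
- Probe collapsing averages arithmetically; a missing probe-sample cell
  is excluded from that cell's mean.
- Degenerate t-tests (zero variance both arms) handled explicitly as
  above.
- IRLS caps weights below at 1e-10 and raises a ConvergenceError naming
  the ridge if the Newton system is singular or fails to settle in 200
  iterations.

## Problem sizes

Test and acceptance runs use: 10⁶ Monte-Carlo null draws for the exact
p-value; a 10⁴-gene, 4-study null matrix (KS uniformity, 20-seed
family-wise control); 2000-gene, 4-study recovery runs (one planted,
20 null seeds); 50 random ≤ 12-node graphs for the MCC brute-force
oracle; 10⁵ percolation realizations for the single-edge EPC check; and
50 permutation seeds for classifier chance-level checks.  The full suite
runs in well under a minute on one CPU apart from the Monte-Carlo
blocks, which dominate at ~20 s.

## Known limitations

- No truncated-list (topCutoff) or weighted aggregation variants; full
  rankings are a hard precondition.
- Welch t, not moderated t; no covariates, batch terms or paired
  designs.
- Enrichment ignores ontology structure.
- MCC is exponential-time in pathological graphs; guarded by a
  configurable node limit (default 5000).
- The classifier offers no cross-validation or regularization-path
  selection; it is a fixed-panel diagnostic readout, not a model-search
  tool.
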