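# Methods

`anchornet` implements, end to end on synthetic data, the computational
chain that links a single "anchor" gene to a downstream
transcription-factor signaling program: differential-expression
meta-analysis across cohorts, median-split survival analysis, weighted
Kolmogorov–Smirnov drug-connectivity scoring, constrained MCMC
Bayesian-network consensus inference, shortest-path subnetwork
extraction, layer-wise enrichment validation, and key-driver analysis.
This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Synthetic-data model

All inputs are drawn from a linear-Gaussian structural equation model
(SEM) on a known random DAG. Nodes are genes; each gene's value is the
weighted sum of its parents plus independent Gaussian noise, sampled in
topological order. A linear SEM was chosen because its moments are
available in closed form (for a chain X→Y with weight b and residual sd
σ, var(Y) = b²·var(X) + σ²), which turns most generator tests into
exact oracles.

**Graph.** `generate_true_dag(n_nodes, mean_out_degree, n_tfs, seed)`
places the nodes in a random topological order and draws each
forward-ordered pair as an edge independently, with the per-pair
probability set so the expected edge count is
`n_nodes × mean_out_degree`. Edge weights are uniform on ±[0.5, 1.5] so
that no edge is near-zero and unidentifiable. The anchor is the node
with the largest descendant set — the master regulator whose downstream
program the pipeline dissects. The `n_tfs` highest-out-degree other
nodes are tagged as transcription factors and their out-edges exported
as orientation priors, emulating ENCODE/ChIP-style TF–target resources.

**Noise modes.** With homoscedastic noise (`noise_mode="fixed"`,
default, residual sd 1.0 everywhere) the closed-form variance oracles
hold exactly, but variance compounds multiplicatively with depth: in a
25-node graph of mean out-degree 2, deep nodes reach sd ≈ 30 and
pairwise correlations ≈ 0.99. Real normalized expression data shows
nothing like this, and the near-collinearity makes score-based
structure learning pathologically rugged. `noise_mode="snr"` therefore
sets each regulated node's residual sd equal to the analytic sd of its
parent signal (constant signal-to-noise, R² = 0.5 per regulated node),
computed exactly from the accumulated SEM covariance. The network
analyses and the end-to-end pipeline declare `"snr"` as their study
condition; generator unit tests that rely on the closed-form variance
identities use `"fixed"`.

**Planted effects.** Knockdown shifts the target's exogenous term by
−δ before propagation (an shRNA dose effect), so descendant shifts are
δ times the summed path-weight products — recoverable in closed form
via (I − W)⁻¹ and used as the sign oracle. Survival times are
exponential with hazard λ₀·HRᶻ, z the above-median indicator of anchor
expression, with independent uniform censoring at the stated fraction.
The drug compendium plants mimic instances (query up-genes pushed to
the top of the fold-change ranking, down-genes to the bottom, at a
stated concordance), reversers (inverted), and fully random nulls.
Copy-number tables plant an exact fraction of samples with GAIN/AMP
segments overlapping the ±2 Mb TSS window.

Every generator is a pure function of (arguments, seed); sub-streams
are derived from the single seed per call.

## Expression statistics

Two-group differential expression is a per-gene two-sample t-test
(Welch by default; the pooled-variance form is a flag) with
Benjamini–Hochberg adjustment across genes; logFC is the difference of
group means on the log2 scale. Cross-cohort evidence is combined by
summing −log10 p per gene; discordant logFC signs are flagged but do
not change the score. Consensus signatures take genes passing
FDR < 0.05 and linear fold change > 1.3 (i.e. |logFC| > log2 1.3) in
the same direction in at least 2 of 3 independent knockdowns; direction
conflicts (possible only when the support threshold is at most half the
tables) are resolved by strict majority, ties dropped — the only rule
consistent with both independent direction tallies and monotonicity in
the support threshold. Anchor correlation uses Spearman's rho with
BH-adjusted p; the pass rule is fdr < 0.05 and |rho| strictly > 0.2.
Gene-set overlap uses the one-sided Fisher exact test with fold
enrichment k·N/(n_a·n_b); the universe defaults to all measured genes
and is configurable. Multi-set overlaps use the exact hypergeometric
tail for two sets and seeded Monte Carlo for three or more. CNA burden
counts samples with any GAIN/AMP segment intersecting the closed
interval [tss − 2 Mb, tss + 2 Mb], 1-based inclusive on both ends.

## Survival

Samples are stratified strictly above/below the median of anchor
expression; ties at the median go to "low" deterministically. The
Kaplan–Meier estimator, two-group log-rank test, and univariate Cox
fit on the high/low indicator are delegated to lifelines (Efron tie
handling, Newton–Raphson); this package owns the stratification rule
and result contracts, and tests verify lifelines' output against a
hand product-limit, a direct O−E−V tabulation, and grid-search
maximization of the partial likelihood.

## Drug connectivity (weighted KS)

A drug instance's N genes are rank-sorted by descending fold change
(ties broken lexicographically) and converted to weights
r_j = (Rank_j − (N+1)/2) / ((N+1)/2), which sum to zero and approach
±1 at the extremes. For a query set G_x the running sum
f1(i) − f2(i) accumulates |r_j|^p / M over members and 1/(N − n_x)
over non-members; S_x is the signed value at the maximum absolute
deviation (earliest index on ties, compared with a 1e-12 tolerance so
exact ±x ties resolve deterministically). With exponent p = 0 this is
the classic unweighted KS-style enrichment statistic; p = 1 is the
default. The combined score is S = 0 when S1·S2 ≥ 0 and S1 − S2
otherwise, so S ∈ [−2, 2]; S/2 is reported alongside so magnitudes are
comparable on a [−1, 1] scale. Permutation significance redraws
disjoint random set pairs of matched sizes with the add-one estimator;
the permutation statistic is the ungated |S1 − S2| — the sign-rule
gate puts a point mass at S = 0 (roughly half of null queries), which
would pile null p-values at 1, while the ungated statistic is
continuous, equals |S| whenever the gate passes, and keeps null
p-values uniform (verified to KS distance < 0.03 at 500 queries).

## Bayesian-network consensus

Structures over continuous expression are scored with decomposable
Gaussian BIC: each node contributes its OLS log-likelihood given its
parents minus (k/2)·log n, k = |parents| + 2. Node terms are computed
from the centered scatter matrix (O(|parents|³) per term, independent
of sample count) and cached; tests verify equality with per-sample
regression. The structure prior is uniform, so Metropolis acceptance
depends only on score differences. TF–target priors ban the reversed
orientation (target → TF) outright — without them, Markov equivalence
leaves many orientations unidentifiable.

The proposal draws a random ordered pair (i, j): if edge i→j exists,
delete or reverse with equal probability; otherwise add or stay. This
kernel is symmetric, so the proposal ratio is identically 1. Proposals
creating cycles, violating bans, or exceeding `max_parents` are
rejected. Chains anneal the acceptance temperature geometrically
(default 500 → 0.05) over the iteration budget: plain fixed-temperature
chains freeze in poor local optima on these landscapes (BIC deltas are
tens to hundreds of units), while the high-temperature phase randomizes
the trajectory — serving the role of the random initial structure —
and the quench settles each chain into a mode. `t_initial = t_final = 1`
recovers the plain sampler. Each chain contributes its final structure;
edges present in strictly more than 30% of chains form the consensus.
Remaining directed cycles are broken by repeatedly deleting the
weakest-supported edge on a deterministically discovered cycle (DFS
from the lexicographically smallest node; support ties broken by
smallest (parent, child)). Per-cohort consensus networks are combined
by the union of directed edges with support = max across cohorts
(cohort provenance kept per edge), followed by cycle removal.

Defaults: 1000 chains in production configs, 50 in validation runs;
`max_parents` 3 by default, 8 in the network-recovery fixture (whose
ground truth has in-degrees up to 8); 100,000 proposals per chain for
25–40 node problems (about 80 visits per ordered pair). At the
documented recovery conditions — 25 nodes, mean out-degree 2,
15 TF-role nodes, n = 1000, `"snr"` noise — consensus precision/recall
was 0.82–0.91 / 0.88–0.93 across three seeds.

## Subnetwork and key drivers

The anchor subnetwork is the union of all tied shortest directed paths
from the anchor to each reachable member of a target gene set
(unreachable targets reported separately); edges are unweighted for
path length since consensus supports are not distances. k-layer
downstream neighborhoods contain all nodes within k directed steps,
source excluded. Layer-wise validation Fisher-tests each neighborhood
against a perturbation signature over a configurable universe
(network nodes by default). Key-driver analysis tests every node's
h-layer downstream neighborhood (h = 6 by default, matching the
deepest layer the validation profile examines; smaller in desk-scale
runs) for target-set enrichment, BH-adjusts across nodes, and ranks by
p, then neighborhood size, then node id. The hub/out-degree criterion
of some key-driver variants is deliberately not included; the
enrichment form is the one validated by the planted-driver fixture.

## Pipeline and problem sizes

`run_pipeline` chains every stage on synthetic data and writes each
intermediate table plus a JSON manifest (config, seeds, thresholds,
SHA-256 digests of every output); replaying a manifest reproduces all
tables bit for bit. The default run uses 40 genes (mean out-degree 2,
16 TFs), two cohorts of 1000 and 800 samples with a planted batch
covariate removed by OLS residualization, three knockdown replicates
of 100 + 100 samples at δ = 4, a survival cohort of 500 with true
HR = 2 and 30% censoring, a compendium of 1 mimic, 1 reverser and 10
nulls, and 30 chains × 120,000 iterations per cohort — about one
minute on one CPU. These sizes are the package's desk-scale study
conditions: large enough that every stage's signal is comfortably
detectable, small enough to rerun casually.

## What the synthetic data does and does not show

The generator reproduces the statistical *structure* of the study's
inputs — multi-cohort expression from a shared regulatory DAG, a
knockdown transcriptome, proportional-hazards survival tied to anchor
expression, a compendium with concordant/reversing/null instances —
but not their scale (tens of genes, not 20k+), their noise family
(Gaussian, not count-based or microarray-specific), batch structure
beyond a single additive covariate, or any real gene identity. Passing
tests therefore demonstrate correctness of the algorithms and
recoverability of planted effects at desk scale, not performance on
the real cohorts. Known limitations: BIC-scored consensus retains a
few reproducible false edges at n = 1000 (shortcut edges whose fit
gain genuinely exceeds the BIC penalty); orientation of edges not
covered by TF priors is only as good as the equivalence class allows;
and the key-driver enrichment form makes no claim of matching the
hub-based variants.
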