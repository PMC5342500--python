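# anchornet

Linking one anchor gene to a downstream signaling program, end to end:
differential-expression meta-analysis across cohorts, median-split
survival analysis, weighted Kolmogorov–Smirnov drug-connectivity
scoring, constrained MCMC Bayesian-network consensus inference,
shortest-path subnetwork extraction, layer-wise enrichment validation,
and key-driver analysis — exercised on seeded synthetic data drawn
from a known ground-truth gene-regulatory DAG, so every planted effect
is recoverable and every statistic has an oracle.

The intended users are computational biologists who want a tested,
reusable implementation of this analysis chain (the kind used to tie a
candidate regulator such as an aminoacyl-tRNA synthetase to estrogen
signaling in breast-tumor cohorts) without depending on any of the
large proprietary or access-controlled datasets such studies consume.

## The statistics at the core

**Meta-analysis.** Per-gene evidence across cohorts is combined as
`score(g) = Σ_cohorts −log10 p_g`; genes rank by summed evidence.

**Drug connectivity (weighted KS).** A drug instance's N genes are
rank-sorted by descending fold change and weighted
`r_j = (Rank_j − mean(Rank)) / mean(Rank)`, `mean(Rank) = (N+1)/2`.
For a query set G_x of size n_x the running sum

    f1(i) = Σ_{g_j∈G_x, j≤i} |r_j|^p / M,   M = Σ_{g_j∈G_x} |r_j|^p
    f2(i) = Σ_{g_j∉G_x, j≤i} 1 / (N − n_x)

gives `S_x` = the signed maximum deviation of `f1 − f2`. With up-set
G1 and down-set G2, the connectivity score is `S = 0` if `S1·S2 ≥ 0`
and `S = S1 − S2` otherwise: positive S means the drug mimics the
query signature, negative means it reverses it. At exponent p = 0 this
reduces to the classic unweighted KS statistic; p = 1 is the default.

**Network inference.** DAGs over expression are scored with Gaussian
BIC and sampled by annealed Metropolis chains under TF-orientation
constraints (targets may not parent their TFs). Edges in strictly more
than 30% of chains form the consensus; cycles are broken by removing
the weakest-supported edge; per-cohort networks are unioned into a
super network. Key drivers are nodes whose k-layer downstream
neighborhoods are Fisher-enriched for a target gene set.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
shared seeded configuration, writing tables under `results/`:

```bash
python analysis/01_simulate_inputs.py
python analysis/02_differential_meta.py
python analysis/03_survival_prognosis.py
python analysis/04_signature_connectivity.py
python analysis/05_network_inference.py
python analysis/06_subnetwork_drivers.py
```

Output from the run at seed 1 (abridged):

```
ground truth: 40 genes, 73 edges, anchor=G008, 54 TF-target priors
meta-analysis top gene: G008 (score 137.3, summed -log10 p over 2 cohorts)
CNA gain/amp fraction within 2 Mb of TSS: 0.450 (225/500)
log-rank: chi2=75.72, p=3.26e-18
Cox high-vs-low: HR=2.66 [2.12, 3.34], Wald p=3.22e-17
consensus signature: 13 up, 6 down (FDR<0.05, FC>1.3, >=2 of 3 replicates)
top instance:    mimic_1 S=+2.000 concordant
bottom instance: reverser_1 S=-2.000 reversing
super network: 92 edges (removed 4 loop edges), precision=0.74, recall=0.93
  layer 2: |N|=21, overlap=15, FE=1.50, p=0.0018
key-driver analysis: 0 drivers at FDR<0.05; top node G002 (p=0.75)
```

Reading it: the anchor gene G008 tops the two-cohort meta-analysis;
samples in the upper half of its expression have about twice the
hazard (the generator planted HR = 2); the knockdown consensus
signature drives a compendium query in which the planted mimic scores
the maximum S = +2 and the planted reverser −2; the recovered super
network contains 93% of the true regulatory edges; and the anchor's
2-layer downstream neighborhood in that network is significantly
enriched for the knockdown signature (p = 0.0018) — the network
validates against the perturbation experiment. No node clears the
key-driver FDR cut here because the desk-scale subnetwork is nearly
saturated by signature genes.

The same chain is available as one call:

```python
from anchornet.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(seed=1), "results/run")
```

Re-running with the same config reproduces every output byte for byte
(the manifest records SHA-256 digests of all tables).

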