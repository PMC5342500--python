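"""Generate every synthetic input: ground-truth DAG, expression cohorts,
anchor-knockdown replicates, survival table, and copy-number segments.

All draws are seeded through the shared config, so rerunning this
script reproduces the files bit for bit.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import CONFIG, DATA

import pandas as pd

from anchornet import io, simulate

net = simulate.generate_true_dag(
    CONFIG.n_genes, CONFIG.mean_out_degree, CONFIG.n_tfs, seed=CONFIG.seed
)
anchor = net.anchor
print(f"ground truth: {len(net.nodes)} genes, {len(net.edges)} edges, "
      f"anchor={anchor}, {len(net.tf_pairs)} TF-target priors")

io.write_network(
    pd.DataFrame(sorted(net.edges), columns=["parent", "child", "support"]),
    DATA / "true_network.tsv",
)
pd.DataFrame(sorted(net.tf_pairs), columns=["tf", "target"]).to_csv(
    DATA / "tf_priors.tsv", sep="\t", index=False
)
pd.Series(net.roles, name="role").rename_axis("gene").to_csv(
    DATA / "node_roles.tsv", sep="\t"
)

for k, n in enumerate(CONFIG.cohort_sizes):
    label = f"cohort{k+1}"
    spec = simulate.CohortSpec(
        n_samples=n, seed=CONFIG.seed + 101 + k, label=label,
        covariate_effects={"batch": 1.0},
    )
    expr, annot = simulate.simulate_cohort_expression(
        net, spec, noise_mode=CONFIG.noise_mode
    )
    io.write_expression(expr, DATA / f"expression_{label}.tsv")
    annot.to_csv(DATA / f"annotations_{label}.tsv", sep="\t")
    print(f"{label}: {expr.shape[1]} samples (batch covariate planted)")

# tumor-vs-normal style contrast per cohort: anchor exogenously elevated
for k in range(len(CONFIG.cohort_sizes)):
    kd, groups = simulate.simulate_knockdown_signature(
        net, anchor, -CONFIG.knockdown_delta,
        n_per_group=CONFIG.n_per_group, seed=CONFIG.seed + 201 + k,
        noise_mode=CONFIG.noise_mode,
    )
    io.write_expression(kd, DATA / f"contrast_cohort{k+1}.tsv")

# three independent anchor-knockdown replicates (shRNA analog)
for r in range(CONFIG.n_replicates):
    kd, groups = simulate.simulate_knockdown_signature(
        net, anchor, CONFIG.knockdown_delta,
        n_per_group=CONFIG.n_per_group, seed=CONFIG.seed + 401 + r,
        noise_mode=CONFIG.noise_mode,
    )
    io.write_expression(kd, DATA / f"knockdown_rep{r+1}.tsv")
print(f"{CONFIG.n_replicates} knockdown replicates, "
      f"delta={CONFIG.knockdown_delta}, n/group={CONFIG.n_per_group}")

# survival cohort tied to anchor expression
spec = simulate.CohortSpec(
    n_samples=CONFIG.survival_n, seed=CONFIG.seed + 301, label="surv"
)
surv_expr, _ = simulate.simulate_cohort_expression(
    net, spec, noise_mode=CONFIG.noise_mode
)
table = simulate.simulate_survival_times(
    surv_expr.loc[anchor], CONFIG.true_hr, CONFIG.censor_frac,
    seed=CONFIG.seed + 302,
)
io.write_survival(table, DATA / "survival.csv")
print(f"survival: n={len(table)}, true HR={CONFIG.true_hr}, "
      f"{int(table['event'].sum())} events")

# copy-number segments with a 45% planted gain fraction near the anchor TSS
segments = simulate.simulate_cna_segments(
    n_samples=500, gain_frac=0.45, tss=100_000_000, seed=CONFIG.seed + 151
)
segments.to_csv(DATA / "cna_segments.tsv", sep="\t", index=False)
print(f"CNA: {len(segments)} segments for 500 samples, planted gain 45%")
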