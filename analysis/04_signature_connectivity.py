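"""Consensus knockdown signature and drug-connectivity query.

Finding to check: genes responding in at least two of three knockdown
replicates form the anchor signature; querying a compendium containing
a planted signature mimic and a planted reverser ranks the mimic first
(S > 0, concordant) and the reverser last (S < 0, reversing) — the
qualitative shape of an anti-endocrine-therapy connectivity hit list.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import CONFIG, DATA, TABLES

import numpy as np

from anchornet import connectivity, exprstats, io, simulate

rep_tables = []
for r in range(CONFIG.n_replicates):
    expr = io.read_expression(DATA / f"knockdown_rep{r+1}.tsv")
    a = [c for c in expr.columns if c.startswith("kd_")]
    b = [c for c in expr.columns if c.startswith("ctrl_")]
    rep_tables.append(exprstats.differential_expression(expr, a, b))

signature = exprstats.consensus_signature(
    rep_tables, CONFIG.de_fdr, CONFIG.de_fc, CONFIG.min_support
)
io.write_gmt(
    io.signature_to_gmt(signature.up, signature.down, "ANCHOR_KD"),
    TABLES / "signature.gmt",
)
print(f"consensus signature: {len(signature.up)} up, "
      f"{len(signature.down)} down "
      f"(FDR<{CONFIG.de_fdr}, FC>{CONFIG.de_fc}, "
      f">={CONFIG.min_support} of {CONFIG.n_replicates} replicates)")

log_cut = float(np.log2(CONFIG.de_fc))
rep_sets = [
    set(t.index[(t["fdr"] < CONFIG.de_fdr) & (t["logFC"].abs() > log_cut)])
    for t in rep_tables
]
universe = set(rep_tables[0].index)
overlap = exprstats.multiset_intersection_test(
    rep_sets, universe, n_mc=2000, seed=CONFIG.seed + 451
)
print(f"replicate DEG overlap: {overlap['observed']} genes shared, "
      f"p={overlap['p']:.3g} ({overlap['method']})")

compendium = simulate.simulate_drug_compendium(
    set(signature.up), set(signature.down),
    n_genes=max(100, CONFIG.n_genes * 4),
    n_nulls=CONFIG.compendium_nulls, seed=CONFIG.seed + 501,
)
compendium.to_csv(DATA / "compendium.tsv", sep="\t", index_label="gene")
query = connectivity.QuerySignature(
    up=frozenset(signature.up), down=frozenset(signature.down)
)
hits = connectivity.query_compendium(compendium, query)
hits.to_csv(TABLES / "connectivity.tsv", sep="\t")
print("top instance:   ", hits.index[0], f"S={hits['s'].iloc[0]:+.3f}",
      hits["call"].iloc[0])
print("bottom instance:", hits.index[-1], f"S={hits['s'].iloc[-1]:+.3f}",
      hits["call"].iloc[-1])
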