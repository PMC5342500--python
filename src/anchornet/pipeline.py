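"""End-to-end synthetic analysis: simulate -> DE/meta -> survival ->
connectivity -> network -> subnetwork -> key drivers.

`run_pipeline` executes the full chain on data drawn from a seeded
ground-truth DAG and writes every intermediate table plus a JSON run
manifest (config, seeds, thresholds, SHA-256 digests of all outputs).
Re-running with the same config reproduces every table bit-for-bit;
`replay` checks that property against a stored manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayesnet, connectivity, exprstats, io, netquery, simulate, survival

log = logging.getLogger("anchornet.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "replay"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, seeds and problem sizes for one synthetic run."""

    seed: int = 0
    # study-condition thresholds
    de_fdr: float = 0.05
    de_fc: float = 1.3
    min_support: int = 2
    rho_cutoff: float = 0.2
    consensus_threshold: float = 0.3
    kda_fdr: float = 0.05
    # problem sizes (desk scale)
    n_genes: int = 40
    mean_out_degree: float = 2.0
    n_tfs: int = 16
    cohort_sizes: tuple = (1000, 800)
    knockdown_delta: float = 4.0
    n_per_group: int = 100
    n_replicates: int = 3
    true_hr: float = 2.0
    censor_frac: float = 0.3
    survival_n: int = 500
    n_chains: int = 30
    n_iter: int = 120000
    max_parents: int = 8
    kda_h: int = 3
    compendium_nulls: int = 10
    noise_mode: str = "snr"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config from a YAML key-value file; keys as above."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort_sizes" in raw:
            raw["cohort_sizes"] = tuple(raw["cohort_sizes"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["cohort_sizes"] = list(d["cohort_sizes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def validate(self) -> None:
        checks = [
            0 < self.de_fdr < 1,
            self.de_fc > 1,
            self.min_support >= 1,
            0 < self.rho_cutoff < 1,
            0 <= self.consensus_threshold < 1,
            0 < self.kda_fdr < 1,
            self.n_genes >= 3,
            all(n >= 2 for n in self.cohort_sizes),
            0 <= self.censor_frac < 1,
            self.true_hr > 0,
            self.n_chains >= 1,
        ]
        if not all(checks):
            raise ValueError("invalid pipeline configuration")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on synthetic data; return the manifest dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # --- stage 1: ground truth and cohorts -------------------------------
    log.info("stage=simulate seed=%d", config.seed)
    net = simulate.generate_true_dag(
        config.n_genes, config.mean_out_degree, config.n_tfs, seed=config.seed
    )
    anchor = net.anchor
    edges_df = pd.DataFrame(
        [(p, c, w) for p, c, w in sorted(net.edges)],
        columns=["parent", "child", "support"],
    )
    io.write_network(edges_df, outdir / "true_network.tsv")

    cohorts = {}
    for k, n in enumerate(config.cohort_sizes):
        label = f"cohort{k+1}"
        spec = simulate.CohortSpec(
            n_samples=n, seed=config.seed + 101 + k, label=label,
            covariate_effects={"batch": 1.0},
        )
        expr, annot = simulate.simulate_cohort_expression(
            net, spec, noise_mode=config.noise_mode
        )
        io.write_expression(expr, outdir / f"expression_{label}.tsv")
        annot.to_csv(outdir / f"annotations_{label}.tsv", sep="\t")
        # remove the planted batch confounder before any downstream stage
        cohorts[label] = exprstats.residualize_covariates(expr, annot[["batch"]])

    # CNA stage: planted gain fraction near the anchor's TSS
    tss = 100_000_000
    segments = simulate.simulate_cna_segments(
        n_samples=500, gain_frac=0.45, tss=tss, seed=config.seed + 151
    )
    segments.to_csv(outdir / "cna_segments.tsv", sep="\t", index=False)
    cna = exprstats.cna_gain_fraction(segments, tss=tss, n_total=500)
    results["cna_gain_fraction"] = cna["fraction"]

    # --- stage 2: differential expression + meta-analysis ----------------
    # tumor-like contrast: anchor exogenously elevated in half the samples
    log.info("stage=differential")
    de_tables = {}
    for k, (label, expr) in enumerate(cohorts.items()):
        kd, groups = simulate.simulate_knockdown_signature(
            net, anchor, -config.knockdown_delta,  # negative delta = upshift
            n_per_group=config.n_per_group, seed=config.seed + 201 + k,
            noise_mode=config.noise_mode,
        )
        a = list(groups.index[groups == "knockdown"])  # elevated group
        b = list(groups.index[groups == "control"])
        tab = exprstats.differential_expression(kd, a, b)
        de_tables[label] = tab
        tab.to_csv(outdir / f"de_{label}.tsv", sep="\t")
    meta = exprstats.meta_combine(de_tables)
    meta.to_csv(outdir / "meta_scores.tsv", sep="\t")
    results["meta_top_gene"] = meta.index[0]
    results["meta_anchor_score"] = float(meta.loc[anchor, "score"])

    # --- stage 3: survival ------------------------------------------------
    log.info("stage=survival")
    spec = simulate.CohortSpec(
        n_samples=config.survival_n, seed=config.seed + 301, label="surv"
    )
    surv_expr, _ = simulate.simulate_cohort_expression(net, spec, noise_mode=config.noise_mode)
    anchor_vals = surv_expr.loc[anchor]
    table = simulate.simulate_survival_times(
        anchor_vals, config.true_hr, config.censor_frac, seed=config.seed + 302
    )
    table["group"] = survival.stratify_by_median(table["anchor_expr"])
    io.write_survival(table, outdir / "survival.csv")
    lr = survival.logrank_test(table)
    cox = survival.cox_hazard_ratio(table)
    fit = pd.DataFrame(
        [{**asdict(cox), "logrank_p": lr["p"], "logrank_stat": lr["statistic"]}]
    )
    fit.to_csv(outdir / "survival_fit.tsv", sep="\t", index=False)
    results["cox_hr"] = cox.hr
    results["logrank_p"] = lr["p"]

    # --- stage 4: anchor correlation -------------------------------------
    log.info("stage=correlate")
    corr = exprstats.correlate_anchor(
        cohorts["cohort1"], anchor, rho_cutoff=config.rho_cutoff
    )
    corr.to_csv(outdir / "anchor_correlation.tsv", sep="\t")
    results["n_correlated"] = int(corr["passes"].sum())

    # --- stage 5: knockdown replicates -> consensus signature ------------
    log.info("stage=signature")
    rep_tables = []
    for r in range(config.n_replicates):
        kd, groups = simulate.simulate_knockdown_signature(
            net, anchor, config.knockdown_delta,
            n_per_group=config.n_per_group, seed=config.seed + 401 + r,
            noise_mode=config.noise_mode,
        )
        a = list(groups.index[groups == "knockdown"])
        b = list(groups.index[groups == "control"])
        rep_tables.append(exprstats.differential_expression(kd, a, b))
    signature = exprstats.consensus_signature(
        rep_tables, config.de_fdr, config.de_fc, config.min_support
    )
    # replicate concordance: multi-set overlap of per-replicate DEG lists
    log_cut = float(np.log2(config.de_fc))
    rep_sets = [
        set(t.index[(t["fdr"] < config.de_fdr) & (t["logFC"].abs() > log_cut)])
        for t in rep_tables
    ]
    overlap = exprstats.multiset_intersection_test(
        rep_sets, set(net.nodes), n_mc=2000, seed=config.seed + 451
    )
    results["replicate_overlap_p"] = overlap["p"]
    io.write_gmt(
        io.signature_to_gmt(signature.up, signature.down, "ANCHOR_KD"),
        outdir / "signature.gmt",
    )
    results["signature_up"] = len(signature.up)
    results["signature_down"] = len(signature.down)

    # --- stage 6: drug-connectivity query --------------------------------
    log.info("stage=connectivity")
    if signature.up and signature.down:
        compendium = simulate.simulate_drug_compendium(
            set(signature.up), set(signature.down),
            n_genes=max(100, config.n_genes * 4),
            n_nulls=config.compendium_nulls, seed=config.seed + 501,
        )
        query = connectivity.QuerySignature(
            up=frozenset(signature.up), down=frozenset(signature.down)
        )
        hits = connectivity.query_compendium(compendium, query)
        hits.to_csv(outdir / "connectivity.tsv", sep="\t")
        results["top_instance"] = hits.index[0]
        results["bottom_instance"] = hits.index[-1]
        results["top_score"] = float(hits["s"].iloc[0])

    # --- stage 7: network inference --------------------------------------
    log.info("stage=network chains=%d iter=%d", config.n_chains, config.n_iter)
    constraints = bayesnet.PriorConstraints.from_pairs(net.tf_pairs)
    nets = []
    for k, (label, expr) in enumerate(cohorts.items()):
        cfg = bayesnet.ChainConfig(
            n_chains=config.n_chains, n_iter=config.n_iter,
            seed=config.seed + 601 + k, max_parents=config.max_parents,
        )
        chains = bayesnet.learn_chains(expr, constraints, cfg)
        nets.append(
            bayesnet.consensus_network(
                chains, config.consensus_threshold, nodes=tuple(expr.index)
            )
        )
    union = bayesnet.union_networks(nets, labels=list(cohorts))
    union_df = pd.DataFrame(
        [
            (p, c, s, ";".join(union.cohorts.get((p, c), ())))
            for (p, c), s in sorted(union.support.items())
        ],
        columns=["parent", "child", "support", "cohorts"],
    )
    io.write_network(union_df, outdir / "super_network.tsv")
    pr = bayesnet.precision_recall(union, {(p, c) for p, c, _ in net.edges})
    results["network_precision"] = pr["precision"]
    results["network_recall"] = pr["recall"]

    # --- stage 8: anchor subnetwork + layer validation + key drivers -----
    log.info("stage=subnetwork")
    g = union.graph()
    sig_all = set(signature.up) | set(signature.down)
    targets = sig_all or {c for _, c, _ in net.edges}
    sub = netquery.shortest_path_subnetwork(g, anchor, targets)
    sub_df = pd.DataFrame(sorted(sub.edges), columns=["parent", "child"])
    sub_df["support"] = [
        union.support.get((p, c), 1.0) for p, c in zip(sub_df["parent"], sub_df["child"])
    ]
    io.write_network(sub_df, outdir / "anchor_subnetwork.tsv")

    layers = netquery.layer_enrichment_profile(
        g, anchor, sig_all, k_max=max(config.kda_h, 6)
    )
    layers.to_csv(outdir / "layer_enrichment.tsv", sep="\t")
    valid = layers["p"].dropna()
    results["layer_min_p"] = float(valid.min()) if len(valid) else float("nan")

    if sub.edges:
        kda = netquery.key_driver_analysis(
            sub.graph(), targets, h=config.kda_h, fdr_cutoff=config.kda_fdr
        )
        kda.to_csv(outdir / "key_drivers.tsv", sep="\t")
        results["n_key_drivers"] = int(kda["is_driver"].sum())

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "results": results,
        "outputs": {
            p.name: _digest(p)
            for p in sorted(outdir.iterdir())
            if p.suffix in (".tsv", ".csv", ".gmt")
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def replay(manifest_path, outdir) -> bool:
    """Re-run the manifest's config and verify bit-identical outputs."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["cohort_sizes"] = tuple(cfg_dict["cohort_sizes"])
    config = PipelineConfig(**cfg_dict)
    new = run_pipeline(config, outdir)
    return new["outputs"] == manifest["outputs"]
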