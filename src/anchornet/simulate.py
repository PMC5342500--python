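"""Seeded synthetic-data generators for every input the pipeline consumes.

All downstream stages — differential expression, survival, drug
connectivity, Bayesian-network inference, subnetwork extraction and
key-driver analysis — are exercised on data drawn from a known
ground-truth model, so every planted effect is recoverable and every
statistic has an oracle.

The generative model is a linear-Gaussian structural equation model
(SEM) on a random DAG: each gene's expression is a weighted sum of its
parents plus independent Gaussian noise, sampled in topological order.
Closed-form moments of this model (e.g. var(Y) = b^2 var(X) + sigma^2
for a chain X -> Y) are used as exact test oracles.

Every generator is a pure function of its arguments and seed: identical
calls return bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TrueNetwork",
    "CohortSpec",
    "generate_true_dag",
    "simulate_cohort_expression",
    "simulate_knockdown_signature",
    "simulate_survival_times",
    "simulate_drug_compendium",
    "simulate_cna_segments",
]


@dataclass(frozen=True)
class TrueNetwork:
    """Ground-truth weighted DAG with node roles.

    Attributes
    ----------
    nodes : tuple of str
        Gene identifiers.
    edges : tuple of (parent, child, weight)
        Directed weighted edges; acyclic by construction.
    noise_sd : float
        Residual standard deviation shared by all nodes.
    roles : dict
        Maps node -> one of {"anchor", "tf", "target", "other"}.
        Exactly one node carries the "anchor" role.
    tf_pairs : tuple of (tf, target)
        Out-edges of TF-role nodes, exported as orientation priors.
    """

    nodes: tuple
    edges: tuple
    noise_sd: float = 1.0
    roles: dict = field(default_factory=dict)
    tf_pairs: tuple = ()

    def __post_init__(self):
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("edge set must be acyclic")
        node_set = set(self.nodes)
        for tf, tgt in self.tf_pairs:
            if tf not in node_set or tgt not in node_set:
                raise ValueError(f"tf_pair ({tf}, {tgt}) references unknown node")
        anchors = [n for n, r in self.roles.items() if r == "anchor"]
        if len(anchors) != 1:
            raise ValueError("exactly one node must carry the anchor role")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g

    @property
    def anchor(self) -> str:
        return next(n for n, r in self.roles.items() if r == "anchor")

    def weight_matrix(self) -> pd.DataFrame:
        """Dense parent-by-child weight matrix (rows act on columns)."""
        w = pd.DataFrame(0.0, index=list(self.nodes), columns=list(self.nodes))
        for p, c, b in self.edges:
            w.loc[p, c] = b
        return w


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for one synthetic cohort."""

    n_samples: int
    seed: int
    label: str = "cohort"
    covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


def _gene_names(n: int) -> list:
    width = max(3, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_true_dag(
    n_nodes: int,
    mean_out_degree: float,
    n_tfs: int = 0,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> TrueNetwork:
    """Sample a random weighted DAG with one anchor and optional TF nodes.

    Nodes are placed in a random topological order; each forward pair is
    an edge independently with probability chosen so the expected edge
    count is ``n_nodes * mean_out_degree`` (a mean out-degree of
    ``mean_out_degree`` per node). Edge weights are uniform on
    +/-[0.5, 1.5] so no edge is near-unidentifiable.

    The anchor is the upstream-most node that has at least one
    descendant; ``n_tfs`` additional high-out-degree nodes are tagged as
    transcription factors and their out-edges exported as orientation
    priors.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if not 0 < mean_out_degree < n_nodes:
        raise ValueError("mean_out_degree must lie in (0, n_nodes)")
    if n_tfs < 0 or n_tfs >= n_nodes:
        raise ValueError("n_tfs must lie in [0, n_nodes)")

    rng = np.random.default_rng(seed)
    names = _gene_names(n_nodes)
    order = list(rng.permutation(names))

    # Expected total edges = n_nodes * mean_out_degree over the C(n,2)
    # ordered-forward pairs; per-pair probability follows.
    n_pairs = n_nodes * (n_nodes - 1) // 2
    target_edges = n_nodes * mean_out_degree
    p_edge = min(1.0, target_edges / n_pairs)

    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                w = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
                edges.append((order[i], order[j], float(w)))

    g = nx.DiGraph()
    g.add_nodes_from(names)
    g.add_edges_from((p, c) for p, c, _ in edges)

    # Anchor: the node with the largest descendant set (the master
    # regulator whose downstream program the pipeline dissects); ties
    # broken by sampled order. If the graph came out edgeless, wire the
    # first node to the second.
    n_desc = {node: len(nx.descendants(g, node)) for node in names}
    anchor = max(order, key=lambda node: n_desc[node])
    if n_desc[anchor] == 0:
        anchor, child = order[0], order[1]
        w = float(rng.uniform(0.5, 1.5))
        edges.append((anchor, child, w))
        g.add_edge(anchor, child)

    roles = {n: "other" for n in names}
    # TFs: the n_tfs non-anchor nodes with the largest out-degree (ties
    # broken by name for determinism).
    candidates = sorted(
        (n for n in names if n != anchor),
        key=lambda n: (-g.out_degree(n), n),
    )
    tfs = [n for n in candidates[:n_tfs] if g.out_degree(n) > 0]
    tf_pairs = []
    for tf in tfs:
        roles[tf] = "tf"
        for _, tgt in sorted(g.out_edges(tf)):
            tf_pairs.append((tf, tgt))
            if roles[tgt] == "other":
                roles[tgt] = "target"
    roles[anchor] = "anchor"

    return TrueNetwork(
        nodes=tuple(names),
        edges=tuple(edges),
        noise_sd=float(noise_sd),
        roles=roles,
        tf_pairs=tuple(tf_pairs),
    )


def _node_noise_sds(net: TrueNetwork, noise_mode: str) -> dict:
    """Per-node residual standard deviations for the chosen noise mode.

    ``fixed``: every node gets ``net.noise_sd`` (closed-form variance
    oracles hold exactly, but variance compounds multiplicatively with
    depth). ``snr``: a node with parents gets residual sd equal to
    ``noise_sd`` times the analytic sd of its parent contribution, so
    every regulated gene has a constant signal-to-noise ratio — the
    bounded, normalization-like variance profile of real expression
    data. Roots get ``noise_sd`` in both modes.
    """
    if noise_mode == "fixed":
        return {n: net.noise_sd for n in net.nodes}
    if noise_mode != "snr":
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    g = net.graph()
    names = list(net.nodes)
    idx = {n: i for i, n in enumerate(names)}
    cov = np.zeros((len(names), len(names)))
    sds = {}
    for node in nx.topological_sort(g):
        i = idx[node]
        ps = [(idx[p], g[p][node]["weight"]) for p in g.predecessors(node)]
        if not ps:
            sds[node] = net.noise_sd
            cov[i, i] = net.noise_sd**2
            continue
        pi = [a for a, _ in ps]
        w = np.array([b for _, b in ps])
        var_sig = float(w @ cov[np.ix_(pi, pi)] @ w)
        sd = net.noise_sd * math.sqrt(max(var_sig, 1e-12))
        sds[node] = sd
        # covariance of the new node with everything already placed
        cov[i, :] = w @ cov[pi, :]
        cov[:, i] = cov[i, :]
        cov[i, i] = var_sig + sd**2
    return sds


def _sem_sample(
    net: TrueNetwork,
    n_samples: int,
    rng: np.random.Generator,
    exo_shift: dict | None = None,
    noise_mode: str = "fixed",
) -> pd.DataFrame:
    """Sample the linear-Gaussian SEM in topological order.

    ``exo_shift`` maps node -> additive shift of that node's exogenous
    term (applied before propagation), the mechanism used for knockdown.
    Returns a gene-by-sample DataFrame.
    """
    g = net.graph()
    sds = _node_noise_sds(net, noise_mode)
    topo = list(nx.topological_sort(g))
    values = {}
    for node in topo:
        eps = rng.normal(0.0, sds[node], size=n_samples)
        if exo_shift and node in exo_shift:
            eps = eps + exo_shift[node]
        total = eps
        for parent in g.predecessors(node):
            total = total + g[parent][node]["weight"] * values[parent]
        values[node] = total
    mat = pd.DataFrame({n: values[n] for n in net.nodes}).T
    mat.columns = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    return mat


def simulate_cohort_expression(
    net: TrueNetwork, spec: CohortSpec, noise_mode: str = "fixed"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort from the SEM, plus sample annotations.

    Covariates are additive on every gene: each named covariate is a
    balanced 0/1 indicator over samples and contributes
    ``effect * indicator`` to all genes, emulating batch/age-style
    confounding that residualization must remove.

    Returns (expression gene-by-sample, annotations sample-by-covariate).
    """
    rng = np.random.default_rng(spec.seed)
    expr = _sem_sample(net, spec.n_samples, rng, noise_mode=noise_mode)
    expr.columns = [f"{spec.label}_{c}" for c in expr.columns]

    annot = pd.DataFrame(index=expr.columns)
    annot.index.name = "sample"
    annot["cohort"] = spec.label
    for cov, effect in spec.covariate_effects.items():
        half = spec.n_samples // 2
        indicator = np.zeros(spec.n_samples)
        indicator[half:] = 1.0
        annot[cov] = indicator
        expr = expr.add(effect * indicator, axis=1)
    return expr, annot


def simulate_knockdown_signature(
    net: TrueNetwork,
    target: str,
    delta: float,
    n_per_group: int,
    seed: int = 0,
    noise_mode: str = "fixed",
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group experiment: control vs knockdown of one gene.

    Knockdown subtracts ``delta`` from the target's exogenous term
    before propagation (an shRNA dose effect), so descendants shift by
    ``-delta`` times the summed path-weight product while the network's
    weights are untouched.

    Returns (expression gene-by-sample, group labels per sample with
    values "control"/"knockdown").
    """
    if target not in net.nodes:
        raise KeyError(f"unknown target gene {target!r}")
    rng = np.random.default_rng(seed)
    ctrl = _sem_sample(net, n_per_group, rng, noise_mode=noise_mode)
    ctrl.columns = [f"ctrl_{c}" for c in ctrl.columns]
    kd = _sem_sample(
        net, n_per_group, rng, exo_shift={target: -delta}, noise_mode=noise_mode
    )
    kd.columns = [f"kd_{c}" for c in kd.columns]
    expr = pd.concat([ctrl, kd], axis=1)
    groups = pd.Series(
        ["control"] * n_per_group + ["knockdown"] * n_per_group,
        index=expr.columns,
        name="group",
    )
    return expr, groups


def expected_knockdown_shift(net: TrueNetwork, target: str, delta: float) -> pd.Series:
    """Closed-form expected logFC (knockdown - control) per gene.

    The SEM is linear, so a shift of -delta on the target's exogenous
    term propagates as -delta * sum over directed paths of the product
    of edge weights. Used as the oracle for knockdown recovery tests.
    """
    w = net.weight_matrix().to_numpy()
    names = list(net.nodes)
    idx = names.index(target)
    # total effect = delta * (I - W)^-1 row of target (paths of all lengths)
    n = len(names)
    total = np.linalg.inv(np.eye(n) - w)
    shift = -delta * total[idx, :]
    return pd.Series(shift, index=names)


def simulate_survival_times(
    expression: pd.Series,
    true_hr: float,
    censor_frac: float,
    seed: int = 0,
    baseline_hazard: float = 0.1,
) -> pd.DataFrame:
    """Proportional-hazards event times tied to anchor expression.

    Event times are exponential with hazard ``lambda0 * true_hr**z``
    where z = 1 for samples above the median of ``expression`` and 0
    otherwise. Censoring is independent: each sample is censored with
    probability ``censor_frac``, at a uniform time before its event.

    Returns a DataFrame with columns (time, event, group, anchor_expr)
    indexed by sample.
    """
    if len(expression) == 0:
        raise ValueError("empty expression vector")
    if true_hr <= 0:
        raise ValueError("true_hr must be positive")
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    x = np.asarray(expression, dtype=float)
    med = np.median(x)
    z = (x > med).astype(int)
    lam = baseline_hazard * np.power(true_hr, z)
    t_event = rng.exponential(1.0 / lam)
    censored = rng.random(len(x)) < censor_frac
    t_cens = t_event * rng.random(len(x))
    time = np.where(censored, t_cens, t_event)
    event = (~censored).astype(int)
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "group": np.where(z == 1, "high", "low"),
            "anchor_expr": x,
        },
        index=expression.index,
    )


def simulate_drug_compendium(
    up: set,
    down: set,
    n_genes: int = 200,
    n_mimics: int = 1,
    n_reversers: int = 1,
    n_nulls: int = 10,
    concordance: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-by-instance fold-change compendium with planted profiles.

    Mimic instances place the query's up-genes at the top and down-genes
    at the bottom of the fold-change ranking (with the stated fraction
    of signature genes ``concordance`` planted; the rest left random);
    reversers invert the placement; nulls are fully random.

    Columns are named mimic_*/reverser_*/null_*. Gene universe is the
    signature plus filler genes up to ``n_genes``.
    """
    up, down = set(up), set(down)
    if not up and not down:
        raise ValueError("signature is empty")
    if up & down:
        raise ValueError("up and down sets overlap")
    if not 0 < concordance <= 1:
        raise ValueError("concordance must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    sig = sorted(up) + sorted(down)
    n_fill = max(0, n_genes - len(sig))
    filler = [f"F{i:04d}" for i in range(1, n_fill + 1)]
    genes = sig + filler
    n = len(genes)

    cols = {}

    def planted(direction: float) -> np.ndarray:
        vals = rng.normal(0.0, 1.0, size=n)
        scale = float(np.abs(vals).max()) + 1.0
        for gs, sign in ((up, 1.0), (down, -1.0)):
            members = sorted(gs)
            k = max(1, int(round(concordance * len(members)))) if members else 0
            chosen = rng.choice(len(members), size=k, replace=False) if k else []
            for ci in chosen:
                gi = genes.index(members[ci])
                # push beyond the random range so the gene lands at an extreme
                vals[gi] = direction * sign * (scale + rng.random())
        return vals

    for i in range(n_mimics):
        cols[f"mimic_{i+1}"] = planted(+1.0)
    for i in range(n_reversers):
        cols[f"reverser_{i+1}"] = planted(-1.0)
    for i in range(n_nulls):
        cols[f"null_{i+1}"] = rng.normal(0.0, 1.0, size=n)

    return pd.DataFrame(cols, index=genes)


def simulate_cna_segments(
    n_samples: int,
    gain_frac: float,
    tss: int,
    window: int = 2_000_000,
    chrom: str = "chr1",
    seed: int = 0,
) -> pd.DataFrame:
    """Copy-number segment table with a planted gain fraction.

    ``round(gain_frac * n_samples)`` samples receive a GAIN or AMP
    segment overlapping the closed window [tss - window, tss + window];
    the remainder receive either no segment or a distant neutral/LOSS
    segment. Coordinates are 1-based inclusive.
    """
    if not 0 <= gain_frac <= 1:
        raise ValueError("gain_frac must lie in [0, 1]")
    if tss < 1:
        raise ValueError("coordinates are 1-based; tss must be >= 1")

    rng = np.random.default_rng(seed)
    n_gain = int(round(gain_frac * n_samples))
    rows = []
    for i in range(n_samples):
        sample = f"S{i+1:04d}"
        if i < n_gain:
            start = max(1, tss - int(rng.integers(0, window)))
            end = tss + int(rng.integers(0, window))
            call = str(rng.choice(["GAIN", "AMP"]))
            rows.append((sample, chrom, start, end, call))
        else:
            # distant segment strictly outside the window, or none
            if rng.random() < 0.5:
                start = tss + window + 1 + int(rng.integers(0, 10 * window))
                end = start + int(rng.integers(1000, window))
                call = str(rng.choice(["LOSS", "NEUT"]))
                rows.append((sample, chrom, start, end, call))
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "call"]
    )
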