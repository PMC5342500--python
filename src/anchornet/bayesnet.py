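"""Score-based Bayesian-network structure learning by MCMC consensus.

Structures over continuous expression are scored with a decomposable
Gaussian BIC: each node contributes the maximized log-likelihood of its
linear regression on its parents minus (k/2) log n. A uniform structure
prior is used, so the Metropolis ratio reduces to the score difference.

Because a uniform prior cannot break Markov equivalence, known
TF-target pairs constrain orientation: a TF may be a parent of its
target but the target may never be a parent of its TF (the reverse
edges are banned outright).

Many chains are run from independent random initial structures; each
chain's final structure is one network sample. Edges present in more
than a support-fraction threshold of the chains (strictly more than
30% by default) define the consensus network; any remaining directed
cycle is broken by deleting the weakest-supported edge on the cycle.
Per-cohort consensus networks are combined into a super network by the
union of directed edges (support = max across cohorts, provenance
kept), with cycles removed again.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PriorConstraints",
    "ChainConfig",
    "ConsensusNetwork",
    "gaussian_bic_score",
    "mcmc_chain",
    "learn_chains",
    "consensus_network",
    "break_cycles",
    "union_networks",
    "precision_recall",
]


@dataclass(frozen=True)
class PriorConstraints:
    """TF orientation priors: targets may not parent their TFs."""

    tf_pairs: frozenset = frozenset()

    @property
    def banned_edges(self) -> frozenset:
        return frozenset((tgt, tf) for tf, tgt in self.tf_pairs)

    @classmethod
    def from_pairs(cls, pairs) -> "PriorConstraints":
        return cls(tf_pairs=frozenset((str(a), str(b)) for a, b in pairs))


@dataclass(frozen=True)
class ChainConfig:
    """MCMC settings. Production default is 1000 chains; tests use ~50.

    Each chain anneals the Metropolis acceptance temperature
    geometrically from ``t_initial`` to ``t_final`` over ``n_iter``
    proposals, so early iterations explore broadly and the final phase
    quenches into a local mode; ``t_initial == t_final == 1`` recovers
    plain fixed-temperature Metropolis. The chain's sample is its
    final-iteration structure, so ``burn_in`` is retained only for
    config compatibility.
    """

    n_chains: int = 1000
    n_iter: int = 20000
    burn_in: int = 0
    seed: int = 0
    max_parents: int = 3
    t_initial: float = 500.0
    t_final: float = 0.05

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must lie in [0, n_iter)")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.t_initial < self.t_final or self.t_final <= 0:
            raise ValueError("need t_initial >= t_final > 0")


@dataclass(frozen=True)
class ConsensusNetwork:
    """Directed edges with chain-support fractions; acyclic."""

    support: dict          # (parent, child) -> fraction in (threshold, 1]
    threshold: float
    nodes: tuple
    cohorts: dict = field(default_factory=dict)   # (parent, child) -> tuple of labels
    removed: tuple = ()    # edges deleted by cycle breaking

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (p, c), s in self.support.items():
            g.add_edge(p, c, support=s)
        return g

    @property
    def edges(self) -> set:
        return set(self.support)


class _NodeScorer:
    """Cached Gaussian-BIC node terms from the centered scatter matrix.

    For node y with parent set P the maximized Gaussian log-likelihood
    is -n/2 (log(2 pi sigma2_hat) + 1) with sigma2_hat = RSS/n, and
    RSS = S_yy - S_yP S_PP^{-1} S_Py computed from the centered scatter
    S = Xc' Xc — identical to per-sample OLS but O(|P|^3) per query.
    Penalty: (k/2) log n with k = |P| + 2 (coefficients, intercept,
    variance).
    """

    def __init__(self, data: pd.DataFrame, ridge: float = 1e-8):
        # data: genes x samples
        x = data.to_numpy(dtype=float).T
        self.n = x.shape[0]
        xc = x - x.mean(axis=0)
        self.scatter = xc.T @ xc
        self.genes = list(data.index)
        self.ridge = ridge
        self._cache: dict = {}
        if self.n < 3:
            raise ValueError("need >= 3 samples")

    def node_term(self, child: int, parents: tuple) -> float:
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        s = self.scatter
        syy = s[child, child]
        if parents:
            p = list(parents)
            spp = s[np.ix_(p, p)]
            spy = s[p, child]
            try:
                sol = np.linalg.solve(spp, spy)
            except np.linalg.LinAlgError:
                warnings.warn("singular parent design; ridge fallback")
                sol = np.linalg.solve(
                    spp + self.ridge * np.eye(len(p)), spy
                )
            rss = syy - spy @ sol
        else:
            rss = syy
        rss = max(rss, 1e-12)
        n = self.n
        sigma2 = rss / n
        ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        k = len(parents) + 2
        term = ll - 0.5 * k * math.log(n)
        self._cache[key] = term
        return term


def gaussian_bic_score(dag: nx.DiGraph, data: pd.DataFrame) -> float:
    """Decomposable Gaussian BIC of a DAG on gene-by-sample data."""
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("structure must be acyclic")
    scorer = _NodeScorer(data)
    idx = {g: i for i, g in enumerate(scorer.genes)}
    n_params = sum(dag.in_degree(n) + 2 for n in data.index)
    if scorer.n < 3 * n_params / max(1, len(data.index)):
        warnings.warn("few samples per free parameter; scores may be unstable")
    total = 0.0
    for node in data.index:
        parents = tuple(sorted(idx[p] for p in dag.predecessors(node)))
        total += scorer.node_term(idx[node], parents)
    return total


def _reachable(children: list, src: int, dst: int) -> bool:
    """True if dst is reachable from src by directed edges."""
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        for v in children[u]:
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def mcmc_chain(
    scorer: _NodeScorer,
    banned: set,
    config: ChainConfig,
    chain_seed: int,
) -> frozenset:
    """One annealed Metropolis chain over DAGs; returns the final edge set.

    Proposal kernel: draw a random ordered node pair (i, j); if edge
    i->j exists, propose delete or reverse with equal probability,
    otherwise propose add or stay. The kernel is symmetric (an add at
    (i, j) and the matching delete are proposed with equal probability,
    as are the two reversals), so the proposal ratio is identically 1
    and acceptance uses the bare score difference, divided by the
    current annealing temperature. Proposals creating a cycle, adding a
    banned edge, or exceeding max_parents are rejected outright.

    Chains start from the empty graph; chain-to-chain randomness comes
    from the seeded proposal stream, and the high-temperature phase
    randomizes the early trajectory (the practical equivalent of a
    random initial structure, without seeding the chain with arbitrary
    wrong edges it must then escape).
    """
    rng = np.random.default_rng(chain_seed)
    p = len(scorer.genes)
    parents = [set() for _ in range(p)]
    children = [set() for _ in range(p)]

    node_terms = [
        scorer.node_term(v, tuple(sorted(parents[v]))) for v in range(p)
    ]

    def term(v, ps):
        return scorer.node_term(v, tuple(sorted(ps)))

    t = config.t_initial
    ratio = (config.t_final / config.t_initial) ** (
        1.0 / max(1, config.n_iter - 1)
    )
    for _ in range(config.n_iter):
        t *= ratio
        i = int(rng.integers(p))
        j = int(rng.integers(p - 1))
        if j >= i:
            j += 1
        coin = rng.random() < 0.5
        if i in parents[j]:
            if coin:
                # delete i -> j
                new_j = term(j, parents[j] - {i})
                delta = new_j - node_terms[j]
                if delta >= 0 or rng.random() < math.exp(delta / t):
                    parents[j].discard(i)
                    children[i].discard(j)
                    node_terms[j] = new_j
            else:
                # reverse i -> j to j -> i
                if (j, i) in banned or len(parents[i]) >= config.max_parents:
                    continue
                children[i].discard(j)
                if _reachable(children, i, j):  # other path i..j: cycle
                    children[i].add(j)
                    continue
                children[i].add(j)
                new_j = term(j, parents[j] - {i})
                new_i = term(i, parents[i] | {j})
                delta = (new_i - node_terms[i]) + (new_j - node_terms[j])
                if delta >= 0 or rng.random() < math.exp(delta / t):
                    parents[j].discard(i)
                    children[i].discard(j)
                    parents[i].add(j)
                    children[j].add(i)
                    node_terms[i], node_terms[j] = new_i, new_j
        else:
            if not coin:
                continue
            # add i -> j
            if (i, j) in banned or len(parents[j]) >= config.max_parents:
                continue
            if _reachable(children, j, i):
                continue
            new_j = term(j, parents[j] | {i})
            delta = new_j - node_terms[j]
            if delta >= 0 or rng.random() < math.exp(delta / t):
                parents[j].add(i)
                children[i].add(j)
                node_terms[j] = new_j

    genes = scorer.genes
    return frozenset(
        (genes[i], genes[j]) for j in range(p) for i in parents[j]
    )


def learn_chains(
    data: pd.DataFrame,
    constraints: PriorConstraints | None = None,
    config: ChainConfig = ChainConfig(),
) -> list[frozenset]:
    """Run config.n_chains independent chains; one edge set per chain."""
    constraints = constraints or PriorConstraints()
    scorer = _NodeScorer(data)
    idx = {g: i for i, g in enumerate(scorer.genes)}
    for a, b in constraints.tf_pairs:
        if a not in idx or b not in idx:
            raise ValueError(f"constraint gene ({a}, {b}) not in data")
    banned = {(idx[a], idx[b]) for a, b in constraints.banned_edges}
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_chains)
    return [
        mcmc_chain(scorer, banned, config, int(s) % (2**31))
        for s in seeds
    ]


def consensus_network(
    chains: list[frozenset],
    threshold: float = 0.3,
    nodes: tuple | None = None,
) -> ConsensusNetwork:
    """Average chains into a consensus: keep edges with support > threshold."""
    if not chains:
        raise ValueError("need >= 1 chain")
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    counts: dict = {}
    for ch in chains:
        for e in ch:
            counts[e] = counts.get(e, 0) + 1
    n = len(chains)
    support = {e: c / n for e, c in counts.items() if c / n > threshold}
    if nodes is None:
        node_set = set()
        for e in support:
            node_set.update(e)
        nodes = tuple(sorted(node_set))
    support, removed = break_cycles(support)
    return ConsensusNetwork(
        support=support, threshold=threshold, nodes=tuple(nodes), removed=removed
    )


def _find_cycle(support: dict) -> list | None:
    """Deterministic DFS cycle search: smallest nodes first.

    Returns the cycle as a list of edges, or None.
    """
    adj: dict = {}
    for p, c in support:
        adj.setdefault(p, []).append(c)
    for k in adj:
        adj[k].sort()
    color: dict = {}
    stack_edges: list = []

    def dfs(u):
        color[u] = 1
        for v in adj.get(u, ()):
            if color.get(v, 0) == 1:
                # back edge: extract cycle from stack
                cyc = [(u, v)]
                for e in reversed(stack_edges):
                    cyc.append(e)
                    if e[0] == v:
                        break
                cyc.reverse()
                return cyc
            if color.get(v, 0) == 0:
                stack_edges.append((u, v))
                found = dfs(v)
                stack_edges.pop()
                if found:
                    return found
        color[u] = 2
        return None

    for node in sorted(adj):
        if color.get(node, 0) == 0:
            found = dfs(node)
            if found:
                return found
    return None


def break_cycles(support: dict) -> tuple[dict, tuple]:
    """Delete the weakest-supported edge of each directed cycle.

    Repeats until acyclic; ties on support are broken by the
    lexicographically smallest (parent, child). Returns (acyclic
    support dict, tuple of removed edges). Terminates because every
    step removes one edge.
    """
    support = dict(support)
    removed = []
    while True:
        cyc = _find_cycle(support)
        if cyc is None:
            break
        victim = min(cyc, key=lambda e: (support[e], e))
        del support[victim]
        removed.append(victim)
    return support, tuple(removed)


def union_networks(
    networks: list[ConsensusNetwork], labels: list[str] | None = None
) -> ConsensusNetwork:
    """Union of directed edges across cohorts; support = max; cycles removed."""
    if not networks:
        raise ValueError("need >= 1 network")
    labels = labels or [f"cohort{i+1}" for i in range(len(networks))]
    support: dict = {}
    cohorts: dict = {}
    nodes: set = set()
    for net, lab in zip(networks, labels):
        nodes.update(net.nodes)
        for e, s in net.support.items():
            support[e] = max(support.get(e, 0.0), s)
            cohorts[e] = tuple(list(cohorts.get(e, ())) + [lab])
    support, removed = break_cycles(support)
    cohorts = {e: c for e, c in cohorts.items() if e in support}
    return ConsensusNetwork(
        support=support,
        threshold=min(n.threshold for n in networks),
        nodes=tuple(sorted(nodes)),
        cohorts=cohorts,
        removed=removed,
    )


def precision_recall(net: ConsensusNetwork, true_edges: set) -> dict:
    """Directed-edge precision/recall of a consensus vs ground truth."""
    found = net.edges
    true_edges = {(p, c) for p, c in true_edges}
    tp = len(found & true_edges)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(true_edges) if true_edges else 0.0
    return {"precision": precision, "recall": recall, "tp": tp, "n_found": len(found)}
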