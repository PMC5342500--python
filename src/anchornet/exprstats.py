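"""Differential expression, meta-analysis, signatures, and enrichment.

Two-group differential expression uses a plain two-sample t-test
(Welch by default) with Benjamini-Hochberg adjustment across genes;
cross-cohort evidence is combined by summing -log10 p-values; consensus
signatures apply an FDR + linear fold-change cutoff with a minimum
support count across independent perturbations; gene-set overlaps are
tested with a one-sided Fisher exact test (fold enrichment
k*N / (n_a*n_b)) or, for three or more sets, a seeded Monte Carlo
intersection test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSignature",
    "bh_adjust",
    "residualize_covariates",
    "differential_expression",
    "meta_combine",
    "consensus_signature",
    "correlate_anchor",
    "fisher_enrichment",
    "multiset_intersection_test",
    "cna_gain_fraction",
    "compare_overlap_distributions",
]


@dataclass(frozen=True)
class GeneSignature:
    """Up/down gene sets with the thresholds that produced them."""

    up: frozenset
    down: frozenset
    fdr_cutoff: float = 0.05
    fc_cutoff: float = 1.3
    min_support: int = 2

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must exceed 1 (linear scale)")


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (order-preserving)."""
    arr = np.asarray(p, dtype=float)
    return multipletests(arr, method="fdr_bh")[1]


def residualize_covariates(
    matrix: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Remove covariate effects gene-wise by OLS, keeping grand means.

    ``matrix`` is gene-by-sample; ``covariates`` is sample-by-covariate
    and must align with the matrix columns. Constant covariate columns
    are dropped with a warning. Per gene, the OLS residual plus the
    gene's grand mean is returned.
    """
    cov = covariates.reindex(matrix.columns)
    if cov.isna().any().any():
        raise ValueError("covariate rows do not align with samples")
    cov = cov.select_dtypes(include=[np.number])
    keep = []
    for c in cov.columns:
        if np.ptp(cov[c].to_numpy()) == 0:
            warnings.warn(f"dropping constant covariate column {c!r}")
        else:
            keep.append(c)
    x = cov[keep].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(cov)), x]) if keep else np.ones((len(cov), 1))
    # rank-deficiency: lstsq handles it; warn when detected
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("covariate design is rank-deficient; using least-norm fit")
    y = matrix.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    out = resid.T + matrix.mean(axis=1).to_numpy()[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def differential_expression(
    matrix: pd.DataFrame,
    group_a: list,
    group_b: list,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test between sample groups a and b.

    logFC = mean(a) - mean(b), with the matrix assumed on log2 scale.
    ``equal_var=False`` (default) gives Welch's test; True gives the
    pooled-variance Student test. Genes with zero variance in both
    groups get p = 1 and ``degenerate=True``. BH adjustment is applied
    across all genes.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p = np.nan_to_num(p, nan=1.0)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "t_stat": t,
            "p": p,
            "fdr": bh_adjust(p),
            "degenerate": degenerate,
        },
        index=matrix.index,
    )


_TINY = np.finfo(float).tiny


def meta_combine(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-cohort differential results by summing -log10 p.

    ``tables`` maps cohort label -> DataFrame with columns (p, logFC)
    indexed by gene. Genes are scored on the cohorts where they appear;
    p = 0 is clamped to the smallest positive float with a warning.
    Returns a DataFrame (score, n_cohorts, discordant) sorted by score
    descending; ``discordant`` flags genes whose logFC signs disagree
    across cohorts.
    """
    genes = sorted(set().union(*(set(t.index) for t in tables.values())))
    score = pd.Series(0.0, index=genes)
    n_cohorts = pd.Series(0, index=genes)
    signs = {g: set() for g in genes}
    for label, tab in tables.items():
        p = tab["p"].astype(float)
        if (p <= 0).any():
            warnings.warn(f"cohort {label!r}: p = 0 clamped to tiny")
            p = p.clip(lower=_TINY)
        if (p > 1).any():
            raise ValueError(f"cohort {label!r}: p-values above 1")
        contrib = -np.log10(p)
        score.loc[p.index] += contrib
        n_cohorts.loc[p.index] += 1
        if "logFC" in tab:
            for g, fc in tab["logFC"].items():
                if fc != 0:
                    signs[g].add(np.sign(fc))
    out = pd.DataFrame(
        {
            "score": score,
            "n_cohorts": n_cohorts,
            "discordant": [len(signs[g]) > 1 for g in genes],
        },
        index=genes,
    )
    return out.sort_values("score", ascending=False)


def consensus_signature(
    results: list[pd.DataFrame],
    fdr_cutoff: float = 0.05,
    fc_cutoff: float = 1.3,
    min_support: int = 2,
) -> GeneSignature:
    """Genes passing FDR and fold-change cuts in >= min_support tables.

    A gene enters the up (down) set iff it shows fdr < fdr_cutoff,
    linear fold change above ``fc_cutoff`` (i.e. |logFC| > log2(fc_cutoff))
    and positive (negative) logFC in at least ``min_support`` of the
    supplied tables; the two directions are tallied independently.
    """
    if min_support > len(results):
        raise ValueError("min_support exceeds the number of result tables")
    log_cut = np.log2(fc_cutoff)
    up_votes: dict = {}
    dn_votes: dict = {}
    for tab in results:
        hit = (tab["fdr"] < fdr_cutoff) & (tab["logFC"].abs() > log_cut)
        for g in tab.index[hit & (tab["logFC"] > 0)]:
            up_votes[g] = up_votes.get(g, 0) + 1
        for g in tab.index[hit & (tab["logFC"] < 0)]:
            dn_votes[g] = dn_votes.get(g, 0) + 1
    # direction conflicts (possible when min_support <= half the tables):
    # keep the direction with the strictly larger vote count; drop ties.
    up = frozenset(
        g for g, v in up_votes.items()
        if v >= min_support and v > dn_votes.get(g, 0)
    )
    down = frozenset(
        g for g, v in dn_votes.items()
        if v >= min_support and v > up_votes.get(g, 0)
    )
    return GeneSignature(up, down, fdr_cutoff, fc_cutoff, min_support)


def correlate_anchor(
    matrix: pd.DataFrame,
    anchor: str,
    rho_cutoff: float = 0.2,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of every gene with the anchor gene.

    The anchor itself is excluded; constant genes are excluded with a
    flag column. ``passes`` requires fdr < fdr_cutoff and |rho| strictly
    above ``rho_cutoff``.
    """
    if anchor not in matrix.index:
        raise KeyError(f"anchor {anchor!r} not in matrix")
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    x = matrix.loc[anchor].to_numpy(dtype=float)
    rows = []
    for gene, vals in matrix.iterrows():
        if gene == anchor:
            continue
        v = vals.to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(x) == 0:
            rows.append((gene, np.nan, np.nan, True))
            continue
        rho, p = stats.spearmanr(x, v)
        rows.append((gene, rho, p, False))
    out = pd.DataFrame(rows, columns=["gene", "rho", "p", "constant"]).set_index(
        "gene"
    )
    ok = ~out["constant"]
    fdr = pd.Series(np.nan, index=out.index)
    if ok.any():
        fdr[ok] = bh_adjust(out.loc[ok, "p"])
    out["fdr"] = fdr
    out["passes"] = ok & (out["fdr"] < fdr_cutoff) & (out["rho"].abs() > rho_cutoff)
    return out


def fisher_enrichment(set_a: set, set_b: set, universe: set) -> dict:
    """One-sided Fisher exact test for over-representation.

    Returns a dict with overlap, sizes, universe size, p (hypergeometric
    upper tail), fold_enrichment = k*N/(n_a*n_b), and the odds ratio of
    the 2x2 table.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a or not set_b:
        raise ValueError("enrichment is undefined for empty sets")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    n_a, n_b = len(set_a), len(set_b)
    k = len(set_a & set_b)
    # P(X >= k) for X ~ Hypergeom(N, n_a, n_b)
    p = float(stats.hypergeom.sf(k - 1, n, n_a, n_b))
    table = [[k, n_a - k], [n_b - k, n - n_a - n_b + k]]
    odds, _ = stats.fisher_exact(table, alternative="greater")
    return {
        "overlap": k,
        "size_a": n_a,
        "size_b": n_b,
        "universe": n,
        "p": min(p, 1.0),
        "fold_enrichment": k * n / (n_a * n_b),
        "odds_ratio": float(odds),
    }


def multiset_intersection_test(
    sets: list[set],
    universe: set,
    n_mc: int = 10_000,
    seed: int = 0,
) -> dict:
    """P(intersection >= observed) under independent uniform draws.

    Exact hypergeometric tail for two sets; seeded Monte Carlo for three
    or more. Returns dict(observed, p, method).
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    if n_mc < 100:
        raise ValueError("n_mc must be >= 100")
    universe = set(universe)
    sets = [set(s) for s in sets]
    for s in sets:
        if not s <= universe:
            raise ValueError("all sets must be subsets of the universe")
    observed = len(set.intersection(*sets))
    n = len(universe)
    if len(sets) == 2:
        p = float(stats.hypergeom.sf(observed - 1, n, len(sets[0]), len(sets[1])))
        return {"observed": observed, "p": min(p, 1.0), "method": "hypergeometric"}
    rng = np.random.default_rng(seed)
    sizes = [len(s) for s in sets]
    hits = 0
    uni = np.arange(n)
    for _ in range(n_mc):
        inter = None
        for sz in sizes:
            draw = set(rng.choice(uni, size=sz, replace=False))
            inter = draw if inter is None else inter & draw
            if not inter:
                break
        if len(inter or ()) >= observed:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    return {"observed": observed, "p": p, "method": "monte-carlo"}


def cna_gain_fraction(
    segments: pd.DataFrame,
    tss: int,
    window: int = 2_000_000,
    n_total: int | None = None,
) -> dict:
    """Fraction of samples with a GAIN/AMP segment near the TSS.

    A sample counts if any of its GAIN or AMP segments intersects the
    closed interval [tss - window, tss + window] (1-based inclusive
    coordinates on both sides). ``n_total`` defaults to the number of
    distinct samples in the table. Malformed rows are skipped with a
    warning.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo, hi = tss - window, tss + window
    gained = set()
    samples = set()
    for _, row in segments.iterrows():
        try:
            s, start, end, call = (
                row["sample"],
                int(row["start"]),
                int(row["end"]),
                str(row["call"]).upper(),
            )
        except (KeyError, TypeError, ValueError):
            warnings.warn(f"skipping malformed segment row {tuple(row)!r}")
            continue
        samples.add(s)
        if call in ("GAIN", "AMP") and start <= hi and end >= lo:
            gained.add(s)
    total = n_total if n_total is not None else len(samples)
    frac = len(gained) / total if total else 0.0
    return {"fraction": frac, "n_gain": len(gained), "n_total": total}


def compare_overlap_distributions(
    scores_a, scores_b
) -> dict:
    """Two-sample Kolmogorov-Smirnov test between score distributions."""
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return {"D": float(res.statistic), "p": float(res.pvalue)}
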