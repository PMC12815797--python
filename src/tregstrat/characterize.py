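"""Immune and molecular characterization of sample clusters.

Statistics offered here are the generic building blocks used to profile
each cluster against the rest of the cohort:

* per-sample gene-signature scores (mean z-score, or a rank-based
  single-sample alternative);
* one-vs-rest gene ranking (signal-to-noise or log2 fold change);
* gene set enrichment analysis (GSEA): weighted Kolmogorov–Smirnov
  running sum over a ranked list, with a gene-set membership permutation
  null, sign-matched NES, and Benjamini–Hochberg FDR across sets;
* over-representation analysis (ORA): hypergeometric upper-tail test;
* nonparametric group comparisons: Kruskal–Wallis, Dunn's post-hoc
  pairwise z-tests on mean ranks, and pairwise Wilcoxon rank-sum;
* a T-cell exhaustion panel linking Treg signature scores to exhaustion
  marker expression per cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import EXHAUSTION_MARKERS, TREG_GENES


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        genes = [g.upper() for g in self.genes]
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")
        self.genes = genes


TREG_SIGNATURE = GeneSet("TREG_SIGNATURE", list(TREG_GENES))
EXHAUSTION_PANEL = GeneSet("EXHAUSTION_PANEL", list(EXHAUSTION_MARKERS))


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float | None
    p: float | None
    fdr_q: float | None
    n_perm: int
    leading_edge: list[str] = field(default_factory=list)


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p, p_adj per test


# ------------------------------------------------------------- signatures

def _zscore_columns(expr: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score; zero-variance columns map to all-zero."""
    mu = expr.mean(axis=0)
    sd = expr.std(axis=0, ddof=1)
    z = (expr - mu).div(sd.where(sd > 0, 1.0), axis=1)
    z.loc[:, ~(sd > 0)] = 0.0
    return z


def signature_score(
    expr: pd.DataFrame, geneset: GeneSet, method: str = "mean_z"
) -> pd.Series:
    """Per-sample score for one gene set on a samples-by-genes matrix."""
    if expr.isna().to_numpy().any():
        raise ValueError("expression matrix has missing entries; impute first")
    present = [g for g in geneset.genes if g in expr.columns]
    absent = sorted(set(geneset.genes) - set(present))
    if not present:
        raise ValueError(
            f"no genes of set {geneset.name!r} found in the expression matrix "
            f"(set: {geneset.genes})"
        )
    if absent:
        warnings.warn(
            f"set {geneset.name!r}: {len(absent)} genes absent from the "
            f"matrix and skipped: {absent}",
            stacklevel=2,
        )
    if method == "mean_z":
        scores = _zscore_columns(expr[present]).mean(axis=1)
    elif method == "ssgsea_like":
        scores = _ssgsea_like(expr, present)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    return scores.rename(f"{geneset.name}_score")


def _ssgsea_like(expr: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Rank-weighted running-sum score per sample (single-sample enrichment)."""
    n_genes = expr.shape[1]
    member = expr.columns.isin(genes)
    out = np.empty(expr.shape[0])
    ranks = stats.rankdata(expr.to_numpy(dtype=float), axis=1)  # high expr = high rank
    for i in range(expr.shape[0]):
        order = np.argsort(-ranks[i], kind="stable")
        m = member[order]
        w = ranks[i][order] ** 0.75
        hit = np.where(m, w / w[m].sum(), 0.0)
        miss = np.where(~m, 1.0 / (n_genes - m.sum()), 0.0)
        running = np.cumsum(hit - miss)
        out[i] = running.sum() / n_genes  # area-style statistic
    return pd.Series(out, index=expr.index)


# ---------------------------------------------------------- gene ranking

def as_ranked(scores: pd.Series, metric: str = "score") -> pd.Series:
    """Descending sort with deterministic lexicographic tie-break on gene id."""
    df = pd.DataFrame({"score": scores.astype(float), "gene": scores.index.astype(str)})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    out = pd.Series(df["score"].to_numpy(), index=df["gene"].to_numpy(), name=metric)
    return out


def rank_genes(
    expr: pd.DataFrame,
    labels,
    cluster,
    metric: str = "signal_to_noise",
) -> pd.Series:
    """One-vs-rest per-gene ranking statistic for a cluster.

    signal_to_noise = (mu1 - mu0) / (sd1 + sd0), with each group's SD
    floored at max(0.2 * |group mean|, 1e-8) — the classical GSEA
    convention that keeps near-constant genes from exploding the ratio.
    """
    labels = np.asarray(labels)
    in_c = labels == cluster
    if in_c.sum() == 0:
        raise ValueError(f"cluster {cluster!r} not present in labels")
    if in_c.sum() < 2 or (~in_c).sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    A = expr.loc[in_c]
    B = expr.loc[~in_c]
    mu1, mu0 = A.mean(axis=0), B.mean(axis=0)
    if metric == "signal_to_noise":
        sd1 = np.maximum(A.std(axis=0, ddof=1), np.maximum(0.2 * mu1.abs(), 1e-8))
        sd0 = np.maximum(B.std(axis=0, ddof=1), np.maximum(0.2 * mu0.abs(), 1e-8))
        stat = (mu1 - mu0) / (sd1 + sd0)
    elif metric == "log2fc":
        if (mu1 < 0).any() or (mu0 < 0).any():
            raise ValueError("log2fc requires nonnegative group means")
        eps = 1e-9
        stat = np.log2((mu1 + eps) / (mu0 + eps))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # genes identical across groups get an exact 0
    stat = stat.where(mu1 != mu0, 0.0) if metric == "signal_to_noise" else stat
    return as_ranked(stat, metric=metric)


# ----------------------------------------------------------------- GSEA

def _running_es(
    member: np.ndarray, scores: np.ndarray, weight: float
) -> tuple[float, int]:
    """ES of a membership mask over a descending-ranked score vector.

    Returns (ES, extremum position).  Hit increments are proportional to
    |score|^weight normalized to sum 1; misses decrement 1/(N - Nh).
    """
    n = member.size
    nh = int(member.sum())
    if nh == 0:
        raise ValueError("gene set has no members in the ranked list")
    if nh == n:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(scores) ** weight if weight != 0 else np.ones(n)
    hit_w = np.where(member, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member scores exactly 0 under weight > 0
        hit_w = member.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - np.where(member, 0.0, 1.0 / (n - nh))
    running = np.cumsum(steps)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), pos


def gsea(
    ranked: pd.Series,
    geneset: GeneSet,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> EnrichmentResult:
    """GSEA for a single set; permutation null over set memberships."""
    ranked = as_ranked(ranked)
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    wanted = {g.upper() for g in geneset.genes}
    member = np.array([str(g).upper() in wanted for g in genes])
    es, pos = _running_es(member, scores, weight)

    if es >= 0:
        leading = [g for g in genes[: pos + 1] if str(g).upper() in wanted]
    else:
        leading = [g for g in genes[pos:] if str(g).upper() in wanted]

    if n_perm == 0:
        return EnrichmentResult(
            set_name=geneset.name, es=es, nes=None, p=None, fdr_q=None,
            n_perm=0, leading_edge=leading,
        )
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for p-values (or 0 for ES only)")

    nh = int(member.sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    mask = np.zeros(genes.size, dtype=bool)
    for i in range(n_perm):
        mask[:] = False
        mask[rng.choice(genes.size, size=nh, replace=False)] = True
        null[i], _ = _running_es(mask, scores, weight)

    same_sign = null * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
    n_same = int(same_sign.sum())
    if n_same:
        nes = es / np.abs(null[same_sign]).mean()
        p = (1 + int((np.abs(null[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    else:  # no null ES of matching sign: maximally significant
        nes = es / max(np.abs(null).mean(), 1e-12)
        p = 1.0 / (1 + n_perm)
    return EnrichmentResult(
        set_name=geneset.name, es=es, nes=float(nes), p=float(p), fdr_q=float(p),
        n_perm=n_perm, leading_edge=leading,
    )


def gsea_collection(
    ranked: pd.Series,
    genesets: list[GeneSet] | dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """GSEA over several sets with BH FDR computed across them."""
    if isinstance(genesets, dict):
        genesets = [GeneSet(name, genes) for name, genes in genesets.items()]
    results = [
        gsea(ranked, gs, n_perm=n_perm, weight=weight, seed=seed + i)
        for i, gs in enumerate(genesets)
    ]
    pvals = [r.p for r in results]
    if all(p is not None for p in pvals):
        _, q, _, _ = multipletests(pvals, method="fdr_bh")
        for r, qi in zip(results, q):
            r.fdr_q = float(qi)
    return results


# ------------------------------------------------------------------- ORA

def ora(hits: list[str], universe: list[str], geneset: GeneSet) -> float:
    """Hypergeometric upper-tail p for overlap >= observed."""
    hits_s = {str(h).upper() for h in hits}
    universe_s = {str(u).upper() for u in universe}
    if not hits_s <= universe_s:
        extra = sorted(hits_s - universe_s)[:5]
        raise ValueError(f"hits not contained in the universe (e.g. {extra})")
    set_in_universe = set(geneset.genes) & universe_s
    if not set_in_universe:
        raise ValueError(
            f"gene set {geneset.name!r} has no overlap with the universe"
        )
    N = len(universe_s)
    K = len(set_in_universe)
    n = len(hits_s)
    k = len(hits_s & set_in_universe)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora_collection(
    hits: list[str], universe: list[str],
    genesets: list[GeneSet] | dict[str, list[str]],
) -> pd.DataFrame:
    """ORA over several sets; returns set, overlap, p, fdr_q."""
    if isinstance(genesets, dict):
        genesets = [GeneSet(name, genes) for name, genes in genesets.items()]
    rows = []
    hits_s = {str(h).upper() for h in hits}
    for gs in genesets:
        p = ora(hits, universe, gs)
        rows.append(
            {"set": gs.name, "overlap": len(hits_s & set(gs.genes)), "p": p}
        )
    df = pd.DataFrame(rows)
    _, q, _, _ = multipletests(df["p"], method="fdr_bh")
    df["fdr_q"] = q
    return df


# ----------------------------------------------------------- group tests

def _dunn_pairwise(values: np.ndarray, groups: np.ndarray, adjust: str) -> pd.DataFrame:
    """Dunn's post-hoc z-tests on mean ranks with tie correction."""
    N = values.size
    ranks = stats.rankdata(values)
    uniq = list(pd.unique(groups))
    mean_rank = {g: ranks[groups == g].mean() for g in uniq}
    n_of = {g: int((groups == g).sum()) for g in uniq}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    rows = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / n_of[a] + 1.0 / n_of[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    method = "bonferroni" if adjust == "bonferroni" else "fdr_bh"
    _, padj, _, _ = multipletests(df["p"], method=method)
    df["p_adj"] = padj
    return df


def group_tests(values, labels, adjust: str = "bonferroni") -> GroupTestResult:
    """Kruskal–Wallis across clusters + Dunn and pairwise Wilcoxon post-hocs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(labels)
    uniq = list(pd.unique(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if any((groups == g).sum() < 2 for g in uniq):
        raise ValueError("every group needs at least 2 samples")

    if np.all(values == values[0]):
        H, p = 0.0, 1.0
        dunn = _dunn_pairwise(values, groups, adjust)
    else:
        H, p = stats.kruskal(*[values[groups == g] for g in uniq])
        dunn = _dunn_pairwise(values, groups, adjust)
    dunn["test"] = "dunn"

    wil_rows = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            va, vb = values[groups == a], values[groups == b]
            if np.all(np.concatenate([va, vb]) == va[0]):
                u, pw = float(len(va) * len(vb) / 2.0), 1.0
            else:
                u, pw = stats.mannwhitneyu(va, vb, alternative="two-sided")
            wil_rows.append({"group_a": a, "group_b": b, "z": u, "p": pw})
    wil = pd.DataFrame(wil_rows)
    method = "bonferroni" if adjust == "bonferroni" else "fdr_bh"
    _, padj, _, _ = multipletests(wil["p"], method=method)
    wil["p_adj"] = padj
    wil["test"] = "wilcoxon"

    pairwise = pd.concat([dunn, wil], ignore_index=True)
    return GroupTestResult(
        test="kruskal_wallis", statistic=float(H), p=float(p), pairwise=pairwise
    )


# ------------------------------------------------------- exhaustion panel

def exhaustion_panel(
    expr: pd.DataFrame,
    treg_scores: pd.Series,
    labels,
    markers: GeneSet = EXHAUSTION_PANEL,
) -> dict:
    """Per-cluster Spearman rho(Treg score, exhaustion score) + marker means."""
    present = [g for g in markers.genes if g in expr.columns]
    if not present:
        raise ValueError(f"no exhaustion markers of {markers.name!r} in the matrix")
    exh = signature_score(expr, GeneSet(markers.name, present))
    labels = np.asarray(labels)
    treg = np.asarray(treg_scores.loc[expr.index], dtype=float)

    corr_rows, mean_rows = [], []
    for c in pd.unique(labels):
        mask = labels == c
        t, e = treg[mask], exh.to_numpy()[mask]
        flagged = bool(np.all(t == t[0]) or np.all(e == e[0]))
        if flagged:
            rho, p = 0.0, 1.0
        else:
            rho, p = stats.spearmanr(t, e)
        corr_rows.append(
            {"cluster": c, "spearman_rho": float(rho), "p": float(p),
             "constant_flag": flagged}
        )
        means = expr.loc[mask, present].mean(axis=0)
        mean_rows.append({"cluster": c, **means.to_dict()})
    return {
        "correlations": pd.DataFrame(corr_rows).set_index("cluster").sort_index(),
        "marker_means": pd.DataFrame(mean_rows).set_index("cluster").sort_index(),
        "exhaustion_score": exh,
    }


# ----------------------------------------------------- DE-table filtering

def filter_de_table(
    de: pd.DataFrame,
    p_col: str = "padj",
    lfc_col: str = "log2FoldChange",
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> pd.DataFrame:
    """Volcano-style filter on an externally fitted DE table."""
    for col in (p_col, lfc_col):
        if col not in de.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    keep = (de[p_col] < alpha) & (de[lfc_col].abs() > min_abs_lfc)
    return de[keep].copy()
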