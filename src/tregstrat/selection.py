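"""Multi-criteria selection of the Treg-enriched cluster.

Each line of evidence (Treg-related GO/ORA term counts, pathway NES,
Treg signature GSEA NES, estimated Treg fraction, immune score) is a
:class:`CriterionResult` holding one scalar per cluster and a direction
flag.  Clusters are ranked within each criterion (rank 1 = most
Treg-like; ties share the minimum rank), and the winner is the cluster
with the most rank-1 finishes.  Ties cascade to (a) lowest mean rank
across criteria, (b) highest Treg-signature GSEA NES, (c) smallest
cluster id — the last purely to keep the rule total.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

KNOWN_CRITERIA = ("go_terms", "kegg_nes", "gsea_nes", "treg_fraction", "immune_score")


def parse_criterion_value(x) -> float:
    """Scalar from a table entry; 'a–b' intervals become midpoints,
    trailing qualifiers like '(Low)' are ignored."""
    if isinstance(x, (int, float, np.integer, np.floating)):
        return float(x)
    s = re.sub(r"\(.*?\)", "", str(x)).strip()
    m = re.match(r"^(-?\d+\.?\d*)\s*[–—-]\s*(-?\d+\.?\d*)$", s)
    if m:
        return (float(m.group(1)) + float(m.group(2))) / 2.0
    return float(s)


@dataclass
class CriterionResult:
    criterion: str
    per_cluster_value: dict
    higher_is_more_treg: bool = True
    significance: dict | None = None

    def __post_init__(self) -> None:
        self.per_cluster_value = {
            c: parse_criterion_value(v) for c, v in self.per_cluster_value.items()
        }


@dataclass
class SelectionMatrix:
    clusters: list
    criteria: list[CriterionResult]
    ranks: pd.DataFrame  # rows = criteria, columns = clusters, 1 = most Treg-like


@dataclass
class SelectionReport:
    selected_cluster: object
    per_criterion_winner: dict
    rank1_counts: dict
    tie_break_used: str | None
    evidence: str
    matrix: SelectionMatrix = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "selected_cluster": self.selected_cluster,
            "per_criterion_winner": self.per_criterion_winner,
            "rank1_counts": self.rank1_counts,
            "tie_break_used": self.tie_break_used,
            "evidence": self.evidence,
        }


def build_selection_matrix(criteria: list[CriterionResult]) -> SelectionMatrix:
    """Rank clusters within each criterion; ties share the minimum rank."""
    if not criteria:
        raise ValueError("need at least one criterion")
    clusters = sorted(criteria[0].per_cluster_value)
    for crit in criteria[1:]:
        if sorted(crit.per_cluster_value) != clusters:
            raise ValueError(
                f"criterion {crit.criterion!r} covers clusters "
                f"{sorted(crit.per_cluster_value)} but expected {clusters}"
            )
    rows = {}
    for crit in criteria:
        vals = np.array([crit.per_cluster_value[c] for c in clusters], dtype=float)
        keyed = -vals if crit.higher_is_more_treg else vals
        rows[crit.criterion] = rankdata(keyed, method="min").astype(int)
    ranks = pd.DataFrame(rows, index=clusters).T
    return SelectionMatrix(clusters=clusters, criteria=criteria, ranks=ranks)


def select_treg_cluster(matrix: SelectionMatrix) -> SelectionReport:
    """Majority-of-rank-1 winner with the deterministic tie cascade."""
    clusters = matrix.clusters
    if len(clusters) == 1:
        warnings.warn("only one cluster present; selection is trivial", stacklevel=2)
        only = clusters[0]
        return SelectionReport(
            selected_cluster=only,
            per_criterion_winner={c.criterion: only for c in matrix.criteria},
            rank1_counts={only: len(matrix.criteria)},
            tie_break_used=None,
            evidence="single cluster; selected by default",
            matrix=matrix,
        )

    ranks = matrix.ranks
    winners = {}
    for crit in matrix.criteria:
        row = ranks.loc[crit.criterion]
        winners[crit.criterion] = list(row.index[row == 1])
    rank1_counts = {c: sum(c in w for w in winners.values()) for c in clusters}

    best_count = max(rank1_counts.values())
    contenders = [c for c in clusters if rank1_counts[c] == best_count]
    tie_break = None
    if len(contenders) > 1:
        mean_rank = ranks[contenders].mean(axis=0)
        low = mean_rank.min()
        contenders = [c for c in contenders if mean_rank[c] == low]
        tie_break = "mean_rank"
    if len(contenders) > 1:
        nes_crit = next(
            (cr for cr in matrix.criteria if cr.criterion == "gsea_nes"), None
        )
        if nes_crit is not None:
            hi = max(nes_crit.per_cluster_value[c] for c in contenders)
            contenders = [
                c for c in contenders if nes_crit.per_cluster_value[c] == hi
            ]
            tie_break = "gsea_nes"
    if len(contenders) > 1:
        contenders = [sorted(contenders)[0]]
        tie_break = "cluster_id"

    selected = contenders[0]
    lines = [
        f"criterion {crit.criterion}: winner(s) {winners[crit.criterion]}"
        for crit in matrix.criteria
    ]
    lines.append(
        f"selected {selected!r} with {rank1_counts[selected]}/"
        f"{len(matrix.criteria)} rank-1 finishes"
        + (f" (tie-break: {tie_break})" if tie_break else "")
    )
    return SelectionReport(
        selected_cluster=selected,
        per_criterion_winner={k: v[0] if len(v) == 1 else v for k, v in winners.items()},
        rank1_counts=rank1_counts,
        tie_break_used=tie_break,
        evidence="\n".join(lines),
        matrix=matrix,
    )


def load_criteria_csv(path) -> list[CriterionResult]:
    """Read a hand-written criteria table: criterion,cluster,value,direction."""
    df = pd.read_csv(path)
    required = {"criterion", "cluster", "value", "direction"}
    if not required <= set(df.columns):
        raise ValueError(f"criteria CSV needs columns {sorted(required)}")
    out = []
    for crit, sub in df.groupby("criterion", sort=False):
        directions = set(sub["direction"].astype(str).str.lower())
        if len(directions) != 1:
            raise ValueError(f"criterion {crit!r} has inconsistent directions")
        higher = directions.pop() in ("higher", "higher_is_more_treg", "up", "true")
        out.append(
            CriterionResult(
                criterion=str(crit),
                per_cluster_value=dict(zip(sub["cluster"], sub["value"])),
                higher_is_more_treg=higher,
            )
        )
    return out
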