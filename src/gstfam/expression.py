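"""Expression fold change, row scaling, tier assignment and clustering.

Operates on pandas DataFrames (genes x conditions, non-negative values).
Hierarchical clustering uses the Manhattan (city-block) metric with average
linkage and fully deterministic tie-breaking, so the ordered output matrix is
the ground truth for any downstream heatmap rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def validate_matrix(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        raise ValueError("empty expression matrix")
    if (df.values < 0).any():
        raise ValueError("expression values must be non-negative")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate gene or condition ids")
    return df


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_matrix(df)


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def fold_change(
    df: pd.DataFrame,
    control: str,
    pseudocount: float = 1.0,
    log2: bool = False,
) -> pd.DataFrame:
    """Per-gene ratio to the control column: ``(x + c) / (x0 + c)``.

    The control column maps to 1 (or 0 under ``log2=True``).
    """
    validate_matrix(df)
    if control not in df.columns:
        raise ValueError(f"control column {control!r} not in matrix")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    base = df[control] + pseudocount
    if (base == 0).any():
        raise ValueError("zero control values; use a positive pseudocount")
    ratios = (df.add(pseudocount)).div(base, axis=0)
    return np.log2(ratios) if log2 else ratios


def row_scale_percent(df: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene row to [0, 100]; constant rows become all 0 (warned)."""
    if df.shape[1] < 1:
        raise ValueError("matrix needs at least one column")
    lo = df.min(axis=1)
    hi = df.max(axis=1)
    span = hi - lo
    constant = span == 0
    if constant.any():
        logger.warning(
            "%d constant rows scaled to all-zero", int(constant.sum())
        )
    span = span.replace(0, np.nan)
    scaled = df.sub(lo, axis=0).div(span, axis=0).fillna(0.0) * 100.0
    return scaled


def assign_tier(
    df: pd.DataFrame,
    thresholds: Optional[tuple[float, float]] = None,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Tier per gene (low/medium/high) by tertiles of mean log2 abundance.

    Explicit ``thresholds=(t_low, t_high)`` on the mean log2 value override
    the tertile rule. All-equal means collapse to "low" with a warning.
    """
    validate_matrix(df)
    if len(df) < 3 and thresholds is None:
        raise ValueError("tertile tiers need at least 3 genes")
    means = np.log2(df + pseudocount).mean(axis=1)
    if thresholds is None:
        if means.nunique() == 1:
            logger.warning("all genes have equal mean abundance; all tiers 'low'")
            return pd.Series("low", index=df.index, name="tier")
        t_low = float(np.quantile(means, 1 / 3))
        t_high = float(np.quantile(means, 2 / 3))
    else:
        t_low, t_high = thresholds
    tiers = pd.Series("medium", index=df.index, name="tier")
    tiers[means <= t_low] = "low"
    tiers[means > t_high] = "high"
    return tiers


def manhattan(x: Sequence[float], y: Sequence[float]) -> float:
    return float(np.abs(np.asarray(x, float) - np.asarray(y, float)).sum())


@dataclass
class ClusterResult:
    """Agglomeration trace: merges (label tuples + height), leaf order."""

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    leaf_order: list[str]
    linkage: str
    metric: str

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        tree = {}

        def key(labels):
            return tuple(sorted(labels))

        for a, b, h in self.merges:
            tree[key(a + b)] = (key(a), key(b), h)

        def render(k):
            if k not in tree:
                assert len(k) == 1
                return k[0]
            a, b, _ = tree[k]
            return f"({render(a)},{render(b)})"

        root = key(tuple(self.leaf_order))
        return render(root) + ";"


def hier_cluster(
    df: pd.DataFrame,
    metric: str = "manhattan",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of gene rows.

    Average linkage recomputes the mean over all cross-pair distances; ties
    break on the smallest (sorted) label pair. Leaf order puts the smaller
    subtree first (ties: subtree containing the smallest label first).
    """
    if len(df) < 2:
        raise ValueError("clustering needs at least 2 genes")
    if metric != "manhattan":
        raise ValueError("only the manhattan metric is supported")
    if linkage not in {"average", "single", "complete"}:
        raise ValueError(f"unknown linkage {linkage!r}")

    labels = list(df.index)
    base = {
        (a, b): manhattan(df.loc[a], df.loc[b])
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    }

    def pair_dist(x, y):
        return base[(x, y)] if (x, y) in base else base[(y, x)]

    def cluster_dist(ca, cb):
        dists = [pair_dist(x, y) for x in ca for y in cb]
        if linkage == "average":
            return sum(dists) / len(dists)
        return min(dists) if linkage == "single" else max(dists)

    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cluster_dist(clusters[i], clusters[j])
                tiebreak = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                cand = (d, tiebreak, i, j)
                if best is None or cand < best:
                    best = cand
        d, _, i, j = best
        a, b = clusters[i], clusters[j]
        merges.append((a, b, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(a + b)

    leaf_order = _leaf_order(merges, tuple(sorted(labels)))
    return ClusterResult(merges, leaf_order, linkage, metric)


def _leaf_order(merges, root_key):
    children = {}
    for a, b, _ in merges:
        children[tuple(sorted(a + b))] = (tuple(sorted(a)), tuple(sorted(b)))

    def walk(k):
        if k not in children:
            assert len(k) == 1
            return list(k)
        a, b = children[k]
        first, second = sorted((a, b), key=lambda c: (len(c), min(c)))
        return walk(first) + walk(second)

    return walk(root_key)


def ordered_matrix(df: pd.DataFrame, result: ClusterResult) -> pd.DataFrame:
    """Rows reordered by the dendrogram leaf order."""
    return df.loc[result.leaf_order]
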