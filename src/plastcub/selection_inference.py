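"""Mutation-vs-selection partitioning of codon-usage variation.

The neutrality plot regresses per-gene GC12 (mean GC of codon positions 1
and 2) on GC3.  Under mutation-driven evolution all three positions track
the same compositional pressure and the slope approaches 1; under
selection on codon choice GC12 is pinned by the protein while GC3 floats,
and the slope approaches 0.  The slope x 100 is reported as the percentage
of codon-usage variation attributable to mutational pressure (the
remainder to selection) - an interpretive convention, not a formal
variance decomposition.

ENC-curve deviation compares each gene's observed effective number of
codons with the compositional expectation at its GC3s; genes far below the
curve indicate selection on synonymous codon choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .codon_metrics import UsageProfile, expected_enc
from .group_stats import GroupTestResult, bonferroni, kruskal_wallis


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    points: tuple[tuple[float, float], ...]  # (gc3, gc12) pairs


def neutrality_regression(
    profiles: Iterable[UsageProfile] | Sequence[tuple[float, float]],
) -> RegressionFit | None:
    """OLS fit of GC12 on GC3 across genes; None with fewer than 3 points.

    Accepts usage profiles (gc3/gc12 fields) or raw (gc3, gc12) pairs.
    """
    points = []
    for item in profiles:
        if isinstance(item, UsageProfile):
            if item.gc3 is None or item.gc12 is None:
                continue
            points.append((item.gc3, item.gc12))
        else:
            points.append((float(item[0]), float(item[1])))
    if len(points) < 3:
        return None
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    if np.all(x == x[0]):
        return None
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if np.isnan(r2) and np.all(y == y[0]):  # constant response: nothing to explain
        r2 = 0.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=len(points),
        points=tuple(points),
    )


def mutation_contribution(fit: RegressionFit | float) -> float:
    """Percent of codon-usage variation attributed to mutational pressure:
    the neutrality slope x 100 (selection contributes the remainder)."""
    slope = fit.slope if isinstance(fit, RegressionFit) else float(fit)
    return slope * 100.0


def enc_deviation(
    profiles: Iterable[UsageProfile],
) -> tuple[pd.DataFrame, float | None]:
    """Per-gene (observed - expected) ENC and the fraction of genes below
    the compositional expectation curve."""
    rows = []
    for p in profiles:
        if p.enc is None or p.gc3s is None:
            continue
        expected = expected_enc(p.gc3s)
        rows.append(
            {"name": p.name, "enc": p.enc, "gc3s": p.gc3s,
             "expected_enc": expected, "deviation": p.enc - expected}
        )
    df = pd.DataFrame(rows, columns=["name", "enc", "gc3s", "expected_enc", "deviation"])
    if df.empty:
        return df, None
    return df, float((df["deviation"] < 0).mean())


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaves: list[str]  # dendrogram leaf order
    labels: dict[str, int] | None  # flat cluster assignment (1-based)


def cluster_profiles(
    matrix: pd.DataFrame,
    method: str = "ward",
    n_clusters: int | None = None,
) -> ClusterResult:
    """Hierarchical clustering of entity rows (Euclidean, Ward by default).

    Missing cells are imputed with the column mean.  Leaf order is the
    deterministic scipy dendrogram order (distance ties broken by merge
    index).  A single row is returned as a singleton cluster.
    """
    data = matrix.astype(float).copy()
    if data.isna().any().any():
        data = data.fillna(data.mean())
    names = [str(i) for i in data.index]
    if len(names) < 2:
        return ClusterResult(np.empty((0, 4)), names, {n: 1 for n in names})
    z = hierarchy.linkage(pdist(data.to_numpy()), method=method)
    order = hierarchy.leaves_list(z)
    leaves = [names[i] for i in order]
    labels = None
    if n_clusters is not None:
        flat = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
        labels = {names[i]: int(flat[i]) for i in range(len(names))}
    return ClusterResult(z, leaves, labels)


def linkage_to_newick(result: ClusterResult) -> str:
    """Export a clustering as a newick string with branch lengths."""
    if len(result.leaves) == 1:
        return f"({result.leaves[0]});"
    tree = hierarchy.to_tree(result.linkage)
    names = list(result.leaves)
    # to_tree indexes leaves by original row order; rebuild that order
    order = hierarchy.leaves_list(result.linkage)
    original = [None] * len(names)
    for pos, idx in enumerate(order):
        original[idx] = names[pos]

    def walk(node, parent_dist):
        if node.is_leaf():
            return f"{original[node.id]}:{parent_dist - node.dist:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_dist - node.dist:.6g}"

    return walk(tree, tree.dist) + ";"


def rscu_group_test(
    rscu_by_group: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-codon Kruskal-Wallis test of RSCU values across groups.

    Each group is a species x codon RSCU table; codons missing in any
    species are dropped within that group.  Degenerate codons (all values
    identical, or fewer than 2 usable members in some group) are skipped.
    Bonferroni correction over the number of codons tested.
    """
    groups = list(rscu_by_group.values())
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    codons = sorted(set.intersection(*(set(g.columns) for g in groups)))
    rows = []
    for codon in codons:
        samples = [g[codon].dropna().to_numpy(float) for g in groups]
        if any(len(s) < 2 for s in samples):
            continue
        res: GroupTestResult = kruskal_wallis(samples)
        rows.append({"codon": codon, "H": res.statistic, "p_raw": res.p_value})
    df = pd.DataFrame(rows, columns=["codon", "H", "p_raw"])
    if not df.empty:
        df["p_bonferroni"] = bonferroni(df["p_raw"].tolist())
    return df
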