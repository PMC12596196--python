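"""Condition-level analysis of the iModulon activity matrix A.

A component's activity row tracks the inferred regulatory signal across
samples: hierarchical clustering of rows groups components that respond
to the same stimuli, two-group comparisons quantify differential
activity between conditions, and per-component explained variance
summarizes how much of the transcriptome each module governs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .expression import ExpressionMatrix
from .ica import RobustDecomposition

logger = logging.getLogger(__name__)


@dataclass
class ActivityProfile:
    """One component's activity vector with per-condition summaries."""

    component_id: str
    activities: pd.Series  # indexed by sample id
    condition_means: dict = field(default_factory=dict)
    condition_sds: dict = field(default_factory=dict)

    @classmethod
    def from_decomposition(cls, decomp: RobustDecomposition, component_id: str,
                           meta: pd.DataFrame | None = None) -> "ActivityProfile":
        row = decomp.A.loc[component_id]
        means, sds = {}, {}
        if meta is not None:
            lookup = meta.set_index("sample_id")["condition"]
            cond = pd.Series([lookup.get(s) for s in row.index], index=row.index)
            for c, grp in row.groupby(cond):
                means[c] = float(grp.mean())
                sds[c] = float(grp.std(ddof=1)) if len(grp) > 1 else 0.0
        return cls(component_id=component_id, activities=row,
                   condition_means=means, condition_sds=sds)


def cluster_activity_rows(A: pd.DataFrame, n_clusters: int | None = None,
                          height: float | None = None):
    """Ward-linkage hierarchical clustering of activity rows.

    Euclidean distance between rows, Ward's method, deterministic.
    Returns ``(linkage, labels)``; the flat cut uses ``n_clusters`` or a
    ``height`` (one of the two; default 2 clusters).
    """
    if A.shape[0] < 2:
        raise ValueError("need at least 2 activity rows to cluster")
    Z = hierarchy.linkage(A.to_numpy(), method="ward", metric="euclidean")
    if height is not None:
        labels = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        labels = hierarchy.fcluster(Z, t=n_clusters or 2, criterion="maxclust")
    return Z, pd.Series(labels, index=A.index, name="cluster")


def differential_activity(
    profile: ActivityProfile,
    group_a: list[str],
    group_b: list[str],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test of a component's activity between sample groups.

    Welch's unequal-variance test by default (``equal_var=True`` gives
    the pooled Student test). Returns (delta, p) where delta is
    mean(group_a) − mean(group_b). Groups must be disjoint with at
    least two samples each. Degenerate zero-variance groups yield p = 1
    when the means agree and p = 0 otherwise.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"overlapping groups: {sorted(overlap)[:5]}")
    a = profile.activities.loc[list(group_a)].to_numpy(dtype=float)
    b = profile.activities.loc[list(group_b)].to_numpy(dtype=float)
    delta = float(a.mean() - b.mean())
    if np.var(a) == 0 and np.var(b) == 0:
        return delta, 1.0 if delta == 0 else 0.0
    _, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return delta, float(p)


def differential_activity_table(
    decomp: RobustDecomposition,
    group_a: list[str],
    group_b: list[str],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Differential activity of every component, with BH-adjusted q."""
    from .enrichment import fdr_adjust

    rows = []
    for cid in decomp.component_ids:
        profile = ActivityProfile.from_decomposition(decomp, cid)
        delta, p = differential_activity(profile, group_a, group_b, equal_var=equal_var)
        rows.append({"component_id": cid, "delta": delta, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = fdr_adjust(table["p"].clip(lower=np.nextafter(0, 1)))
    return table


def activity_expression_correlation(
    profile: ActivityProfile, x: ExpressionMatrix, gene: str
) -> float:
    """Pearson correlation between a component's activity and one gene."""
    if gene not in x.data.index:
        raise KeyError(f"unknown gene {gene!r}")
    expr = x.data.loc[gene, profile.activities.index].to_numpy(dtype=float)
    act = profile.activities.to_numpy(dtype=float)
    if np.std(expr) == 0 or np.std(act) == 0:
        raise ValueError("zero-variance vector in activity-expression correlation")
    return float(np.corrcoef(act, expr)[0, 1])


def variance_treemap(
    x: ExpressionMatrix,
    decomp: RobustDecomposition,
    categories: dict,
) -> pd.DataFrame:
    """Per-category explained-variance table.

    Each component's marginal explained variance (single-component
    least-squares reconstruction of centered X) is aggregated by its
    curated category. For correlated components the marginal shares
    need not sum exactly to the joint explained variance; the overlap
    is reported, not forced.
    """
    from .ica import explained_variance

    missing = [cid for cid in decomp.component_ids if cid not in categories]
    if missing:
        raise ValueError(f"uncategorized components: {missing[:5]}")
    per_component = {
        cid: explained_variance(x, decomp, subset=[cid]) for cid in decomp.component_ids
    }
    rows = []
    for category in sorted(set(categories[cid] for cid in decomp.component_ids)):
        cids = [cid for cid in decomp.component_ids if categories[cid] == category]
        rows.append(
            {
                "category": category,
                "n_components": len(cids),
                "explained_variance": float(sum(per_component[c] for c in cids)),
            }
        )
    table = pd.DataFrame(rows)
    table["share_of_total"] = table["explained_variance"] / table["explained_variance"].sum()
    return table


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def build(node):
        if node.is_leaf():
            return labels[node.id]
        left, right = build(node.get_left()), build(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return build(tree) + ";"
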