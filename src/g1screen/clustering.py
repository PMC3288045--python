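"""Phenotype-profile assembly and unsupervised hierarchical clustering.

Profiles are rows of normalized assay means per target.  Clustering is
agglomerative with Euclidean distance and complete linkage after row-wise
standardization (mean 0, SD 1 per target) — the defaults of the standard
heatmap routine — and the dendrogram is cut into k groups (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import G1ScreenError


@dataclass
class ClusterResult:
    linkage: np.ndarray
    groups: pd.Series            # target -> group label (1..k)
    newick: str
    order: list[str]             # leaf order of the dendrogram
    params: dict


def build_profile_matrix(results: pd.DataFrame,
                         target_col: str = "target_id",
                         assay_col: str = "assay",
                         value_col: str = "value") -> pd.DataFrame:
    """Pivot long-form normalized assay means into a targets x assays matrix.

    Every target must have every assay column; a missing cell raises with
    the offending (target, assay) pairs named.  Column order follows first
    appearance in the input.
    """
    needed = {target_col, assay_col, value_col}
    missing_cols = needed - set(results.columns)
    if missing_cols:
        raise G1ScreenError(f"missing columns: {sorted(missing_cols)}")
    dup = results.duplicated([target_col, assay_col])
    if dup.any():
        raise G1ScreenError("duplicate (target, assay) entries in profile input")
    assay_order = list(dict.fromkeys(results[assay_col]))
    target_order = list(dict.fromkeys(results[target_col]))
    matrix = results.pivot(index=target_col, columns=assay_col, values=value_col)
    matrix = matrix.reindex(index=target_order, columns=assay_order)
    if matrix.isna().any().any():
        gaps = [(t, a) for t in matrix.index for a in matrix.columns
                if pd.isna(matrix.at[t, a])]
        raise G1ScreenError(f"missing profile values for: {gaps}")
    matrix.columns.name = None
    matrix.index.name = "target_id"
    return matrix


def standardize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, SD 1 (sample SD).

    Constant rows cannot be standardized and raise before clustering.
    """
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any() or not np.isfinite(sd).all():
        bad = matrix.index[(sd == 0) | ~np.isfinite(sd)].tolist()
        raise G1ScreenError(f"constant rows cannot be standardized: {bad}")
    out = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def cluster_targets(matrix: pd.DataFrame, k: int = 2,
                    metric: str = "euclidean", method: str = "complete",
                    row_standardize: bool = True) -> ClusterResult:
    """Hierarchical clustering of phenotype profiles, cut into k groups.

    Deterministic given the matrix; group labels are renumbered by first
    appearance in the input row order so permuting rows permutes nothing
    but the dendrogram drawing.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise G1ScreenError("need >= 2 targets and >= 2 assay columns")
    if not 1 <= k <= matrix.shape[0]:
        raise G1ScreenError("k must lie in 1..n_targets")
    data = standardize_rows(matrix) if row_standardize else matrix
    Z = hierarchy.linkage(data.to_numpy(dtype=float), method=method, metric=metric)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for g in raw:
        if g not in relabel:
            relabel[g] = len(relabel) + 1
        labels.append(relabel[g])
    groups = pd.Series(labels, index=matrix.index, name="group")
    tree = hierarchy.to_tree(Z)
    order = [matrix.index[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(
        linkage=Z, groups=groups,
        newick=to_newick(tree, list(matrix.index)),
        order=order,
        params={"k": k, "metric": metric, "method": method,
                "row_standardize": row_standardize},
    )


def to_newick(node, labels: list[str]) -> str:
    """Render a scipy cluster tree as a newick string with branch lengths."""

    def walk(n, parent_dist: float) -> str:
        length = parent_dist - n.dist
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.6g}"
        left = walk(n.get_left(), n.dist)
        right = walk(n.get_right(), n.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(node, node.dist) + ";"


def cophenetic_matrix(Z: np.ndarray) -> np.ndarray:
    """Square cophenetic distance matrix of a linkage."""
    from scipy.spatial.distance import squareform
    return squareform(hierarchy.cophenet(Z))


def plot_heatmap(matrix: pd.DataFrame, result: ClusterResult, path: str) -> None:
    """Optional clustered-heatmap rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = standardize_rows(matrix) if result.params.get("row_standardize") else matrix
    ordered = data.loc[result.order]
    fig, ax = plt.subplots(figsize=(1.2 * matrix.shape[1], 0.45 * matrix.shape[0] + 1.5))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(ordered.index)), ordered.index)
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=45, ha="right")
    fig.colorbar(im, ax=ax, label="row-standardized value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
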