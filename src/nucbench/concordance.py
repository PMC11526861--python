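"""Cross-dataset concordance: profile correlation matrices and dataset clustering.

Datasets are compared through their per-bin 1D summaries (compartment
eigenvector or insulation score) on a shared bin table: pairwise Spearman or
Pearson correlation over pairwise-complete bins, then average- or
complete-linkage agglomeration on distance 1 - r. The expected structure of a
well-behaved assay panel is clustering first by cell type (truth), then by
method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = ["ProfileSet", "correlation_matrix", "cluster_datasets", "top_split"]


class ProfileSet:
    """Labeled per-bin profiles on a common bin table, with optional metadata."""

    def __init__(self, bin_table, profiles: dict[str, np.ndarray], metadata: pd.DataFrame | None = None):
        self.bin_table = bin_table
        n = bin_table.n_bins
        for label, v in profiles.items():
            if np.asarray(v).shape != (n,):
                raise ValueError(f"profile {label} length does not match bin table")
        if len(set(profiles)) != len(profiles):
            raise ValueError("profile labels must be unique")
        self.frame = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in profiles.items()})
        self.metadata = metadata

    @property
    def labels(self) -> list[str]:
        return list(self.frame.columns)


def correlation_matrix(profiles: ProfileSet | pd.DataFrame, method: str = "spearman", min_pairs: int = 100) -> pd.DataFrame:
    """Pairwise-complete correlation matrix of the profiles.

    Constant profiles get an undefined (NaN) row/column; pairs with fewer
    than ``min_pairs`` jointly defined bins are rejected.
    """
    df = profiles.frame if isinstance(profiles, ProfileSet) else profiles
    if df.shape[1] < 2:
        raise ValueError("need at least two profiles")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    notna = df.notna().to_numpy()
    pair_n = notna.T.astype(int) @ notna.astype(int)
    off = ~np.eye(df.shape[1], dtype=bool)
    if (pair_n[off] < min_pairs).any():
        k = np.argwhere((pair_n < min_pairs) & off)[0]
        raise ValueError(
            f"profiles {df.columns[k[0]]} and {df.columns[k[1]]} share fewer than {min_pairs} defined bins"
        )
    corr = df.corr(method=method)
    # unit diagonal where defined; constant profiles stay NaN
    for k, c in enumerate(df.columns):
        col = df[c].dropna()
        if col.nunique() > 1:
            corr.iloc[k, k] = 1.0
        else:
            corr.iloc[k, :] = np.nan
            corr.iloc[:, k] = np.nan
    return corr


def cluster_datasets(corr: pd.DataFrame, linkage: str = "average"):
    """Agglomerative clustering of datasets on distance 1 - r.

    Labels are pre-sorted lexicographically so tie-breaking is deterministic
    and independent of input order. Returns ``(Z, leaf_labels, newick)``.
    """
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    bad = corr.columns[corr.isna().any(axis=0)].tolist()
    if bad:
        raise ValueError(f"undefined correlation entries for: {', '.join(map(str, bad))}")
    labels = sorted(corr.columns)
    c = corr.loc[labels, labels].to_numpy()
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(Z)
    leaf_labels = [labels[k] for k in order]
    newick = _to_newick(Z, labels)
    return Z, leaf_labels, newick


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, labels)
    return str(tree).strip()


def top_split(Z: np.ndarray, labels: list[str]) -> tuple[set, set]:
    """The two label groups separated by the root of the dendrogram."""
    n = len(labels)
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, _, _) in enumerate(Z):
        children[n + k] = (int(a), int(b))

    def leaves(node: int) -> set:
        if node < n:
            return {labels[node]}
        a, b = children[node]
        return leaves(a) | leaves(b)

    root_a, root_b = children[n + Z.shape[0] - 1]
    return leaves(root_a), leaves(root_b)
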