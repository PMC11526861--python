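"""SPRITE-style multiway proximity clusters and their pairwise conversion.

A cluster is a set of spatially proximal genomic positions detected together.
To compare with pairwise assays, each cluster of n distinct bins contributes
all n(n-1)/2 unordered bin pairs, each down-weighted by 2/n so the cluster's
total pairwise mass is exactly n-1 (the default rule; "unit" weighting is
available for sensitivity analysis). Cluster size means *distinct bins* after
per-bin deduplication, since pairwise weights would otherwise double-count
within-bin fragments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .contact_core import BinTable, ContactMatrix

__all__ = [
    "ClusterSet",
    "clusters_to_pairs",
    "stratify_by_size",
    "cluster_size_histogram",
    "read_clusters",
    "write_clusters",
]


class ClusterSet:
    """Multiway proximity clusters as lists of distinct global bin indices."""

    def __init__(self, bin_table: BinTable, members: list[np.ndarray], raw_sizes: list[int] | None = None):
        self.bin_table = bin_table
        self.members = [np.unique(np.asarray(m, dtype=np.int64)) for m in members]
        for m in self.members:
            if m.size and (m.min() < 0 or m.max() >= bin_table.n_bins):
                raise ValueError("cluster member bin out of range")
        # raw fragment counts before deduplication, when known
        self.raw_sizes = list(raw_sizes) if raw_sizes is not None else [m.size for m in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def sizes(self, by: str = "bins") -> np.ndarray:
        """Cluster sizes by distinct bins (default) or raw fragment count."""
        if by == "bins":
            return np.array([m.size for m in self.members], dtype=int)
        if by == "fragments":
            return np.array(self.raw_sizes, dtype=int)
        raise ValueError("by must be 'bins' or 'fragments'")


def clusters_to_pairs(
    clusters: ClusterSet,
    bin_table: BinTable | None = None,
    weight_rule: str = "two_over_n",
) -> tuple[ContactMatrix, int]:
    """Weighted pairwise contact matrix from multiway clusters.

    Under the default 2/n rule a cluster of n distinct bins contributes total
    mass n-1; the matrix holds fractional counts. Clusters with fewer than
    two distinct bins are skipped and their number returned.
    """
    bt = bin_table or clusters.bin_table
    n = bt.n_bins
    dense = np.zeros((n, n))
    skipped = 0
    for m in clusters.members:
        k = m.size
        if k < 2:
            skipped += 1
            continue
        if weight_rule == "two_over_n":
            w = 2.0 / k
        elif weight_rule == "unit":
            w = 1.0
        else:
            raise ValueError("weight_rule must be 'two_over_n' or 'unit'")
        i, j = np.triu_indices(k, k=1)
        np.add.at(dense, (m[i], m[j]), w)
    iu, ju = np.nonzero(np.triu(dense))
    return ContactMatrix(bt, iu, ju, dense[iu, ju]), skipped


def stratify_by_size(
    clusters: ClusterSet,
    size_ranges: list[tuple[int, int]],
    by: str = "bins",
) -> tuple[dict[tuple[int, int], ClusterSet], int]:
    """Partition clusters into half-open size ranges [lo, hi).

    Ranges must be disjoint; clusters outside all ranges are dropped and
    their number returned.
    """
    ranges = sorted(size_ranges)
    for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
        if b0 < a1:
            raise ValueError(f"overlapping size ranges {(a0, a1)} and {(b0, b1)}")
    sizes = clusters.sizes(by=by)
    out = {r: [] for r in size_ranges}
    raw = {r: [] for r in size_ranges}
    dropped = 0
    for m, rs, s in zip(clusters.members, clusters.raw_sizes, sizes):
        for lo, hi in size_ranges:
            if lo <= s < hi:
                out[(lo, hi)].append(m)
                raw[(lo, hi)].append(rs)
                break
        else:
            dropped += 1
    return {r: ClusterSet(clusters.bin_table, out[r], raw[r]) for r in size_ranges}, dropped


def cluster_size_histogram(clusters: ClusterSet, log_bins: int = 20, by: str = "bins"):
    """Counts per log-spaced size bin; returns (edges, counts)."""
    sizes = clusters.sizes(by=by)
    if sizes.size == 0:
        edges = np.geomspace(2, 4, log_bins + 1)
        return edges, np.zeros(log_bins, dtype=int)
    lo, hi = sizes.min(), max(sizes.max(), sizes.min() + 1)
    edges = np.geomspace(lo, hi * (1 + 1e-9), log_bins + 1)
    counts, _ = np.histogram(sizes, bins=edges)
    return edges, counts


# ------------------------------------------------------------------ file I/O

def write_clusters(clusters: ClusterSet, path: str | Path) -> None:
    """TSV: cluster_id TAB comma-separated chrom:pos entries (bin midpoints)."""
    bt = clusters.bin_table
    bins = bt.bins()
    chrom = bins["chrom"].to_numpy()
    mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
    with open(path, "w") as f:
        for k, m in enumerate(clusters.members):
            entries = ",".join(f"{chrom[b]}:{mid[b]}" for b in m)
            f.write(f"cluster_{k}\t{entries}\n")


def read_clusters(path: str | Path, bin_table: BinTable) -> ClusterSet:
    members = []
    raw_sizes = []
    with open(path) as f:
        for line in f:
            if not line.strip():
                continue
            _, entries = line.rstrip("\n").split("\t", 1)
            bins = []
            for entry in entries.split(","):
                chrom, pos = entry.rsplit(":", 1)
                bins.append(bin_table.bin_id(chrom, int(pos)))
            raw_sizes.append(len(bins))
            members.append(np.asarray(bins))
    return ClusterSet(bin_table, members, raw_sizes)
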