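"""Chromatin-loop analysis: calling, APA, anchor sets, state enrichment,
loop clustering, and promoter-enhancer loop counting.

The caller is a deterministic local-background test in the HiCCUPS mold: for
every candidate cis pixel in a distance range, the null expectation is the
maximum over four local neighborhood backgrounds (donut, lower-left,
horizontal, vertical) of the local mean O/E, times the distance-decay
expectation, converted back to raw-count units through the balancing weights.
Significance is a Poisson upper tail with Benjamini-Hochberg correction over
all candidates jointly; significant pixels are clustered by 8-connectivity and
each cluster is reported at its maximal pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import poisson

from .contact_core import ContactMatrix, expected_by_distance, oe_transform

__all__ = [
    "BackgroundSpec",
    "call_loops",
    "apa",
    "shifted_loops",
    "union_anchors",
    "state_fold_enrichment",
    "embed_and_cluster_loops",
    "count_interacting_enhancers",
    "loops_from_bins",
    "write_bedpe",
    "read_bedpe",
]


@dataclass(frozen=True)
class BackgroundSpec:
    """Neighborhood radii of the four local background kernels."""

    outer: int = 5   # half-width of the full window
    inner: int = 2   # excluded peak neighborhood half-width

    def kernels(self) -> dict[str, np.ndarray]:
        R, r = self.outer, self.inner
        size = 2 * R + 1
        y, x = np.mgrid[-R : R + 1, -R : R + 1]
        inside_inner = (np.abs(y) <= r) & (np.abs(x) <= r)
        donut = ~inside_inner & ~((y == 0) | (x == 0))
        lower_left = (y > 0) & (x < 0) & ~inside_inner
        horizontal = (np.abs(y) <= 1) & ~inside_inner
        vertical = (np.abs(x) <= 1) & ~inside_inner
        return {
            "donut": donut.astype(float),
            "lower_left": lower_left.astype(float),
            "horizontal": horizontal.astype(float),
            "vertical": vertical.astype(float),
        }


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    q = np.empty(n)
    ranked = p[order] * n / np.arange(1, n + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.minimum(q, 1.0)


def call_loops(
    matrix: ContactMatrix,
    distance_range: tuple[int, int] = (100_000, 1_000_000),
    peak_width: int = 1,
    background: BackgroundSpec = BackgroundSpec(),
    fdr: float = 0.05,
    min_enrichment: float = 0.0,
) -> pd.DataFrame:
    """Call focal loops against the strongest of four local backgrounds.

    Optionally, significant pixel clusters whose maximal pixel is not at
    least ``min_enrichment``-fold over the donut/lower-left background are
    dropped (the fold-change filter of donut-style callers; off by default
    because sharply discontinuous compartment structure also depresses the
    fold change of genuine loops in locally depleted contexts).

    Returns a BEDPE-like frame (chrom, start1, end1, start2, end2, bin1,
    bin2, enrichment, pvalue, qvalue, source). Anchors are the called bin
    widened to ``peak_width + 1`` bins on output.
    """
    if matrix.weights is None:
        raise ValueError("loop calling requires a balanced matrix")
    bt = matrix.bin_table
    bs = bt.bin_size
    lo = -(-distance_range[0] // bs)
    hi = distance_range[1] // bs
    expected = expected_by_distance(matrix)
    oe = oe_transform(matrix, expected=expected)
    kernels = BackgroundSpec.kernels(background)

    cand = {"chrom": [], "i": [], "j": [], "obs": [], "lam": [], "oe": [], "enr": []}
    for chrom in bt.chrom_names:
        m = oe[chrom]
        n = m.shape[0]
        if n <= lo:
            continue
        sl = bt.chrom_slice(chrom)
        raw = matrix.dense(chrom, balanced=False)
        w = matrix.weights[sl]
        valid = np.isfinite(m)
        filled = np.where(valid, m, 0.0)
        local = {}
        for name, k in kernels.items():
            num = ndimage.correlate(filled, k, mode="constant", cval=0.0)
            den = ndimage.correlate(valid.astype(float), k, mode="constant", cval=0.0)
            with np.errstate(invalid="ignore"):
                local[name] = np.where(den > 0, num / den, np.nan)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            max_bg = np.nanmax(np.stack(list(local.values())), axis=0)
            # fold-change reference: donut and lower-left only; the strip
            # backgrounds can be contaminated by peaks sharing an anchor
            fold_bg = np.nanmax(np.stack([local["donut"], local["lower_left"]]), axis=0)

        i, j = np.triu_indices(n, k=lo)
        keep = (j - i) <= hi
        i, j = i[keep], j[keep]
        ok = valid[i, j] & np.isfinite(max_bg[i, j]) & (max_bg[i, j] > 0)
        i, j = i[ok], j[ok]
        idx = np.arange(n)
        sep = j - i
        e_d = expected[chrom][sep]
        lam = max_bg[i, j] * e_d / (w[i] * w[j])
        good = np.isfinite(lam) & (lam > 0)
        i, j, lam = i[good], j[good], lam[good]
        cand["chrom"].extend([chrom] * i.size)
        cand["i"].append(i)
        cand["j"].append(j)
        cand["obs"].append(raw[i, j])
        cand["lam"].append(lam)
        cand["oe"].append(oe[chrom][i, j])
        with np.errstate(invalid="ignore"):
            cand["enr"].append(oe[chrom][i, j] / fold_bg[i, j])

    cols = ["chrom", "start1", "end1", "start2", "end2", "bin1", "bin2", "enrichment", "oe", "pvalue", "qvalue", "source"]
    if not cand["i"]:
        return pd.DataFrame(columns=cols)
    chroms = np.array(cand["chrom"])
    i = np.concatenate(cand["i"])
    j = np.concatenate(cand["j"])
    obs = np.concatenate(cand["obs"])
    lam = np.concatenate(cand["lam"])
    oev = np.concatenate(cand["oe"])
    enr = np.concatenate(cand["enr"])
    pvals = poisson.sf(obs - 1, lam)
    qvals = _bh(pvals)
    sig = qvals <= fdr
    if not np.any(sig):
        return pd.DataFrame(columns=cols)

    rows = []
    for chrom in bt.chrom_names:
        sel = sig & (chroms == chrom)
        if not np.any(sel):
            continue
        n = bt.chrom_nbins(chrom)
        mask = np.zeros((n, n), dtype=bool)
        mask[i[sel], j[sel]] = True
        lab, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        stats = {"obs": {}, "best": {}}
        li, lj = i[sel], j[sel]
        lo_, lq, le, lp, loe = lab[li, lj], qvals[sel], enr[sel], pvals[sel], oev[sel]
        lobs = obs[sel]
        for k in range(li.size):
            c = lo_[k]
            cur = stats["best"].get(c)
            if cur is None or lobs[k] > cur[0] or (lobs[k] == cur[0] and (li[k], lj[k]) < cur[1]):
                stats["best"][c] = (lobs[k], (li[k], lj[k]), le[k], lp[k], lq[k], loe[k])
        size = bt.chromsizes[chrom]
        for c, (o, (bi, bj), e, p, q, ov) in sorted(stats["best"].items()):
            if e < min_enrichment:
                continue
            half = peak_width  # widen each anchor to peak_width+1 bins
            rows.append(
                {
                    "chrom": chrom,
                    "start1": bi * bs,
                    "end1": min((bi + 1 + half) * bs, size),
                    "start2": bj * bs,
                    "end2": min((bj + 1 + half) * bs, size),
                    "bin1": bt.chrom_offsets[chrom] + bi,
                    "bin2": bt.chrom_offsets[chrom] + bj,
                    "enrichment": float(e),
                    "oe": float(ov),
                    "pvalue": float(p),
                    "qvalue": float(q),
                    "source": "nucbench",
                }
            )
    return pd.DataFrame(rows, columns=cols)


def loops_from_bins(bin_table, pairs, source: str = "truth") -> pd.DataFrame:
    """BEDPE-like loop frame from global (bin1, bin2) pixel pairs."""
    bs = bin_table.bin_size
    bins = bin_table.bins()
    rows = []
    for b1, b2 in pairs:
        r1, r2 = bins.iloc[int(b1)], bins.iloc[int(b2)]
        rows.append(
            {
                "chrom": r1["chrom"],
                "start1": r1["start"],
                "end1": r1["end"],
                "start2": r2["start"],
                "end2": r2["end"],
                "bin1": int(b1),
                "bin2": int(b2),
                "enrichment": np.nan,
                "oe": np.nan,
                "pvalue": np.nan,
                "qvalue": np.nan,
                "source": source,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------- APA

def apa(
    matrix: ContactMatrix,
    loops: pd.DataFrame,
    half_window: int = 10,
    oe: dict[str, np.ndarray] | None = None,
):
    """Aggregate peak analysis: mean O/E in a window centered on loop pixels.

    Default geometry is the standard 21x21-pixel window (``half_window`` 10)
    at the matrix resolution. Loops closer than ``half_window + 1`` bins to a
    matrix edge or to the diagonal are skipped (the count is reported).
    Returns ``(grid, apa_score, n_used, n_skipped)`` with apa_score = center
    cell / mean of the lower-left 6x6 corner.
    """
    bt = matrix.bin_table
    if oe is None:
        oe = oe_transform(matrix)
    hw = half_window
    size = 2 * hw + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    used = skipped = 0
    offsets = bt.chrom_offsets
    for _, row in loops.iterrows():
        chrom = row["chrom"]
        off = offsets[chrom]
        b1, b2 = int(row["bin1"]) - off, int(row["bin2"]) - off
        n = oe[chrom].shape[0]
        if b1 - hw < 0 or b2 + hw >= n or (b2 - b1) < hw + 1:
            skipped += 1
            continue
        win = oe[chrom][b1 - hw : b1 + hw + 1, b2 - hw : b2 + hw + 1]
        good = np.isfinite(win)
        acc[good] += win[good]
        cnt[good] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable loops for APA")
    with np.errstate(invalid="ignore"):
        grid = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    corner = grid[-6:, :6]
    score = float(grid[hw, hw] / np.nanmean(corner))
    return grid, score, used, skipped


def shifted_loops(loops: pd.DataFrame, bin_table, shift_bins: int = 20) -> pd.DataFrame:
    """Null loop list: both anchors shifted along the diagonal by a fixed offset."""
    out = loops.copy()
    bs = bin_table.bin_size
    out["bin1"] = out["bin1"] + shift_bins
    out["bin2"] = out["bin2"] + shift_bins
    out["start1"] += shift_bins * bs
    out["end1"] += shift_bins * bs
    out["start2"] += shift_bins * bs
    out["end2"] += shift_bins * bs
    return out


# ------------------------------------------------------------- anchor union

def union_anchors(loop_lists: dict[str, pd.DataFrame], bin_table, merge_slack_bins: int = 1):
    """Union of loop anchors across sources with per-source membership flags.

    Anchor intervals from all lists are pooled per chromosome and merged by
    single linkage whenever they are within ``merge_slack_bins`` bins of each
    other. Returns ``(anchors, upset)`` where ``anchors`` has chrom, start,
    end and one boolean column per source, and ``upset`` maps the sorted
    tuple of member sources to a count.
    """
    slack = merge_slack_bins * bin_table.bin_size
    records = []
    for src, df in loop_lists.items():
        for _, row in df.iterrows():
            records.append((row["chrom"], row["start1"], row["end1"], src))
            records.append((row["chrom"], row["start2"], row["end2"], src))
    if not records:
        return pd.DataFrame(columns=["chrom", "start", "end"]), {}
    pool = pd.DataFrame(records, columns=["chrom", "start", "end", "source"])
    sources = list(loop_lists)
    out_rows = []
    upset: dict[tuple, int] = {}
    for chrom, grp in pool.groupby("chrom", sort=False):
        grp = grp.sort_values(["start", "end"]).reset_index(drop=True)
        cur_start, cur_end = None, None
        cur_src: set = set()

        def flush():
            if cur_start is None:
                return
            members = tuple(sorted(cur_src))
            row = {"chrom": chrom, "start": cur_start, "end": cur_end}
            row.update({s: (s in cur_src) for s in sources})
            out_rows.append(row)
            upset[members] = upset.get(members, 0) + 1

        for _, r in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end, cur_src = r["start"], r["end"], {r["source"]}
            elif r["start"] <= cur_end + slack:
                cur_end = max(cur_end, r["end"])
                cur_src.add(r["source"])
            else:
                flush()
                cur_start, cur_end, cur_src = r["start"], r["end"], {r["source"]}
        flush()
    anchors = pd.DataFrame(out_rows)
    return anchors, upset


# ------------------------------------------------------- state enrichment

def _overlap_bp(intervals: pd.DataFrame, segmentation: pd.DataFrame) -> dict[str, float]:
    """Base pairs of overlap between query intervals and each state.

    The segmentation must be non-overlapping; intervals are clipped onto it
    with a sorted sweep.
    """
    out: dict[str, float] = {}
    for chrom, seg in segmentation.groupby("chrom", sort=False):
        seg = seg.sort_values("start")
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        states = seg["state"].to_numpy()
        q = intervals[intervals["chrom"] == chrom]
        for _, r in q.iterrows():
            a = np.searchsorted(ends, r["start"], side="right")
            b = np.searchsorted(starts, r["end"], side="left")
            for k in range(a, b):
                ov = min(ends[k], r["end"]) - max(starts[k], r["start"])
                if ov > 0:
                    out[states[k]] = out.get(states[k], 0.0) + ov
    return out


def state_fold_enrichment(
    categories: dict[str, pd.DataFrame],
    segmentation: pd.DataFrame,
) -> pd.DataFrame:
    """Fold enrichment of chromatin states within anchor categories.

    enrichment(category, state) = (fraction of category bp in state) /
    (fraction of segmented genome bp in state); states absent from the
    genome give NaN (undefined, not infinite).
    """
    bp = segmentation["end"] - segmentation["start"]
    genome = bp.groupby(segmentation["state"]).sum().to_dict()
    genome_total = sum(genome.values())
    states = sorted(segmentation["state"].unique())
    rows = {}
    for name, cat in categories.items():
        ov = _overlap_bp(cat, segmentation)
        cat_total = sum(ov.values())
        row = {}
        for s in states:
            gfrac = genome.get(s, 0.0) / genome_total if genome_total else 0.0
            if gfrac == 0 or cat_total == 0:
                row[s] = np.nan
            else:
                row[s] = (ov.get(s, 0.0) / cat_total) / gfrac
        rows[name] = row
    return pd.DataFrame(rows).T[states]


# -------------------------------------------------- embedding / clustering

def anchor_state_fractions(loops: pd.DataFrame, segmentation: pd.DataFrame, bin_table) -> np.ndarray:
    """Per-loop composition vector: concatenated state fractions of both anchors.

    Orientation-normalized: the two anchor vectors are ordered
    lexicographically so that loops, being unordered pairs, get a canonical
    representation.
    """
    states = sorted(segmentation["state"].unique())
    state_id = {s: k for k, s in enumerate(states)}
    # per-bin state lookup (segmentation tiles the genome on bin boundaries)
    per_bin = np.zeros(bin_table.n_bins, dtype=int)
    for _, r in segmentation.iterrows():
        b0 = bin_table.bin_id(r["chrom"], int(r["start"]))
        b1 = bin_table.bin_id(r["chrom"], int(r["end"]) - 1)
        per_bin[b0 : b1 + 1] = state_id[r["state"]]
    vecs = []
    bs = bin_table.bin_size
    for _, row in loops.iterrows():
        parts = []
        for s_col, e_col in (("start1", "end1"), ("start2", "end2")):
            b0 = bin_table.bin_id(row["chrom"], int(row[s_col]))
            b1 = bin_table.bin_id(row["chrom"], int(row[e_col]) - 1)
            v = np.bincount(per_bin[b0 : b1 + 1], minlength=len(states)).astype(float)
            parts.append(v / v.sum())
        a, b = sorted(parts, key=lambda x: tuple(x))
        vecs.append(np.concatenate([a, b]))
    return np.asarray(vecs)


@dataclass
class LoopEmbedding:
    coords: np.ndarray          # n_loops x 2
    cluster: np.ndarray         # per-loop cluster id
    summaries: pd.DataFrame     # per-cluster median separation, size, ...
    degenerate: bool = False


def embed_and_cluster_loops(
    loops: pd.DataFrame,
    segmentation: pd.DataFrame,
    bin_table,
    n_clusters: int = 6,
    seed: int = 0,
    matrices: dict[str, ContactMatrix] | None = None,
) -> LoopEmbedding:
    """UMAP projection and k-means clustering of loops by state composition.

    Clusters are computed on the composition vectors; the 2D embedding is for
    display. Per-cluster summaries include median anchor separation and,
    when matrices are given, the mean O/E at the loop pixels per source.
    """
    if len(loops) < n_clusters:
        raise ValueError("fewer loops than clusters")
    X = anchor_state_fractions(loops, segmentation, bin_table)
    degenerate = bool(np.allclose(X, X[0]))
    from sklearn.cluster import KMeans

    if degenerate:
        labels = np.zeros(len(loops), dtype=int)
    else:
        km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
        labels = km.fit_predict(X)

    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        from umap import UMAP

        nn = min(15, max(2, len(loops) - 1))
        coords = UMAP(n_components=2, random_state=seed, n_neighbors=nn).fit_transform(X)

    sep = (loops["start2"].to_numpy() - loops["start1"].to_numpy()).astype(float)
    oe_by_src = {}
    if matrices:
        for src, m in matrices.items():
            oe = oe_transform(m)
            vals = []
            for _, row in loops.iterrows():
                off = bin_table.chrom_offsets[row["chrom"]]
                vals.append(oe[row["chrom"]][int(row["bin1"]) - off, int(row["bin2"]) - off])
            oe_by_src[src] = np.asarray(vals)
    rows = []
    for c in np.unique(labels):
        sel = labels == c
        row = {"cluster": int(c), "n_loops": int(sel.sum()), "median_separation": float(np.median(sep[sel]))}
        for src, vals in oe_by_src.items():
            row[f"mean_oe_{src}"] = float(np.nanmean(vals[sel]))
        rows.append(row)
    return LoopEmbedding(np.asarray(coords), labels, pd.DataFrame(rows), degenerate)


# ------------------------------------------------ enhancer-promoter counts

def _overlaps(a_start, a_end, b_start, b_end, slack=0) -> bool:
    return a_start < b_end + slack and b_start - slack < a_end


def count_interacting_enhancers(
    loops: pd.DataFrame,
    promoters: pd.DataFrame,
    enhancers: pd.DataFrame,
    anchor_slack: int = 0,
) -> pd.Series:
    """Distinct interacting enhancers per gene via loop anchors.

    A gene's count is the number of distinct enhancer intervals overlapping
    (within ``anchor_slack`` bp) the distal anchor of any loop whose other
    anchor overlaps the gene's promoter. Loops with both anchors on the
    promoter are excluded. Genes absent from any loop get count 0.
    """
    hits: dict[str, set] = {name: set() for name in promoters["name"]}
    for _, lp in loops.iterrows():
        for p_cols, e_cols in (
            (("start1", "end1"), ("start2", "end2")),
            (("start2", "end2"), ("start1", "end1")),
        ):
            ps, pe = lp[p_cols[0]], lp[p_cols[1]]
            ds, de = lp[e_cols[0]], lp[e_cols[1]]
            for _, pr in promoters[promoters["chrom"] == lp["chrom"]].iterrows():
                if not _overlaps(pr["start"], pr["end"], ps, pe, anchor_slack):
                    continue
                # both anchors on the promoter -> not a distal interaction
                if _overlaps(pr["start"], pr["end"], ds, de, anchor_slack):
                    continue
                for ei, er in enhancers[enhancers["chrom"] == lp["chrom"]].iterrows():
                    if _overlaps(er["start"], er["end"], ds, de, anchor_slack):
                        hits[pr["name"]].add(ei)
    return pd.Series({g: len(s) for g, s in hits.items()}, dtype=int).sort_index()


# ------------------------------------------------------------------- BEDPE

_BEDPE_COLS = ["chrom", "start1", "end1", "chrom2", "start2", "end2", "name", "score", "strand1", "strand2"]


def write_bedpe(loops: pd.DataFrame, path) -> None:
    df = pd.DataFrame(
        {
            "chrom1": loops["chrom"],
            "start1": loops["start1"],
            "end1": loops["end1"],
            "chrom2": loops["chrom"],
            "start2": loops["start2"],
            "end2": loops["end2"],
            "name": loops.get("source", "."),
            "score": loops.get("enrichment", np.nan),
            "strand1": ".",
            "strand2": ".",
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path, bin_table=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :10]
    df.columns = ["chrom", "start1", "end1", "chrom2", "start2", "end2", "name", "score", "strand1", "strand2"]
    out = df[["chrom", "start1", "end1", "start2", "end2"]].copy()
    out["source"] = df["name"]
    out["enrichment"] = pd.to_numeric(df["score"], errors="coerce")
    if bin_table is not None:
        out["bin1"] = [bin_table.bin_id(c, int(s)) for c, s in zip(out["chrom"], out["start1"])]
        out["bin2"] = [bin_table.bin_id(c, int(s)) for c, s in zip(out["chrom"], out["start2"])]
    return out
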