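"""Diamond insulation scores, boundary calling, aggregate boundary profiles.

The insulation score of a bin is the mean balanced contact in the w x w
diamond of pairs spanning it ((b-w..b-1) x (b+1..b+w)); local minima mark
positions where contacts across the bin are depleted, i.e. TAD boundaries.
Scores are reported in log2 units normalized per chromosome so that defined
scores average zero; boundaries are strict local minima with a topographic
prominence (against the lower of the two enclosing maxima) above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .contact_core import ContactMatrix

__all__ = [
    "InsulationProfile",
    "insulation_score",
    "call_boundaries",
    "aggregate_at_boundaries",
    "consensus_boundaries",
]


@dataclass
class InsulationProfile:
    bin_table: "BinTable"
    values: np.ndarray   # per-bin log2 score, NaN = missing
    window: int          # bp


def insulation_score(matrix: ContactMatrix, window: int, use_balanced: bool = True) -> InsulationProfile:
    """Per-bin log2 diamond insulation score.

    The diamond mean is zero-inclusive over unmasked pairs; bins within one
    window of a chromosome end, masked bins, and bins with an empty or
    all-zero diamond are missing. Scores are log2 of the diamond mean,
    centered per chromosome so the mean of defined scores is zero.
    """
    bt = matrix.bin_table
    bs = bt.bin_size
    if window < 3 * bs:
        raise ValueError("window must be at least 3 bins")
    w = window // bs
    values = np.full(bt.n_bins, np.nan)
    masked = matrix.masked_bins()
    for chrom in bt.chrom_names:
        sl = bt.chrom_slice(chrom)
        n = sl.stop - sl.start
        if window > bt.chromsizes[chrom] / 4:
            raise ValueError(f"window larger than a quarter of chromosome {chrom}")
        d = matrix.dense(chrom, balanced=use_balanced)
        diamond = np.full(n, np.nan)
        for b in range(w, n - w):
            if masked[sl.start + b]:
                continue
            block = d[b - w : b, b + 1 : b + w + 1]
            good = np.isfinite(block)
            if good.any():
                diamond[b] = block[good].mean()
        with np.errstate(divide="ignore"):
            logd = np.where(diamond > 0, np.log2(diamond), np.nan)
        defined = np.isfinite(logd)
        if defined.any():
            logd = logd - logd[defined].mean()
        values[sl] = logd
    return InsulationProfile(bt, values, window)


def call_boundaries(
    profile: InsulationProfile, min_prominence: float = 0.2, max_gap: int = 2
) -> pd.DataFrame:
    """Local insulation minima with prominence >= ``min_prominence``.

    Prominence is measured against the lower of the two enclosing maxima; on
    a flat minimum the leftmost bin is reported. Interior missing runs of at
    most ``max_gap`` bins (isolated masked bins) are bridged by linear
    interpolation so a minimum flanking a masked bin is not lost; longer
    gaps split the profile. Returns a frame (chrom, start, end, bin,
    strength) with the global bin index and the prominence in log2 units.
    """
    bt = profile.bin_table
    bs = bt.bin_size
    rows = []
    for chrom in bt.chrom_names:
        sl = bt.chrom_slice(chrom)
        v = _bridge_gaps(profile.values[sl], max_gap)
        finite = np.isfinite(v)
        k = 0
        n = v.size
        while k < n:
            if not finite[k]:
                k += 1
                continue
            j = k
            while j < n and finite[j]:
                j += 1
            seg = v[k:j]
            if seg.size >= 3:
                peaks, props = find_peaks(-seg, prominence=min_prominence, plateau_size=1)
                lefts = props.get("left_edges", peaks)
                for p, left, prom in zip(peaks, lefts, props["prominences"]):
                    b = k + int(left)
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": b * bs,
                            "end": min((b + 1) * bs, bt.chromsizes[chrom]),
                            "bin": sl.start + b,
                            "strength": float(prom),
                        }
                    )
            k = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "bin", "strength"])


def _bridge_gaps(v: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_gap."""
    if max_gap <= 0:
        return v
    v = v.copy()
    finite = np.isfinite(v)
    idx = np.flatnonzero(finite)
    if idx.size < 2:
        return v
    k = 0
    n = v.size
    while k < n:
        if finite[k]:
            k += 1
            continue
        j = k
        while j < n and not finite[j]:
            j += 1
        if k > 0 and j < n and (j - k) <= max_gap:
            v[k:j] = np.interp(np.arange(k, j), [k - 1, j], [v[k - 1], v[j]])
        k = j
    return v


def aggregate_at_boundaries(
    profiles: list[InsulationProfile],
    boundaries: np.ndarray | pd.DataFrame,
    flank: int = 10,
) -> np.ndarray:
    """Mean insulation score around a set of boundary bins.

    Returns an array of shape (n_profiles, 2*flank+1) with the mean score at
    offsets -flank..+flank over all boundaries, skipping missing values and
    out-of-range offsets.
    """
    if isinstance(boundaries, pd.DataFrame):
        bins = boundaries["bin"].to_numpy()
    else:
        bins = np.asarray(boundaries, dtype=int)
    if bins.size == 0:
        raise ValueError("empty boundary set")
    out = np.full((len(profiles), 2 * flank + 1), np.nan)
    for pi, prof in enumerate(profiles):
        n = prof.values.size
        for oi, off in enumerate(range(-flank, flank + 1)):
            idx = bins + off
            ok = (idx >= 0) & (idx < n)
            vals = prof.values[idx[ok]]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                out[pi, oi] = vals.mean()
    return out


def consensus_boundaries(calls: list[pd.DataFrame], slack_bins: int = 1, min_support: int = 2) -> np.ndarray:
    """Boundary bins supported by >= ``min_support`` call sets within a slack.

    A stand-in for "boundaries identified in multiple datasets": a boundary
    from any set is kept if at least ``min_support`` sets have a call within
    ``slack_bins``; kept positions within the slack are collapsed to their
    leftmost representative.
    """
    all_bins = [np.sort(df["bin"].to_numpy()) for df in calls if len(df)]
    support_of = {}
    for bins in all_bins:
        for b in bins:
            support = sum(
                1 for other in all_bins if other.size and np.min(np.abs(other - b)) <= slack_bins
            )
            if support >= min_support:
                support_of[b] = support
    kept = np.array(sorted(support_of), dtype=int)
    out = []
    for b in kept:
        if not out or b - out[-1] > slack_bins:
            out.append(b)
    return np.array(out, dtype=int)
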