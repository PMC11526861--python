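"""Contact-frequency-vs-distance curves P(s), log-log derivatives, dynamic range.

P(s) is the mean contact value at genomic separation s, averaged in geometric
distance bins (``bins_per_decade`` per decade) from two bin widths out to the
longest chromosome, zero-inclusive over unmasked pixels, aggregated over
chromosomes weighted by valid pixel counts, and normalized to unit sum (the
curve is relative; assays differ in arbitrary units). The local log-log slope
d log P / d log s is the standard summary of decay shape; a local slope
maximum at cohesin-loop separations is the "bump" signature of loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_core import ContactMatrix, expected_by_distance

__all__ = ["ScalingCurve", "compute_ps", "ps_derivative", "fit_slope"]


@dataclass
class ScalingCurve:
    edges: np.ndarray      # geometric distance-bin edges, bp
    s_mid: np.ndarray      # geometric midpoints, bp
    P: np.ndarray          # normalized mean contact per distance bin
    n_pixels: np.ndarray   # valid pixels contributing per bin
    slope: np.ndarray | None = None

    @property
    def dynamic_range(self) -> float:
        """log10(max P / min P) over populated bins."""
        p = self.P[(self.n_pixels > 0) & (self.P > 0)]
        if p.size < 2:
            return 0.0
        return float(np.log10(p.max() / p.min()))


def compute_ps(
    matrix: ContactMatrix,
    bins_per_decade: int = 8,
    use_balanced: bool = True,
    smoothing_window: int = 5,
) -> ScalingCurve:
    """Distance-scaling curve of a contact matrix."""
    bt = matrix.bin_table
    bs = bt.bin_size
    max_len = max(bt.chromsizes.values())
    lo, hi = 2 * bs, max_len
    n_edges = max(int(np.ceil(np.log10(hi / lo) * bins_per_decade)) + 1, 2)
    edges = np.geomspace(lo, hi, n_edges)
    if edges.size - 1 < 3:
        raise ValueError("fewer than 3 usable distance bins")

    sums = np.zeros(edges.size - 1)
    npx = np.zeros(edges.size - 1)
    for chrom in bt.chrom_names:
        d = matrix.dense(chrom, balanced=use_balanced)
        n = d.shape[0]
        for sep in range(2, n):
            s_bp = sep * bs
            k = np.searchsorted(edges, s_bp, side="right") - 1
            if k < 0 or k >= edges.size - 1:
                continue
            diag = np.diagonal(d, sep)
            good = np.isfinite(diag)
            sums[k] += diag[good].sum()
            npx[k] += good.sum()

    with np.errstate(invalid="ignore"):
        P = np.where(npx > 0, sums / np.maximum(npx, 1), np.nan)
    tot = np.nansum(P)
    if tot > 0:
        P = P / tot
    s_mid = np.sqrt(edges[:-1] * edges[1:])
    curve = ScalingCurve(edges, s_mid, P, npx)
    curve.slope = ps_derivative(curve, smoothing_window)
    return curve


def ps_derivative(curve: ScalingCurve, smoothing_window: int = 5) -> np.ndarray:
    """Local least-squares slope of log P vs log s in a centered window.

    Endpoints use truncated windows; windows containing a non-positive or
    missing P yield NaN at that point.
    """
    if smoothing_window < 2:
        raise ValueError("smoothing_window must be >= 2")
    nb = curve.P.size
    if nb < smoothing_window:
        raise ValueError("curve shorter than smoothing window")
    half = smoothing_window // 2
    slope = np.full(nb, np.nan)
    for k in range(nb):
        a, b = max(0, k - half), min(nb, k + half + 1)
        p = curve.P[a:b]
        s = curve.s_mid[a:b]
        if np.any(~np.isfinite(p)) or np.any(p <= 0):
            continue
        x = np.log(s)
        y = np.log(p)
        slope[k] = np.polyfit(x, y, 1)[0]
    return slope


def fit_slope(curve: ScalingCurve, s_range: tuple[float, float]) -> float:
    """Single log-log regression slope of P(s) over a distance range (bp)."""
    sel = (curve.s_mid >= s_range[0]) & (curve.s_mid <= s_range[1])
    sel &= np.isfinite(curve.P) & (curve.P > 0) & (curve.n_pixels > 0)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 usable points in fit range")
    return float(np.polyfit(np.log(curve.s_mid[sel]), np.log(curve.P[sel]), 1)[0])
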