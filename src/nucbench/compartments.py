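"""A/B compartment calling, saddle plots and compartment strength.

The leading eigenvectors of the distance-normalized contact map (O/E - 1)
capture the plaid pattern of A/B compartmentalization; the eigenvector best
correlated with an orienting activity track (here the simulator's SON-like
speckle signal, standing in for GC content / activity) is reported per
chromosome, signed so that positive values mark A.

A saddle plot ranks bins by any per-bin track into Q equal-occupancy
quantiles and averages cis O/E within quantile pairs. With an A-high
ranking, A-A enrichment sits in the bottom-right corner, B-B in the top
left. Compartment strength is the ratio of the mean homotypic corner signal
(A-A or B-B) to the mean heterotypic (A-B) corner signal; corner means are
pair-weighted so that strengths are invariant to the arbitrary ordering of
tied ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact_core import ContactMatrix, Track, oe_transform

__all__ = [
    "CompartmentProfile",
    "SaddleResult",
    "compute_eigenvector",
    "saddle",
    "compartment_strength",
    "call_domains",
]


@dataclass
class CompartmentProfile:
    bin_table: "BinTable"
    values: np.ndarray                       # per-bin EV, NaN = missing
    explained_share: dict[str, float]        # per chromosome
    chosen_index: dict[str, int]             # which of the first n_eigs
    reference: str = ""

    def as_track(self, name: str = "EV1") -> Track:
        return Track(self.bin_table, self.values, name)


def compute_eigenvector(
    matrix: ContactMatrix,
    reference_track: Track,
    n_eigs: int = 3,
    use_balanced: bool = True,
    oe: dict[str, np.ndarray] | None = None,
) -> CompartmentProfile:
    """Compartment eigenvector per chromosome, oriented by a reference track.

    Per chromosome the dense (O/E - 1) matrix (masked rows/columns removed,
    undefined long-range entries treated as expectation) is eigendecomposed;
    among the ``n_eigs`` largest-magnitude eigenvectors the one with maximal
    |Pearson r| against the reference track is selected and signed so the
    correlation is positive. Chromosomes with fewer than 20 usable bins get
    all-missing values and a warning.
    """
    bt = matrix.bin_table
    if oe is None:
        oe = oe_transform(matrix, use_balanced=use_balanced)
    values = np.full(bt.n_bins, np.nan)
    share: dict[str, float] = {}
    chosen: dict[str, int] = {}
    for chrom in bt.chrom_names:
        m = oe[chrom]
        sl = bt.chrom_slice(chrom)
        valid = np.isfinite(m).any(axis=1)
        n_valid = int(valid.sum())
        if n_valid < 20:
            warnings.warn(f"chromosome {chrom}: only {n_valid} usable bins, eigenvector skipped")
            continue
        a = m[np.ix_(valid, valid)] - 1.0
        a[~np.isfinite(a)] = 0.0
        a = (a + a.T) / 2.0
        evals, evecs = np.linalg.eigh(a)
        order = np.argsort(-np.abs(evals))[:n_eigs]
        ref = reference_track.values[sl][valid]
        best, best_r, best_k = None, 0.0, -1
        for rank, k in enumerate(order):
            v = evecs[:, k]
            good = np.isfinite(ref)
            if good.sum() < 3 or np.std(v[good]) == 0 or np.std(ref[good]) == 0:
                continue
            r = np.corrcoef(v[good], ref[good])[0, 1]
            if abs(r) > abs(best_r):
                best, best_r, best_k = v, r, rank
        if best is None or best_r == 0.0:
            raise ValueError(f"chromosome {chrom}: eigenvector orientation undefined (zero correlation)")
        if best_r < 0:
            best = -best
        out = np.full(sl.stop - sl.start, np.nan)
        out[valid] = best
        values[sl] = out
        tot = np.abs(evals).sum()
        share[chrom] = float(np.abs(evals[order[best_k]]) / tot) if tot > 0 else 0.0
        chosen[chrom] = best_k
    return CompartmentProfile(bt, values, share, chosen, reference_track.name)


@dataclass
class SaddleResult:
    grid: np.ndarray              # Q x Q mean O/E per quantile pair
    counts: np.ndarray            # pairs per cell
    quantile_edges: np.ndarray    # track values at quantile boundaries
    corner_fraction: float
    strength_AA: float
    strength_BB: float
    per_chrom: dict = field(default_factory=dict)  # chrom -> (sum_grid, cnt_grid)


def _corner_strengths(sums: np.ndarray, cnts: np.ndarray, corner_fraction: float):
    q = sums.shape[0]
    c = max(1, int(round(corner_fraction * q)))
    aa_s, aa_n = sums[q - c :, q - c :].sum(), cnts[q - c :, q - c :].sum()
    bb_s, bb_n = sums[:c, :c].sum(), cnts[:c, :c].sum()
    ab_s = sums[:c, q - c :].sum() + sums[q - c :, :c].sum()
    ab_n = cnts[:c, q - c :].sum() + cnts[q - c :, :c].sum()
    if ab_n == 0 or ab_s == 0:
        return np.nan, np.nan
    ab = ab_s / ab_n
    aa = aa_s / aa_n if aa_n > 0 else np.nan
    bb = bb_s / bb_n if bb_n > 0 else np.nan
    return aa / ab, bb / ab


def saddle(
    oe: dict[str, np.ndarray],
    track: Track,
    Q: int = 50,
    corner_fraction: float = 0.2,
    min_sep_bins: int = 2,
) -> SaddleResult:
    """Saddle plot of cis O/E by track-quantile pair.

    ``oe`` is the per-chromosome dense O/E as returned by
    :func:`nucbench.contact_core.oe_transform`.
    """
    bt = track.bin_table
    t = track.values
    valid = np.isfinite(t)
    if valid.sum() < Q * 5:
        raise ValueError("track defined on fewer than Q*5 bins")
    tv = t[valid]
    if np.all(tv == tv[0]):
        raise ValueError("constant track: quantiles undefined")
    # equal-occupancy quantile of each valid bin (stable ranking)
    order = np.argsort(tv, kind="stable")
    ranks = np.empty(tv.size, dtype=int)
    ranks[order] = np.arange(tv.size)
    qbin_valid = np.minimum((ranks * Q) // tv.size, Q - 1)
    qbin = np.full(bt.n_bins, -1, dtype=int)
    qbin[valid] = qbin_valid
    edges = np.quantile(tv, np.linspace(0, 1, Q + 1))

    per_chrom = {}
    sums = np.zeros((Q, Q))
    cnts = np.zeros((Q, Q))
    for chrom in bt.chrom_names:
        m = oe.get(chrom)
        if m is None:
            continue
        sl = bt.chrom_slice(chrom)
        n = m.shape[0]
        i, j = np.triu_indices(n, k=min_sep_bins)
        v = m[i, j]
        qi = qbin[sl][i]
        qj = qbin[sl][j]
        ok = np.isfinite(v) & (qi >= 0) & (qj >= 0)
        s = np.zeros((Q, Q))
        c = np.zeros((Q, Q))
        np.add.at(s, (qi[ok], qj[ok]), v[ok])
        np.add.at(c, (qi[ok], qj[ok]), 1.0)
        s, c = s + s.T, c + c.T
        per_chrom[chrom] = (s, c)
        sums += s
        cnts += c

    with np.errstate(invalid="ignore"):
        grid = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    s_aa, s_bb = _corner_strengths(sums, cnts, corner_fraction)
    return SaddleResult(grid, cnts, edges, corner_fraction, s_aa, s_bb, per_chrom)


def compartment_strength(
    matrix: ContactMatrix,
    track: Track | CompartmentProfile,
    Q: int = 50,
    corner_fraction: float = 0.2,
    min_sep_bins: int = 2,
    n_boot: int = 0,
    seed: int = 0,
    oe: dict[str, np.ndarray] | None = None,
):
    """A-A and B-B compartment strengths, optional chromosome-block bootstrap CI.

    Returns ``(strength_AA, strength_BB, ci)`` where ``ci`` is None unless
    ``n_boot`` > 0 and more than one chromosome is present.
    """
    if isinstance(track, CompartmentProfile):
        track = track.as_track()
    if oe is None:
        oe = oe_transform(matrix)
    res = saddle(oe, track, Q=Q, corner_fraction=corner_fraction, min_sep_bins=min_sep_bins)
    ci = None
    chroms = list(res.per_chrom)
    if n_boot > 0 and len(chroms) > 1:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            pick = rng.choice(len(chroms), size=len(chroms), replace=True)
            s = sum(res.per_chrom[chroms[k]][0] for k in pick)
            c = sum(res.per_chrom[chroms[k]][1] for k in pick)
            reps.append(_corner_strengths(s, c, corner_fraction))
        reps = np.array(reps)
        ci = {
            "AA": tuple(np.nanpercentile(reps[:, 0], [2.5, 97.5])),
            "BB": tuple(np.nanpercentile(reps[:, 1], [2.5, 97.5])),
        }
    return res.strength_AA, res.strength_BB, ci


# ------------------------------------------------------------------- domains

def call_domains(profile: CompartmentProfile, min_size_bins: int = 1) -> pd.DataFrame:
    """Compartment domains: maximal runs of constant EV sign.

    Runs shorter than ``min_size_bins`` are merged into the flanking run with
    the larger |mean EV| (ties to the left); adjacent same-label runs then
    coalesce. Returns a BED-like frame (chrom, start, end, label, mean_ev,
    n_bins).
    """
    bt = profile.bin_table
    bs = bt.bin_size
    rows = []
    for chrom in bt.chrom_names:
        sl = bt.chrom_slice(chrom)
        v = profile.values[sl]
        runs = _sign_runs(v)
        if not runs:
            continue
        runs = _merge_short_runs(runs, v, min_size_bins)
        size = bt.chromsizes[chrom]
        for a, b, lab in runs:
            vals = v[a:b]
            rows.append(
                {
                    "chrom": chrom,
                    "start": a * bs,
                    "end": min(b * bs, size),
                    "label": "A" if lab > 0 else "B",
                    "mean_ev": float(np.nanmean(vals)),
                    "n_bins": b - a,
                }
            )
    return pd.DataFrame(rows)


def _sign_runs(v: np.ndarray):
    """Maximal runs [(start, end, sign)] over finite nonzero-sign bins."""
    runs = []
    cur = None
    for k, x in enumerate(v):
        s = 0 if not np.isfinite(x) else int(np.sign(x))
        if s == 0:
            cur = None
            continue
        if cur is not None and cur[2] == s:
            cur[1] = k + 1
        else:
            cur = [k, k + 1, s]
            runs.append(cur)
    return [tuple(r) for r in runs]


def _merge_short_runs(runs, v, min_size):
    runs = [list(r) for r in runs]

    def mean_abs(r):
        return abs(np.nanmean(v[r[0] : r[1]]))

    while True:
        short = [
            (r[1] - r[0], k) for k, r in enumerate(runs) if r[1] - r[0] < min_size and len(runs) > 1
        ]
        if not short:
            break
        _, k = min(short)  # shortest, leftmost on tie
        left = runs[k - 1] if k > 0 else None
        right = runs[k + 1] if k + 1 < len(runs) else None
        if left is not None and (right is None or mean_abs(left) >= mean_abs(right)):
            tgt, drop = k - 1, k
            runs[tgt][1] = runs[drop][1]
        else:
            tgt, drop = k + 1, k
            runs[tgt][0] = runs[drop][0]
        del runs[drop]
        # coalesce adjacent same-sign runs
        k = 0
        while k + 1 < len(runs):
            if runs[k][2] == runs[k + 1][2] and runs[k][1] >= runs[k + 1][0]:
                runs[k][1] = runs[k + 1][1]
                del runs[k + 1]
            else:
                k += 1
    return [tuple(r) for r in runs]


def domain_size_cdf(domains: pd.DataFrame):
    """Sorted domain sizes (bp) and their empirical CDF values."""
    sizes = np.sort((domains["end"] - domains["start"]).to_numpy())
    return sizes, np.arange(1, sizes.size + 1) / sizes.size
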