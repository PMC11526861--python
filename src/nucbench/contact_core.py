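"""Binned contact-matrix data model, I/O, balancing and distance normalization.

The central objects are :class:`BinTable` (the genome coordinate system: fixed-size
bins tiling each chromosome, indexed globally), :class:`ContactMatrix` (upper-triangle
sparse counts on those bins, with optional per-bin balancing weights) and
:class:`Track` (one real value per bin, NaN = missing).

Conventions: coordinates are 0-based half-open (BED); bin index = floor(start /
bin_size); the matrix stores each unordered pair once with bin1 <= bin2; a balanced
pixel value is count * w_i * w_j, and masked bins carry NaN weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "BinTable",
    "ContactMatrix",
    "Track",
    "read_matrix",
    "write_matrix",
    "balance_ic",
    "expected_by_distance",
    "oe_transform",
    "cis_trans_fraction",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass(frozen=True)
class BinTable:
    """Fixed-size bins tiling an ordered set of chromosomes.

    Bins run left-to-right per chromosome with no gaps; the last bin of a
    chromosome may be short. Global bin indices are contiguous from 0 in
    chromosome order.
    """

    chromsizes: dict[str, int]
    bin_size: int

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not self.chromsizes:
            raise ValueError("need at least one chromosome")
        for name, length in self.chromsizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chromsizes)

    def chrom_nbins(self, chrom: str) -> int:
        return -(-self.chromsizes[chrom] // self.bin_size)

    @property
    def n_bins(self) -> int:
        return sum(self.chrom_nbins(c) for c in self.chromsizes)

    @property
    def chrom_offsets(self) -> dict[str, int]:
        out, pos = {}, 0
        for c in self.chromsizes:
            out[c] = pos
            pos += self.chrom_nbins(c)
        return out

    def chrom_slice(self, chrom: str) -> slice:
        off = self.chrom_offsets[chrom]
        return slice(off, off + self.chrom_nbins(chrom))

    def bins(self) -> pd.DataFrame:
        """Bin table as a (chrom, start, end) DataFrame in global-index order."""
        rows = []
        for c, size in self.chromsizes.items():
            starts = np.arange(0, size, self.bin_size)
            ends = np.minimum(starts + self.bin_size, size)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def bin_id(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.chromsizes[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return self.chrom_offsets[chrom] + pos // self.bin_size

    def chrom_of_bins(self, bin_ids: np.ndarray) -> np.ndarray:
        """Integer chromosome id for each global bin index."""
        edges = np.cumsum([self.chrom_nbins(c) for c in self.chromsizes])
        return np.searchsorted(edges, np.asarray(bin_ids), side="right")

    def same_chrom(self, b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
        return self.chrom_of_bins(b1) == self.chrom_of_bins(b2)


class ContactMatrix:
    """Symmetric binned contact matrix in upper-triangle sparse form."""

    def __init__(
        self,
        bin_table: BinTable,
        bin1: np.ndarray,
        bin2: np.ndarray,
        count: np.ndarray,
        weights: np.ndarray | None = None,
    ):
        bin1 = np.asarray(bin1, dtype=np.int64)
        bin2 = np.asarray(bin2, dtype=np.int64)
        count = np.asarray(count, dtype=np.float64)
        if not (bin1.shape == bin2.shape == count.shape):
            raise ValueError("bin1, bin2, count must have equal length")
        n = bin_table.n_bins
        if bin1.size and (bin1.min() < 0 or bin2.max() >= n):
            raise ValueError("bin index out of range")
        if np.any(bin1 > bin2):
            raise ValueError("pixels must satisfy bin1 <= bin2 (upper triangle)")
        if np.any(count < 0):
            raise ValueError("counts must be non-negative")
        # duplicate check on sorted keys
        order = np.lexsort((bin2, bin1))
        b1s, b2s = bin1[order], bin2[order]
        dup = (b1s[1:] == b1s[:-1]) & (b2s[1:] == b2s[:-1])
        if np.any(dup):
            k = np.argmax(dup)
            raise ValueError(f"duplicate pixel ({b1s[k]}, {b2s[k]})")
        self.bin_table = bin_table
        self.bin1 = b1s
        self.bin2 = b2s
        self.count = count[order]
        if weights is not None:
            weights = np.asarray(weights, dtype=np.float64)
            if weights.shape != (n,):
                raise ValueError("weights must have one entry per bin")
        self.weights = weights
        self.balance_info: dict = {}

    # ------------------------------------------------------------------ basics
    @property
    def n_bins(self) -> int:
        return self.bin_table.n_bins

    @property
    def n_pixels(self) -> int:
        return self.bin1.size

    def total(self) -> float:
        return float(self.count.sum())

    def is_cis(self) -> np.ndarray:
        return self.bin_table.same_chrom(self.bin1, self.bin2)

    def masked_bins(self) -> np.ndarray:
        """Boolean mask of bins excluded by balancing (NaN weight)."""
        if self.weights is None:
            return np.zeros(self.n_bins, dtype=bool)
        return ~np.isfinite(self.weights)

    def dense(self, chrom: str, balanced: bool = False) -> np.ndarray:
        """Dense symmetric block for one chromosome.

        When ``balanced`` the values are count * w_i * w_j and rows/columns of
        masked bins are NaN.
        """
        sl = self.bin_table.chrom_slice(chrom)
        n = sl.stop - sl.start
        sel = (self.bin1 >= sl.start) & (self.bin1 < sl.stop) & (self.bin2 >= sl.start) & (self.bin2 < sl.stop)
        i = self.bin1[sel] - sl.start
        j = self.bin2[sel] - sl.start
        v = self.count[sel]
        if balanced:
            if self.weights is None:
                raise ValueError("matrix has no balancing weights")
            w = self.weights[sl]
            v = v * w[i] * w[j]
        m = np.zeros((n, n))
        m[i, j] = v
        m[j, i] = v
        if balanced:
            bad = ~np.isfinite(self.weights[sl])
            m[bad, :] = np.nan
            m[:, bad] = np.nan
        return m

    def marginals(self) -> np.ndarray:
        """Raw coverage per bin (diagonal counted once)."""
        m = np.bincount(self.bin1, weights=self.count, minlength=self.n_bins)
        off = self.bin1 != self.bin2
        m += np.bincount(self.bin2[off], weights=self.count[off], minlength=self.n_bins)
        return m


@dataclass
class Track:
    """Per-bin real-valued signal; NaN marks missing values (never imputed)."""

    bin_table: BinTable
    values: np.ndarray
    name: str = "track"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.bin_table.n_bins,):
            raise ValueError("track length must equal number of bins")


# ============================================================================ I/O

_COOL_FORMAT = "HDF5::Cooler"


def write_matrix(matrix: ContactMatrix, path: str | Path, format: str = "cool") -> None:
    """Write a matrix as a single-resolution cooler-schema HDF5 file or COO text.

    COO text format: `bin1_id TAB bin2_id TAB count` with a `<path>.bins.bed`
    sidecar holding chrom/start/end (and weight when present).
    """
    path = Path(path)
    bt = matrix.bin_table
    if format == "cool":
        with h5py.File(path, "w") as f:
            f.attrs["format"] = _COOL_FORMAT
            f.attrs["format-version"] = 3
            f.attrs["bin-type"] = "fixed"
            f.attrs["bin-size"] = bt.bin_size
            f.attrs["nbins"] = bt.n_bins
            f.attrs["nchroms"] = len(bt.chromsizes)
            f.attrs["nnz"] = matrix.n_pixels
            g = f.create_group("chroms")
            g.create_dataset("name", data=np.array(bt.chrom_names, dtype="S32"))
            g.create_dataset("length", data=np.array(list(bt.chromsizes.values()), dtype=np.int64))
            bins = bt.bins()
            cid = bt.chrom_of_bins(np.arange(bt.n_bins))
            g = f.create_group("bins")
            g.create_dataset("chrom", data=cid.astype(np.int32))
            g.create_dataset("start", data=bins["start"].to_numpy(np.int64))
            g.create_dataset("end", data=bins["end"].to_numpy(np.int64))
            if matrix.weights is not None:
                g.create_dataset("weight", data=matrix.weights)
            g = f.create_group("pixels")
            g.create_dataset("bin1_id", data=matrix.bin1)
            g.create_dataset("bin2_id", data=matrix.bin2)
            g.create_dataset("count", data=matrix.count)
            g = f.create_group("indexes")
            offsets = np.array(list(bt.chrom_offsets.values()) + [bt.n_bins], dtype=np.int64)
            g.create_dataset("chrom_offset", data=offsets)
            g.create_dataset("bin1_offset", data=np.searchsorted(matrix.bin1, np.arange(bt.n_bins + 1)))
    elif format == "coo_text":
        df = pd.DataFrame({"bin1_id": matrix.bin1, "bin2_id": matrix.bin2, "count": matrix.count})
        df.to_csv(path, sep="\t", index=False, header=False)
        bins = bt.bins()
        if matrix.weights is not None:
            bins = bins.assign(weight=matrix.weights)
        bins.to_csv(str(path) + ".bins.bed", sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown format: {format}")


def read_matrix(path: str | Path, format: str = "cool") -> ContactMatrix:
    path = Path(path)
    if format == "cool":
        with h5py.File(path, "r") as f:
            names = [n.decode() for n in f["chroms/name"][:]]
            lengths = f["chroms/length"][:]
            bin_size = int(f.attrs["bin-size"])
            bt = BinTable(dict(zip(names, map(int, lengths))), bin_size)
            starts = f["bins/start"][:]
            _check_uniform_bins(bt, f["bins/chrom"][:], starts, names)
            weights = f["bins/weight"][:] if "weight" in f["bins"] else None
            return ContactMatrix(bt, f["pixels/bin1_id"][:], f["pixels/bin2_id"][:], f["pixels/count"][:], weights)
    elif format == "coo_text":
        bins = pd.read_csv(str(path) + ".bins.bed", sep="\t", header=None)
        bins.columns = ["chrom", "start", "end", "weight"][: bins.shape[1]]
        chromsizes = bins.groupby("chrom", sort=False)["end"].max().to_dict()
        sizes = bins.groupby("chrom", sort=False).size()
        bin_size = int((bins["end"] - bins["start"]).max())
        bt = BinTable({c: int(v) for c, v in chromsizes.items()}, bin_size)
        for c in chromsizes:
            if bt.chrom_nbins(c) != sizes[c]:
                raise ValueError(f"non-uniform binning on chromosome {c}")
        df = pd.read_csv(path, sep="\t", header=None, names=["bin1_id", "bin2_id", "count"])
        weights = bins["weight"].to_numpy() if "weight" in bins else None
        return ContactMatrix(bt, df["bin1_id"].to_numpy(), df["bin2_id"].to_numpy(), df["count"].to_numpy(), weights)
    raise ValueError(f"unknown format: {format}")


def _check_uniform_bins(bt: BinTable, chrom_ids, starts, names) -> None:
    for k, c in enumerate(names):
        s = starts[chrom_ids == k]
        step = np.diff(s)
        if s.size > 1 and not np.all(step == bt.bin_size):
            raise ValueError(f"non-uniform binning on chromosome {c}")


def write_bedgraph(track: Track, path: str | Path) -> None:
    bins = track.bin_table.bins().assign(value=track.values)
    bins.dropna(subset=["value"]).to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path: str | Path, bin_table: BinTable, name: str = "track") -> Track:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    values = np.full(bin_table.n_bins, np.nan)
    for chrom, start, value in zip(df["chrom"], df["start"], df["value"]):
        values[bin_table.bin_id(chrom, int(start))] = value
    return Track(bin_table, values, name)


# ===================================================================== balancing

def balance_ic(
    matrix: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mad_max: float = 5.0,
) -> ContactMatrix:
    """Iterative-correction (matrix balancing) with MAD-max coverage filtering.

    Bins whose log coverage falls more than ``mad_max`` median absolute
    deviations below the median (or with zero coverage) are masked (NaN
    weight). The remaining weights are iterated until the coefficient of
    variation of balanced marginals drops below ``tol``. Weights are scaled so
    the total balanced mass equals the total raw count. Convergence details
    are stored in ``result.balance_info``.
    """
    cis = matrix.is_cis()
    if not np.any(cis & (matrix.count > 0)):
        raise ValueError("matrix has no cis pixels; cannot balance")
    cov = matrix.marginals()
    mask = cov <= 0
    if np.any(~mask):
        logm = np.log(cov[~mask])
        med = np.median(logm)
        mad = np.median(np.abs(logm - med))
        if mad > 0:
            bad = np.zeros_like(mask)
            bad[~mask] = logm < med - mad_max * mad
            mask |= bad
    if mask.all():
        raise ValueError("all bins masked by coverage filter")

    b1, b2, c = matrix.bin1, matrix.bin2, matrix.count
    keep = ~(mask[b1] | mask[b2])
    b1k, b2k, ck = b1[keep], b2[keep], c[keep]
    n = matrix.n_bins
    w = np.ones(n)
    w[mask] = 0.0
    converged = False
    cv = np.inf
    for it in range(1, max_iter + 1):
        v = ck * w[b1k] * w[b2k]
        m = np.bincount(b1k, weights=v, minlength=n)
        off = b1k != b2k
        m += np.bincount(b2k[off], weights=v[off], minlength=n)
        mm = m[~mask]
        mean = mm.mean()
        if mean == 0:
            raise ValueError("balanced marginals collapsed to zero")
        cv = mm.std() / mean
        if cv < tol:
            converged = True
            break
        upd = np.ones(n)
        upd[~mask] = mm / mean
        upd[upd == 0] = 1.0
        w /= np.sqrt(upd)
    # scale: total balanced mass == total raw mass
    v = ck * w[b1k] * w[b2k]
    tot = v.sum()
    if tot > 0:
        w *= np.sqrt(c.sum() / tot)
    weights = np.where(mask, np.nan, w)
    out = ContactMatrix(matrix.bin_table, b1, b2, c, weights)
    out.balance_info = {"converged": converged, "iterations": it, "cv": float(cv), "n_masked": int(mask.sum())}
    return out


# ============================================== expected / O/E / cis-trans

def expected_by_distance(matrix: ContactMatrix, use_balanced: bool = True) -> dict[str, np.ndarray]:
    """Per-chromosome mean contact value at each bin separation.

    Zero-inclusive: every unmasked pixel at a separation contributes, whether
    or not a contact was observed; masked bins are excluded from numerator and
    denominator.
    """
    if use_balanced and matrix.weights is None:
        raise ValueError("balanced expected requested but no weights present")
    out = {}
    for chrom in matrix.bin_table.chrom_names:
        d = matrix.dense(chrom, balanced=use_balanced)
        n = d.shape[0]
        exp = np.full(n, np.nan)
        for sep in range(n):
            diag = np.diagonal(d, sep)
            good = np.isfinite(diag)
            if good.any():
                exp[sep] = diag[good].mean()
        out[chrom] = exp
    return out


def oe_transform(
    matrix: ContactMatrix,
    expected: dict[str, np.ndarray] | None = None,
    use_balanced: bool = True,
) -> dict[str, np.ndarray]:
    """Observed/expected dense matrix per chromosome.

    Entries at masked bins or where the distance-expected is zero/undefined
    are NaN.
    """
    if expected is None:
        expected = expected_by_distance(matrix, use_balanced=use_balanced)
    out = {}
    for chrom in matrix.bin_table.chrom_names:
        d = matrix.dense(chrom, balanced=use_balanced)
        n = d.shape[0]
        idx = np.arange(n)
        sep = np.abs(idx[:, None] - idx[None, :])
        e = expected[chrom][sep]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(e > 0, d / e, np.nan)
        out[chrom] = oe
    return out


def cis_trans_fraction(matrix: ContactMatrix) -> float:
    """Fraction of contacts with both ends on one chromosome."""
    tot = matrix.total()
    if tot == 0:
        raise ValueError("matrix has zero total count")
    return float(matrix.count[matrix.is_cis()].sum() / tot)
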