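"""Binned contact matrices with the {1, NaN} weight convention and cooler-schema IO.

Maps produced and consumed here are sparse single-cell or merged matrices that
are deliberately *not* balanced: bins with any coverage get weight 1, bins with
zero coverage get weight NaN.  The HDF5 layout follows the cooler
single-resolution schema (groups ``chroms``, ``bins``, ``pixels``, ``indexes``)
so files interoperate with external cooler tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["ContactMap", "read_cool", "write_cool"]

COOLER_FORMAT = "HDF5::Cooler"
COOLER_VERSION = 3


@dataclass
class ContactMap:
    """Symmetric binned contact matrix for one chromosome (or region).

    Parameters
    ----------
    matrix:
        Dense symmetric ``(n, n)`` array of contact counts (or O/E values).
    resolution:
        Bin size in bp.
    chrom:
        Chromosome / region name.
    start:
        Genomic coordinate (bp) of the left edge of bin 0.
    weights:
        Per-bin weights; exactly 1.0 for covered bins and NaN for bins with
        zero coverage.  Computed from the matrix when not supplied.
    """

    matrix: np.ndarray
    resolution: int
    chrom: str = "chrS"
    start: int = 0
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.weights is None:
            cov = np.nansum(self.matrix, axis=0) > 0
            self.weights = np.where(cov, 1.0, np.nan)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_bins,):
                raise ValueError("weights length must match bin count")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def length_bp(self) -> int:
        return self.n_bins * self.resolution

    def bin_of(self, pos_bp: float) -> int:
        """Bin index of a genomic position (bp, region coordinates)."""
        return int((pos_bp - self.start) // self.resolution)

    def covered(self) -> np.ndarray:
        """Boolean mask of bins with non-zero coverage."""
        return np.isfinite(self.weights)

    def total_contacts(self) -> float:
        """Sum of the upper triangle plus diagonal (each contact once)."""
        return float(np.nansum(np.triu(self.matrix)))

    def observed_over_expected(self) -> "ContactMap":
        """Distance-normalized map: each diagonal divided by its mean.

        Expected at separation d is the mean raw value over pairs of covered
        bins at that separation.  Bins without coverage propagate NaN.
        """
        n = self.n_bins
        cov = self.covered()
        oe = np.full((n, n), np.nan)
        mat = self.matrix
        for d in range(n):
            i = np.arange(n - d)
            j = i + d
            ok = cov[i] & cov[j]
            if not ok.any():
                continue
            exp = np.nanmean(mat[i[ok], j[ok]])
            if exp > 0:
                vals = mat[i, j] / exp
                vals[~ok] = np.nan
                oe[i, j] = vals
                oe[j, i] = vals
        return ContactMap(oe, self.resolution, self.chrom, self.start,
                          weights=self.weights.copy())


def write_cool(path: str, cmap: ContactMap, group: str | None = None) -> None:
    """Write a :class:`ContactMap` as a cooler single-resolution HDF5 file.

    ``group`` may point inside the file (e.g. ``resolutions/16000`` for an
    mcool-style layout).
    """
    n = cmap.n_bins
    res = cmap.resolution
    iu, ju = np.triu_indices(n)
    counts = cmap.matrix[iu, ju]
    keep = np.isfinite(counts) & (counts != 0)
    bin1, bin2, counts = iu[keep], ju[keep], counts[keep]

    with h5py.File(path, "a") as f:
        grp = f.require_group(group) if group else f
        for key in ("chroms", "bins", "pixels", "indexes"):
            if key in grp:
                del grp[key]
        grp.attrs["format"] = COOLER_FORMAT
        grp.attrs["format-version"] = COOLER_VERSION
        grp.attrs["bin-size"] = res
        grp.attrs["bin-type"] = "fixed"
        grp.attrs["symmetric-upper"] = True
        grp.attrs["storage-mode"] = "symmetric-upper"
        grp.attrs["nbins"] = n
        grp.attrs["nchroms"] = 1
        grp.attrs["nnz"] = len(counts)
        grp.attrs["region-start"] = cmap.start

        chroms = grp.create_group("chroms")
        chroms.create_dataset(
            "name", data=np.array([cmap.chrom.encode()], dtype="S32"))
        chroms.create_dataset(
            "length", data=np.array([cmap.start + n * res], dtype=np.int64))

        bins = grp.create_group("bins")
        starts = cmap.start + res * np.arange(n, dtype=np.int64)
        bins.create_dataset("chrom", data=np.zeros(n, dtype=np.int32))
        bins.create_dataset("start", data=starts)
        bins.create_dataset("end", data=starts + res)
        bins.create_dataset("weight", data=cmap.weights)

        pixels = grp.create_group("pixels")
        pixels.create_dataset("bin1_id", data=bin1.astype(np.int64))
        pixels.create_dataset("bin2_id", data=bin2.astype(np.int64))
        pixels.create_dataset("count", data=counts)

        indexes = grp.create_group("indexes")
        chrom_offset = np.array([0, n], dtype=np.int64)
        bin1_offset = np.searchsorted(bin1, np.arange(n + 1))
        indexes.create_dataset("chrom_offset", data=chrom_offset)
        indexes.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))


def read_cool(path: str, group: str | None = None) -> ContactMap:
    """Read a single-chromosome cooler-schema file back into a dense map."""
    with h5py.File(path, "r") as f:
        grp = f[group] if group else f
        res = int(grp.attrs["bin-size"])
        n = int(grp.attrs["nbins"])
        chrom = grp["chroms/name"][0].decode()
        start = int(grp.attrs.get("region-start", 0))
        weights = grp["bins/weight"][:]
        b1 = grp["pixels/bin1_id"][:]
        b2 = grp["pixels/bin2_id"][:]
        cnt = grp["pixels/count"][:].astype(float)
    mat = np.zeros((n, n))
    mat[b1, b2] = cnt
    mat[b2, b1] = cnt
    return ContactMap(mat, res, chrom, start, weights=weights)
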