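"""Contact-map statistics: cross-pattern score, diamond insulation,
random-shift pileups, rescaled interval pileups, quadrant insulation,
saddle compartment strength and contact-composition fractions.

All operations work on dense :class:`~lampsim.contactmap.ContactMap` objects
and honor the {1, NaN} weight convention (NaN-weighted bins are excluded from
means and propagate NaN in per-bin tracks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contactmap import ContactMap

__all__ = [
    "Pileup", "cps_track", "diamond_insulation", "pileup_local",
    "pileup_rescaled", "quadrant_insulation_score", "saddle_strength",
    "contact_fractions", "read_bedgraph", "write_bedgraph",
]


@dataclass
class Pileup:
    matrix: np.ndarray
    resolution: int
    n_used: int
    n_dropped: int = 0


def _sat(mat: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero border; NaN treated as 0."""
    s = np.zeros((mat.shape[0] + 1, mat.shape[1] + 1))
    s[1:, 1:] = np.nancumsum(np.nancumsum(np.nan_to_num(mat), axis=0), axis=1)
    return s


def _rect(sat: np.ndarray, i0: np.ndarray, i1: np.ndarray,
          j0: np.ndarray, j1: np.ndarray) -> np.ndarray:
    """Inclusive rectangle sums [i0..i1] x [j0..j1] from a summed-area table."""
    return (sat[i1 + 1, j1 + 1] - sat[i0, j1 + 1]
            - sat[i1 + 1, j0] + sat[i0, j0])


def cps_track(cmap: ContactMap, s_bp: float = 35_000.0,
              w_bp: float = 4_000_000.0) -> np.ndarray:
    """Cross-pattern score per bin.

    For bin ``n`` with half-windows ``s`` (narrow) and ``W`` (wide), both in
    bins and truncated at the chromosome ends::

        CPS_n = (band_row + band_col - 2 * square) / square

    where ``band_row`` sums contacts over rows ``n-W..n+W`` and columns
    ``n-s..n+s``, ``band_col`` is the transpose band and ``square`` is the
    ``(2s+1)^2`` local block.  Low values mean contacts confined near the
    diagonal (a "cross" locus).  NaN where the local square is empty.
    """
    res = cmap.resolution
    sb = int(round(s_bp / res))
    wb = int(round(w_bp / res))
    if sb >= wb:
        raise ValueError("narrow half-window s must be smaller than W")
    n = cmap.n_bins
    sat = _sat(cmap.matrix)
    idx = np.arange(n)
    s0 = np.clip(idx - sb, 0, n - 1)
    s1 = np.clip(idx + sb, 0, n - 1)
    w0 = np.clip(idx - wb, 0, n - 1)
    w1 = np.clip(idx + wb, 0, n - 1)
    band_row = _rect(sat, w0, w1, s0, s1)
    band_col = _rect(sat, s0, s1, w0, w1)
    square = _rect(sat, s0, s1, s0, s1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cps = (band_row + band_col - 2.0 * square) / square
    cps[square <= 0] = np.nan
    return cps


def diamond_insulation(cmap: ContactMap, window_bp: float = 2_000_000.0,
                       log2_normalize: bool = True) -> np.ndarray:
    """Per-bin mean of contacts in the window x window square crossing the
    bin, optionally log2-normalized by the chromosome-wide mean."""
    res = cmap.resolution
    w = int(round(window_bp / res))
    n = cmap.n_bins
    if w < 1 or w > n:
        raise ValueError("window must be between one bin and the chromosome")
    cov = cmap.covered()
    track = np.full(n, np.nan)
    mat = cmap.matrix
    for i in range(w, n - w):
        rows = slice(i - w, i)
        cols = slice(i + 1, i + 1 + w)
        mask = np.outer(cov[rows], cov[cols])
        if not mask.any():
            continue
        track[i] = mat[rows, cols][mask].mean()
    if log2_normalize:
        mean = np.nanmean(track)
        with np.errstate(invalid="ignore", divide="ignore"):
            track = np.log2(track / mean)
    return track


def pileup_local(cmap: ContactMap, anchors_bp, flank_bp: float,
                 maxshift_bp: float = 2_000_000.0, n_controls: int = 10,
                 rng: np.random.Generator | None = None) -> Pileup:
    """Anchor-centered diagonal pileup normalized by randomly shifted
    controls.

    Each anchor contributes its (2f+1)^2 on-diagonal submatrix; the control
    is the mean over ``n_controls`` submatrices per anchor whose centers are
    shifted by a uniform nonzero offset within +/- ``maxshift_bp``.  Anchors
    (or controls) whose window leaves the chromosome are dropped.
    """
    rng = rng or np.random.default_rng()
    res = cmap.resolution
    f = int(round(flank_bp / res))
    ms = max(1, int(round(maxshift_bp / res)))
    n = cmap.n_bins
    obs = []
    ctl = []
    dropped = 0
    for a in np.atleast_1d(anchors_bp):
        c = cmap.bin_of(a)
        if c - f < 0 or c + f >= n:
            dropped += 1
            continue
        obs.append(cmap.matrix[c - f:c + f + 1, c - f:c + f + 1])
        got = 0
        tries = 0
        while got < n_controls and tries < 50 * n_controls:
            tries += 1
            shift = int(rng.integers(-ms, ms + 1))
            if shift == 0:
                continue
            cc = c + shift
            if cc - f < 0 or cc + f >= n:
                continue
            ctl.append(cmap.matrix[cc - f:cc + f + 1, cc - f:cc + f + 1])
            got += 1
    if not obs:
        raise ValueError("no usable anchors")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mo = np.nanmean(np.stack(obs), axis=0)
        mc = np.nanmean(np.stack(ctl), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = mo / mc
    return Pileup(ratio, res, n_used=len(obs), n_dropped=dropped)


def pileup_rescaled(map_oe: ContactMap, intervals_bp, flank_units: int = 6,
                    body_px: int = 6, flank_px: int = 33) -> Pileup:
    """Average O/E submatrices around intervals rescaled to a fixed grid.

    Each interval of length L is extended by ``flank_units * L`` on both
    sides; the window is sampled onto a grid where the body occupies
    ``body_px`` of ``2*flank_px + body_px`` pixels (defaults put the body at
    1/12 of the width).  Sampling is nearest-bin at pixel centers.  Intervals
    shorter than two bins, or whose window leaves the map, are skipped.
    """
    res = map_oe.resolution
    n = map_oe.n_bins
    npx = 2 * flank_px + body_px
    acc = np.zeros((npx, npx))
    cnt = np.zeros((npx, npx))
    used = 0
    dropped = 0
    for (a, b) in intervals_bp:
        L = b - a
        if L < 2 * res:
            warnings.warn("interval shorter than two bins skipped")
            dropped += 1
            continue
        lo = a - flank_units * L
        hi = b + flank_units * L
        if lo < map_oe.start or hi > map_oe.start + n * res:
            dropped += 1
            continue
        # pixel-center genomic coordinates: flank | body | flank
        px_left = lo + (np.arange(flank_px) + 0.5) * (flank_units * L / flank_px)
        px_body = a + (np.arange(body_px) + 0.5) * (L / body_px)
        px_right = b + (np.arange(flank_px) + 0.5) * (flank_units * L / flank_px)
        centers = np.concatenate([px_left, px_body, px_right])
        bins = np.clip(((centers - map_oe.start) // res).astype(int), 0, n - 1)
        sub = map_oe.matrix[np.ix_(bins, bins)]
        ok = np.isfinite(sub)
        acc[ok] += sub[ok]
        cnt[ok] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable intervals")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt
    return Pileup(mean, res, n_used=used, n_dropped=dropped)


def quadrant_insulation_score(pileup: Pileup | np.ndarray) -> float:
    """Relative mean signal of the diagonal quadrants (Q1, Q3) over the
    cross quadrants (Q2, Q4), split at the matrix center.

    Higher values indicate stronger spatial separation across the center.
    An odd-sided matrix drops the central row/column.
    """
    mat = pileup.matrix if isinstance(pileup, Pileup) else np.asarray(pileup)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("pileup must be square")
    s = mat.shape[0]
    m = s // 2
    if s % 2 == 1:
        mat = np.delete(np.delete(mat, m, axis=0), m, axis=1)
    q1 = mat[:m, :m]
    q3 = mat[m:, m:]
    q2 = mat[:m, m:]
    q4 = mat[m:, :m]
    intra = np.nanmean(np.concatenate([q1.ravel(), q3.ravel()]))
    inter = np.nanmean(np.concatenate([q2.ravel(), q4.ravel()]))
    if not np.isfinite(inter) or inter == 0:
        return float("nan")
    return float(intra / inter)


def saddle_strength(map_oe: ContactMap, eigenvector: np.ndarray,
                    n_bins: int = 40, exclude_extremes: int = 1):
    """Percentile-binned saddle matrix and (AA+BB)/(AB+BA) strength.

    The eigenvector is an external compartment annotation at map resolution.
    Bins are equal-occupancy percentile groups; ``exclude_extremes`` groups
    are dropped at each end; the strength ratio uses the corner quarters of
    the remaining saddle.
    """
    ev = np.asarray(eigenvector, dtype=float)
    if ev.shape[0] != map_oe.n_bins:
        raise ValueError("eigenvector length must match bin count")
    ok = np.isfinite(ev) & map_oe.covered()
    if not ok.any():
        raise ValueError("eigenvector has no finite values on covered bins")
    idx = np.where(ok)[0]
    order = np.argsort(ev[idx], kind="stable")
    groups = np.array_split(idx[order], n_bins)
    groups = groups[exclude_extremes:len(groups) - exclude_extremes]
    g = len(groups)
    saddle = np.full((g, g), np.nan)
    for p in range(g):
        for q in range(p, g):
            block = map_oe.matrix[np.ix_(groups[p], groups[q])]
            v = np.nanmean(block) if np.isfinite(block).any() else np.nan
            saddle[p, q] = saddle[q, p] = v
    k = max(1, g // 4)
    bb = np.nanmean(saddle[:k, :k])
    aa = np.nanmean(saddle[-k:, -k:])
    ab = np.nanmean(saddle[:k, -k:])
    ba = np.nanmean(saddle[-k:, :k])
    strength = (aa + bb) / (ab + ba)
    return float(strength), saddle


def contact_fractions(contacts: pd.DataFrame, domains=None,
                      qc_cap: int = 8) -> dict:
    """Composition report for a contact list.

    ``contacts`` needs columns chrom1, pos1, chrom2, pos2 (one row per
    contact).  Returns the trans fraction; with ``domains`` (sorted
    non-overlapping (chrom, start, end) records), the fraction of cis
    contacts with both ends inside domains that join *adjacent* domains; and
    the number of sites whose unique-partner count exceeds ``qc_cap``.
    """
    if len(contacts) == 0:
        raise ValueError("empty contact list")
    trans = contacts["chrom1"] != contacts["chrom2"]
    report = {"n_contacts": int(len(contacts)),
              "trans_fraction": float(trans.mean())}

    sites = pd.concat([
        contacts[["chrom1", "pos1"]].rename(columns={"chrom1": "c", "pos1": "p"}),
        contacts[["chrom2", "pos2"]].rename(columns={"chrom2": "c", "pos2": "p"}),
    ])
    partners = pd.DataFrame({
        "site": sites["c"].astype(str) + ":" + sites["p"].astype(str),
        "other": pd.concat([
            contacts["chrom2"].astype(str) + ":" + contacts["pos2"].astype(str),
            contacts["chrom1"].astype(str) + ":" + contacts["pos1"].astype(str),
        ]),
    })
    uniq = partners.drop_duplicates().groupby("site").size()
    report["n_sites_over_cap"] = int((uniq > qc_cap).sum())

    if domains is not None:
        dom = pd.DataFrame(domains, columns=["chrom", "start", "end"])
        dom = dom.sort_values(["chrom", "start"]).reset_index(drop=True)
        dom["rank"] = dom.groupby("chrom").cumcount()
        cis = contacts[~trans]

        def locate(chroms, poss):
            out = np.full(len(chroms), -1)
            for c, sub in dom.groupby("chrom"):
                mask = (chroms == c).to_numpy()
                if not mask.any():
                    continue
                starts = sub["start"].to_numpy()
                ends = sub["end"].to_numpy()
                ranks = sub["rank"].to_numpy()
                p = poss[mask].to_numpy()
                j = np.searchsorted(starts, p, side="right") - 1
                good = (j >= 0) & (p < ends[np.clip(j, 0, None)])
                res = np.full(mask.sum(), -1)
                res[good] = ranks[j[good]]
                out[mask] = res
            return out

        d1 = locate(cis["chrom1"], cis["pos1"])
        d2 = locate(cis["chrom2"], cis["pos2"])
        both = (d1 >= 0) & (d2 >= 0)
        if both.any():
            adjacent = np.abs(d1[both] - d2[both]) == 1
            report["neighboring_domain_fraction"] = float(adjacent.mean())
        else:
            report["neighboring_domain_fraction"] = float("nan")
    return report


def read_bedgraph(path: str, resolution: int, chrom_length: int,
                  chrom: str | None = None) -> np.ndarray:
    """Read a bedGraph into a per-bin array (coverage-weighted mean)."""
    n = int(np.ceil(chrom_length / resolution))
    acc = np.zeros(n)
    wgt = np.zeros(n)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            c, s, e, v = line.split()[:4]
            if chrom is not None and c != chrom:
                continue
            s, e, v = int(s), int(e), float(v)
            b0, b1 = s // resolution, (e - 1) // resolution
            for b in range(b0, min(b1, n - 1) + 1):
                ov = min(e, (b + 1) * resolution) - max(s, b * resolution)
                acc[b] += v * ov
                wgt[b] += ov
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(wgt > 0, acc / np.maximum(wgt, 1e-300), np.nan)


def write_bedgraph(path: str, values: np.ndarray, resolution: int,
                   chrom: str = "chrS", start: int = 0) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{start + i * resolution}\t"
                         f"{start + (i + 1) * resolution}\t{v:.6g}\n")
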