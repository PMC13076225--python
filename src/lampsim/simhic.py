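"""Simulated Hi-C: contact capture from 3D conformations, per-site
normalization, binning, and contact-probability scaling curves.

A "site" is one cluster (the coarse-grained analogue of a restriction
fragment); because a single conformation represents a single nucleus, the sum
of contacts incident to one site is capped (default 8, matching the
two-ends-per-fragment x four-copies bound) by uniform subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter1d

from .contactmap import ContactMap

__all__ = [
    "ContactList", "contacts_from_conformation", "normalize_per_site",
    "bin_contacts", "ps_curve", "write_pairs", "read_pairs",
]


@dataclass
class ContactList:
    """Pairwise contacts assigned to genomic sites (bp midpoints)."""

    site_a: np.ndarray       # float64[k] bp, site_a <= site_b
    site_b: np.ndarray
    cluster_a: np.ndarray    # int32[k] site (cluster) indices
    cluster_b: np.ndarray
    capture_radius: float = 0.0

    def __len__(self) -> int:
        return len(self.site_a)

    def concat(self, other: "ContactList") -> "ContactList":
        return ContactList(
            np.concatenate([self.site_a, other.site_a]),
            np.concatenate([self.site_b, other.site_b]),
            np.concatenate([self.cluster_a, other.cluster_a]),
            np.concatenate([self.cluster_b, other.cluster_b]),
            self.capture_radius)


@njit(cache=True)
def _find_contacts(coords, radii, cluster_idx, chromatid, capture):
    n = coords.shape[0]
    rmax = 0.0
    for i in range(n):
        if radii[i] > rmax:
            rmax = radii[i]
    cut = 2.0 * rmax + capture
    xmin = coords[:, 0].min()
    ymin = coords[:, 1].min()
    zmin = coords[:, 2].min()
    nx = max(1, min(128, int(min((coords[:, 0].max() - xmin) / cut, 127.0)) + 1))
    ny = max(1, min(128, int(min((coords[:, 1].max() - ymin) / cut, 127.0)) + 1))
    nz = max(1, min(128, int(min((coords[:, 2].max() - zmin) / cut, 127.0)) + 1))
    ncell = nx * ny * nz
    cell = np.empty(n, dtype=np.int64)
    count = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        # clamp in float space: int() of an overflowing float is UB
        cx = int(min(max((coords[i, 0] - xmin) / cut, 0.0), nx - 1.0))
        cy = int(min(max((coords[i, 1] - ymin) / cut, 0.0), ny - 1.0))
        cz = int(min(max((coords[i, 2] - zmin) / cut, 0.0), nz - 1.0))
        c = (cx * ny + cy) * nz + cz
        cell[i] = c
        count[c + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    slot = count[:ncell].copy()
    members = np.empty(n, dtype=np.int64)
    for i in range(n):
        members[slot[cell[i]]] = i
        slot[cell[i]] += 1
    out_i = []
    out_j = []
    for i in range(n):
        ci = cell[i]
        cz0 = ci % nz
        cy0 = (ci // nz) % ny
        cx0 = ci // (nz * ny)
        for ddx in range(-1, 2):
            cx = cx0 + ddx
            if cx < 0 or cx >= nx:
                continue
            for ddy in range(-1, 2):
                cy = cy0 + ddy
                if cy < 0 or cy >= ny:
                    continue
                for ddz in range(-1, 2):
                    cz = cz0 + ddz
                    if cz < 0 or cz >= nz:
                        continue
                    c = (cx * ny + cy) * nz + cz
                    for s in range(count[c], count[c + 1]):
                        j = members[s]
                        if j <= i:
                            continue
                        # skip chain neighbors on the same chromatid
                        if chromatid[i] == chromatid[j]:
                            diff = cluster_idx[i] - cluster_idx[j]
                            if diff == 1 or diff == -1 or diff == 0:
                                continue
                        elif cluster_idx[i] == cluster_idx[j]:
                            continue  # sister copies of the same locus
                        dx = coords[j, 0] - coords[i, 0]
                        dy = coords[j, 1] - coords[i, 1]
                        dz = coords[j, 2] - coords[i, 2]
                        d = (dx * dx + dy * dy + dz * dz) ** 0.5
                        if d - (radii[i] + radii[j]) <= capture:
                            out_i.append(i)
                            out_j.append(j)
    res = np.empty((len(out_i), 2), dtype=np.int64)
    for k in range(len(out_i)):
        res[k, 0] = out_i[k]
        res[k, 1] = out_j[k]
    return res


def contacts_from_conformation(coords: np.ndarray, radii: np.ndarray,
                               chromatid: np.ndarray, mid_bp: np.ndarray,
                               capture_radius: float) -> ContactList:
    """Record a contact for every non-neighbor cluster pair whose surface
    distance ``d - (r_i + r_j)`` is within the capture radius.

    ``mid_bp`` gives the genomic midpoint of each cluster (single-chromatid
    template of length ``m``); particle ``p`` maps to cluster ``p % m``.
    """
    m = len(mid_bp)
    cluster_idx = (np.arange(len(coords)) % m).astype(np.int64)
    pairs = _find_contacts(coords, radii, cluster_idx,
                           chromatid.astype(np.int64), capture_radius)
    ca = cluster_idx[pairs[:, 0]]
    cb = cluster_idx[pairs[:, 1]]
    swap = ca > cb
    ca2 = np.where(swap, cb, ca)
    cb2 = np.where(swap, ca, cb)
    return ContactList(mid_bp[ca2].astype(float), mid_bp[cb2].astype(float),
                       ca2.astype(np.int32), cb2.astype(np.int32),
                       capture_radius)


def normalize_per_site(contacts: ContactList, cap: int = 8,
                       rng: np.random.Generator | None = None) -> ContactList:
    """Subsample contacts so no site's incident sum exceeds ``cap``.

    Sites are processed worst-first; each overloaded site keeps a uniform
    random subset of exactly ``cap`` incident contacts.  Iterates until no
    site exceeds the cap.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = rng or np.random.default_rng()
    keep = np.ones(len(contacts), dtype=bool)
    if len(contacts) == 0:
        return contacts
    nsite = int(max(contacts.cluster_a.max(), contacts.cluster_b.max())) + 1
    while True:
        idx = np.where(keep)[0]
        counts = (np.bincount(contacts.cluster_a[idx], minlength=nsite) +
                  np.bincount(contacts.cluster_b[idx], minlength=nsite))
        over = np.where(counts > cap)[0]
        if len(over) == 0:
            break
        worst = over[np.argmax(counts[over])]
        inc = idx[(contacts.cluster_a[idx] == worst) |
                  (contacts.cluster_b[idx] == worst)]
        drop = rng.choice(inc, size=len(inc) - cap, replace=False)
        keep[drop] = False
    return ContactList(contacts.site_a[keep], contacts.site_b[keep],
                       contacts.cluster_a[keep], contacts.cluster_b[keep],
                       contacts.capture_radius)


def site_incidence(contacts: ContactList) -> np.ndarray:
    """Incident contact count per site index."""
    if len(contacts) == 0:
        return np.zeros(0, dtype=np.int64)
    nsite = int(max(contacts.cluster_a.max(), contacts.cluster_b.max())) + 1
    return (np.bincount(contacts.cluster_a, minlength=nsite) +
            np.bincount(contacts.cluster_b, minlength=nsite))


def bin_contacts(contacts: ContactList, resolution: int, length_bp: int,
                 start: int = 0, chrom: str = "chrS") -> ContactMap:
    """Symmetric binned matrix; total (upper triangle + diagonal) count equals
    the number of contact records."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    n = int(np.ceil(length_bp / resolution))
    mat = np.zeros((n, n))
    if len(contacts):
        ia = ((contacts.site_a - start) // resolution).astype(int)
        ib = ((contacts.site_b - start) // resolution).astype(int)
        ia = np.clip(ia, 0, n - 1)
        ib = np.clip(ib, 0, n - 1)
        np.add.at(mat, (ia, ib), 1.0)
        off = ia != ib
        np.add.at(mat, (ib[off], ia[off]), 1.0)
    return ContactMap(mat, resolution, chrom, start)


def ps_curve(cmap: ContactMap, n_bins: int = 30, sigma_log10: float = 0.1):
    """Contact probability vs genomic separation in log-spaced bins.

    Returns a dict with separation-bin centers (bp), the normalized,
    log-Gaussian-smoothed probability (mass sums to 1 over the reported
    range), and the log-log slope curve.
    """
    n = cmap.n_bins
    mat = cmap.matrix
    seps = np.arange(1, n)
    sums = np.array([np.nansum(np.diagonal(mat, d)) for d in seps])
    npairs = (n - seps).astype(float)
    if sums.sum() == 0:
        raise ValueError("no cis contacts off the diagonal")
    lo = np.log10(cmap.resolution)
    hi = np.log10(n * cmap.resolution)
    edges = np.logspace(lo, hi, n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    sep_bp = seps * cmap.resolution
    which = np.clip(np.digitize(sep_bp, edges) - 1, 0, n_bins - 1)
    c_sum = np.bincount(which, weights=sums, minlength=n_bins)
    p_sum = np.bincount(which, weights=npairs, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = c_sum / p_sum
    valid = p_sum > 0
    # smooth in log10-distance; bins are uniform in log10 so sigma converts
    dlog = (hi - lo) / n_bins
    sm = freq.copy()
    sm[valid] = gaussian_filter1d(freq[valid], sigma_log10 / dlog,
                                  mode="nearest")
    mass = np.nansum(sm[valid])
    sm = sm / mass
    with np.errstate(invalid="ignore", divide="ignore"):
        logp = np.log10(sm)
        logs = np.log10(centers)
    slope = np.gradient(logp, logs)
    return {"s_bp": centers, "p": sm, "slope": slope, "valid": valid}


def write_pairs(path: str, contacts: ContactList, chrom: str = "chrS") -> None:
    """Plain-text pairs interchange: chrom1 pos1 chrom2 pos2 count."""
    from collections import Counter

    counts = Counter(zip(contacts.site_a.astype(np.int64),
                         contacts.site_b.astype(np.int64)))
    with open(path, "w") as fh:
        for (a, b), c in sorted(counts.items()):
            fh.write(f"{chrom}\t{a}\t{chrom}\t{b}\t{c}\n")


def read_pairs(path: str) -> ContactList:
    """Read the plain-text pairs format back into a contact list.

    Cluster indices are synthesized from the rank of each distinct site.
    """
    a_pos, b_pos = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            _, p1, _, p2, c = line.split()[:5]
            for _ in range(int(c)):
                a_pos.append(int(p1))
                b_pos.append(int(p2))
    a = np.array(a_pos, dtype=float)
    b = np.array(b_pos, dtype=float)
    sites = np.unique(np.concatenate([a, b]))
    ca = np.searchsorted(sites, a).astype(np.int32)
    cb = np.searchsorted(sites, b).astype(np.int32)
    return ContactList(a, b, ca, cb)
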