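"""Coarse-grained 3D relaxation of 1D lattice snapshots.

Ten consecutive lattice beads form one cluster (450-2250 bp).  Two sister
chromatids are laid out as parallel plane-filling curves; LEF loops become
harmonic bridge bonds (~40 nm rest length) refreshed at every 1D snapshot;
clusters holding a cohesive cohesin are tied to their sister with an
inter-chromatid bond.  Nascent RNA accumulated by resident polymerases
inflates cluster radii (``r = base + a * rna_bp**nu``), and the excluded
volume uses the truncated-harmonic overlap penalty
``E = 0.5 * k * (r1 + r2 - d)**2`` for ``d < r1 + r2`` (the only reading of
the additive-radii repulsion that vanishes at separation).  Dynamics are
overdamped Euler-Maruyama; an optional harmonic slab wall flattens one axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .sim1d import BeadArray1D, Snapshot

__all__ = [
    "Sim3DConfig", "ClusterChain", "Conformation3D",
    "coarse_grain", "rna_inflated_radius", "init_conformation", "relax",
    "flatten", "run_sim3d",
]

CLUSTER_SIZE = 10


@dataclass
class Sim3DConfig:
    radius_scale: float = 1.83      # nm per cluster_bp**(1/3)
    rna_prefactor_nm: float = 1.0   # a in r = base + a * rna_bp**nu
    rna_exponent: float = 0.5       # nu; 0.5 = ideal-coil scaling
    rna_bp_cap: float = 250_000.0   # cap on per-cluster RNA load (numerics)
    lef_rest_nm: float = 40.0
    coh_rest_nm: float = 40.0
    k_chain: float = 0.05
    k_lef: float = 0.05
    k_coh: float = 0.05
    k_rep: float = 0.02
    k_wall: float = 0.1
    kT: float = 1.0
    mobility_dt: float = 2.0        # mu*dt, nm^2 per kT per step
    slab_height_nm: float = 0.0     # 0 disables the slab wall
    init_dimension: float = 2.0     # d in spacing ~ cluster_bp**(1/d)
    chromatid_offset_nm: float = 60.0
    seed: int = 0


@dataclass
class ClusterChain:
    """Per-cluster view of a 1D snapshot (single chromatid template)."""

    cluster_bp: np.ndarray       # int64[m]
    base_radius: np.ndarray      # float64[m], nm
    rna_bp: np.ndarray           # float64[m]
    lef_bonds: np.ndarray        # int32[k, 2] cluster index pairs
    cohesive_mask: np.ndarray    # bool[m]
    bead_cluster: np.ndarray     # int32[n_beads] bead -> cluster
    cluster_start_bp: np.ndarray  # int64[m] genomic start (region coords)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_bp)

    def radii(self, config: Sim3DConfig) -> np.ndarray:
        rna = np.minimum(self.rna_bp, config.rna_bp_cap)
        return rna_inflated_radius(self.base_radius, rna,
                                   config.rna_prefactor_nm,
                                   config.rna_exponent)

    def cluster_mid_bp(self) -> np.ndarray:
        return self.cluster_start_bp + self.cluster_bp / 2.0


@dataclass
class Conformation3D:
    """Coordinates for both chromatids plus the active bond table."""

    coords: np.ndarray           # float64[2*m, 3], nm
    radii: np.ndarray            # float64[2*m]
    chromatid: np.ndarray        # int8[2*m], 1 or 2
    bonds: np.ndarray            # int32[nb, 2] particle index pairs
    bond_rest: np.ndarray        # float64[nb] nm
    bond_k: np.ndarray           # float64[nb]
    n_clusters: int = 0
    slab_height_nm: float = 0.0

    def finite(self) -> bool:
        return bool(np.isfinite(self.coords).all())


def rna_inflated_radius(base_radius, rna_bp, prefactor: float = 1.0,
                        exponent: float = 0.5):
    """Radius of a cluster inflated by its nascent-RNA load (power law)."""
    rna = np.asarray(rna_bp, dtype=float)
    if np.any(rna < 0):
        raise ValueError("rna_bp must be non-negative")
    return np.asarray(base_radius, dtype=float) + prefactor * rna ** exponent


def coarse_grain(beads: BeadArray1D, snapshot: Snapshot,
                 config: Sim3DConfig | None = None) -> ClusterChain:
    """Group the lattice into clusters of 10 beads and map agents onto them."""
    config = config or Sim3DConfig()
    n = beads.n_beads
    bead_cluster = (np.arange(n) // CLUSTER_SIZE).astype(np.int32)
    m = int(bead_cluster[-1]) + 1
    cluster_bp = np.zeros(m, dtype=np.int64)
    np.add.at(cluster_bp, bead_cluster, beads.bead_bp)
    cluster_start = np.zeros(m, dtype=np.int64)
    first = np.unique(bead_cluster, return_index=True)[1]
    cluster_start[:] = beads.bead_start[first]

    rna = np.zeros(m)
    np.add.at(rna, bead_cluster[snapshot.pol_bead], snapshot.pol_rna)

    alive = snapshot.lef_left >= 0
    ll = bead_cluster[snapshot.lef_left[alive]]
    rr = bead_cluster[snapshot.lef_right[alive]]
    keep = ll != rr
    lef_bonds = np.stack([ll[keep], rr[keep]], axis=1).astype(np.int32)

    coh = np.zeros(m, dtype=bool)
    coh[bead_cluster[snapshot.coh_bead]] = True

    base_r = config.radius_scale * cluster_bp.astype(float) ** (1.0 / 3.0)
    return ClusterChain(cluster_bp, base_r, rna, lef_bonds, coh,
                        bead_cluster, cluster_start)


# --- initialization ---------------------------------------------------------

def _hilbert_points(order: int) -> np.ndarray:
    """Vertices of the order-`order` Hilbert curve on a 2^order grid."""
    n = 1 << order
    d = np.arange(n * n)
    x = np.zeros_like(d)
    y = np.zeros_like(d)
    t = d.copy()
    s = 1
    while s < n:
        rx = 1 & (t // 2)
        ry = 1 & (t ^ rx)
        # rotate quadrant
        flip = ry == 0
        swap_x = np.where(flip & (rx == 1), s - 1 - x, x)
        swap_y = np.where(flip & (rx == 1), s - 1 - y, y)
        x2 = np.where(flip, swap_y, x)
        y2 = np.where(flip, swap_x, y)
        x = x2 + s * rx
        y = y2 + s * ry
        t //= 4
        s *= 2
    return np.stack([x, y], axis=1).astype(float)


def init_conformation(chain: ClusterChain,
                      config: Sim3DConfig | None = None) -> Conformation3D:
    """Lay both chromatids on congruent plane-filling curves.

    Clusters are placed along the Hilbert polyline at arclength steps
    proportional to ``cluster_bp ** (1/d)``; the sister is the same curve
    offset along z.  LEF bridges are mirrored onto both chromatids; clusters
    holding a cohesive get an inter-chromatid bond.
    """
    config = config or Sim3DConfig()
    m = chain.n_clusters
    radii1 = chain.radii(config)

    spacing = (chain.cluster_bp.astype(float) ** (1.0 / config.init_dimension))
    mean_sep = 2.0 * float(np.mean(chain.base_radius))
    spacing = spacing / spacing.mean() * mean_sep
    arc = np.concatenate([[0.0], np.cumsum(spacing[1:])])

    order = 1
    while (1 << (2 * order)) < m + 2:
        order += 1
    pts = _hilbert_points(order) * mean_sep
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    # stretch the curve if the requested arclength exceeds it
    scale = max(1.0, arc[-1] / max(cum[-1], 1e-9))
    pts *= scale
    cum *= scale
    xy = np.empty((m, 2))
    xy[:, 0] = np.interp(arc, cum, pts[:, 0])
    xy[:, 1] = np.interp(arc, cum, pts[:, 1])

    coords = np.zeros((2 * m, 3))
    coords[:m, :2] = xy
    coords[m:, :2] = xy
    coords[m:, 2] = config.chromatid_offset_nm

    radii = np.concatenate([radii1, radii1])
    chromatid = np.concatenate([np.ones(m, dtype=np.int8),
                                np.full(m, 2, dtype=np.int8)])

    bonds, rest, ks = _build_bonds(chain, radii1, config)
    return Conformation3D(coords, radii, chromatid, bonds, rest, ks,
                          n_clusters=m, slab_height_nm=config.slab_height_nm)


def _build_bonds(chain: ClusterChain, radii1: np.ndarray,
                 config: Sim3DConfig):
    """Chain + LEF + cohesive bond table over both chromatids."""
    m = chain.n_clusters
    b: list[tuple[int, int, float, float]] = []
    for off in (0, m):
        for i in range(m - 1):
            b.append((off + i, off + i + 1,
                      radii1[i] + radii1[i + 1], config.k_chain))
        for (i, j) in chain.lef_bonds:
            b.append((off + int(i), off + int(j),
                      config.lef_rest_nm, config.k_lef))
    for i in np.where(chain.cohesive_mask)[0]:
        b.append((int(i), m + int(i), config.coh_rest_nm, config.k_coh))
    if not b:
        return (np.zeros((0, 2), dtype=np.int32), np.zeros(0), np.zeros(0))
    arr = np.array([(i, j) for i, j, _, _ in b], dtype=np.int32)
    rest = np.array([r for _, _, r, _ in b])
    ks = np.array([k for _, _, _, k in b])
    return arr, rest, ks


def update_bonds(conf: Conformation3D, chain: ClusterChain,
                 config: Sim3DConfig) -> None:
    """Refresh bond table and radii from a new 1D snapshot (no teleporting)."""
    radii1 = chain.radii(config)
    conf.radii = np.concatenate([radii1, radii1])
    conf.bonds, conf.bond_rest, conf.bond_k = _build_bonds(chain, radii1, config)


# --- dynamics ---------------------------------------------------------------

@njit(cache=True)
def _forces(coords, radii, bonds, bond_rest, bond_k, k_rep, k_wall,
            slab_h, forces):
    n = coords.shape[0]
    forces[:] = 0.0
    # bonds
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        d = (dx * dx + dy * dy + dz * dz) ** 0.5
        if d < 1e-9:
            continue
        f = bond_k[b] * (d - bond_rest[b]) / d
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
    # repulsion via cell list
    rmax = 0.0
    for i in range(n):
        if radii[i] > rmax:
            rmax = radii[i]
    cut = 2.0 * rmax
    xmin = coords[:, 0].min()
    ymin = coords[:, 1].min()
    zmin = coords[:, 2].min()
    span = ((coords[:, 0].max() - xmin) + (coords[:, 1].max() - ymin)
            + (coords[:, 2].max() - zmin))
    # skip repulsion once coordinates go non-finite (divergence is detected
    # and reported by the Python driver)
    if cut > 0.0 and np.isfinite(span):
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
                            dx = coords[j, 0] - coords[i, 0]
                            dy = coords[j, 1] - coords[i, 1]
                            dz = coords[j, 2] - coords[i, 2]
                            d2 = dx * dx + dy * dy + dz * dz
                            rsum = radii[i] + radii[j]
                            if d2 >= rsum * rsum or d2 < 1e-18:
                                continue
                            d = d2 ** 0.5
                            f = k_rep * (rsum - d) / d
                            forces[i, 0] -= f * dx
                            forces[i, 1] -= f * dy
                            forces[i, 2] -= f * dz
                            forces[j, 0] += f * dx
                            forces[j, 1] += f * dy
                            forces[j, 2] += f * dz
    # slab wall on z
    if slab_h > 0.0:
        half = slab_h / 2.0
        for i in range(n):
            z = coords[i, 2]
            if z > half:
                forces[i, 2] -= k_wall * (z - half)
            elif z < -half:
                forces[i, 2] -= k_wall * (z + half)
    return forces


@njit(cache=True)
def _bd_steps(coords, radii, bonds, bond_rest, bond_k, k_rep, k_wall,
              slab_h, mob_dt, kT, nsteps, seed):
    np.random.seed(seed)
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    amp = (2.0 * kT * mob_dt) ** 0.5
    for _ in range(nsteps):
        _forces(coords, radii, bonds, bond_rest, bond_k, k_rep, k_wall,
                slab_h, forces)
        for i in range(n):
            coords[i, 0] += mob_dt * forces[i, 0] + amp * np.random.normal()
            coords[i, 1] += mob_dt * forces[i, 1] + amp * np.random.normal()
            coords[i, 2] += mob_dt * forces[i, 2] + amp * np.random.normal()
    return coords


def relax(conf: Conformation3D, steps: int, config: Sim3DConfig | None = None,
          seed: int = 0, frame_every: int = 0) -> list[np.ndarray]:
    """Overdamped Langevin relaxation in place; returns emitted frames.

    ``frame_every = 0`` emits only the final frame.  Raises on divergence.
    """
    config = config or Sim3DConfig()
    frames: list[np.ndarray] = []
    chunk = frame_every if frame_every > 0 else steps
    done = 0
    sub = 0
    while done < steps:
        k = min(chunk, steps - done)
        _bd_steps(conf.coords, conf.radii, conf.bonds, conf.bond_rest,
                  conf.bond_k, config.k_rep, config.k_wall,
                  conf.slab_height_nm, config.mobility_dt, config.kT,
                  k, seed + sub)
        if not conf.finite():
            raise FloatingPointError("3D relaxation diverged "
                                     f"(non-finite coordinates at step {done + k})")
        frames.append(conf.coords.copy())
        done += k
        sub += 1
    return frames


def flatten(conf: Conformation3D, height_nm: float = 1000.0) -> Conformation3D:
    """Enable the harmonic slab wall confining z to ``height_nm``."""
    conf.slab_height_nm = float(height_nm)
    return conf


def run_sim3d(beads: BeadArray1D, snapshots: list[Snapshot],
              config: Sim3DConfig | None = None,
              equil_steps: int = 2000, steps_per_snapshot: int = 400,
              frames_per_snapshot: int = 1, seed: int = 0):
    """Drive a 3D trajectory through a series of 1D snapshots.

    Initializes from the first snapshot, equilibrates, then for each further
    snapshot refreshes LEF/cohesive bonds and RNA radii and relaxes onward,
    emitting ``frames_per_snapshot`` frames per snapshot.  Returns
    (conformation, frames, chains) with one chain entry per frame.
    """
    config = config or Sim3DConfig()
    chain = coarse_grain(beads, snapshots[0], config)
    conf = init_conformation(chain, config)
    if config.slab_height_nm > 0:
        flatten(conf, config.slab_height_nm)
    relax(conf, equil_steps, config, seed=seed * 1000)
    frames = [conf.coords.copy()]
    chains = [chain]
    every = max(1, steps_per_snapshot // max(1, frames_per_snapshot))
    for k, snap in enumerate(snapshots[1:], start=1):
        chain = coarse_grain(beads, snap, config)
        update_bonds(conf, chain, config)
        emitted = relax(conf, steps_per_snapshot, config,
                        seed=seed * 1000 + k, frame_every=every)
        frames.extend(emitted)
        chains.extend([chain] * len(emitted))
    return conf, frames, chains


# --- trajectory store --------------------------------------------------------

def write_trajectory(path: str, frames: list[np.ndarray],
                     conf: Conformation3D) -> None:
    """Chunked HDF5 trajectory: coordinates per frame plus radii/bonds."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("radii", data=conf.radii)
        f.create_dataset("chromatid", data=conf.chromatid)
        f.create_dataset("bonds", data=conf.bonds)
        f.create_dataset("bond_rest", data=conf.bond_rest)
        arr = np.stack(frames)
        f.create_dataset("coordinates", data=arr,
                         chunks=(1,) + arr.shape[1:])
        f.attrs["n_clusters"] = conf.n_clusters
        f.attrs["slab_height_nm"] = conf.slab_height_nm


def export_xyz(path: str, frames: list[np.ndarray],
               chromatid: np.ndarray) -> None:
    """Plain multi-frame XYZ for external viewers (element = chromatid)."""
    names = {1: "C", 2: "N"}
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{len(frame)}\nlampsim frame\n")
            for p, (x, y, z) in zip(chromatid, frame):
                fh.write(f"{names.get(int(p), 'X')} {x:.2f} {y:.2f} {z:.2f}\n")
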