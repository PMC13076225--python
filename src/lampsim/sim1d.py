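"""Stochastic 1D lattice simulation of polymerases, loop extruders and
cohesive (non-extruding) cohesins on a heterogeneous bead array.

The lattice mixes 45-bp beads inside transcription units (one polymerase
footprint) with 225-bp beads in nucleosome-condensed silent chromatin.  Agents
occupy beads exclusively.  Polymerases load at unit starts with probability
proportional to activity, translocate at ``vp``, and push any contiguous run
of SMC complexes ahead of them until the run hits another polymerase or the
array end.  Loop-extruding factors (LEFs) extrude two-sided at ``vL``, can
bypass polymerases and cohesives with configurable probabilities, push single
cohesives, and turn over with a per-timestep hazard calibrated so that the
mean per-leg travel on naked chromatin equals ``lifetime_bp``.  Cohesives are
non-removable and move only when pushed.

All motion uses a fixed-increment loop with per-attempt probability
``v * dt / bead_bp`` (clamped to 1 on sub-45-bp residual beads), so agents
advance in bead units but at the configured speeds in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .annotations import TranscriptionUnit

__all__ = [
    "Sim1DConfig", "BeadArray1D", "Snapshot", "Sim1D",
    "build_bead_array", "run_sim1d", "post_lbc_mode", "lef_cycle_stats",
]

TU_BEAD_BP = 45
NUC_BEAD_BP = 225

OCC_NONE, OCC_POL, OCC_LEF, OCC_COH = 0, 1, 2, 3


@dataclass
class Sim1DConfig:
    """Parameters of the lattice dynamics (speeds in bp/s, sizes in bp)."""

    vp: float = 100.0
    vL: float = 625.0
    dt: float = 0.02
    lifetime_bp: float = 1_000_000.0
    average_loop_size: float = 90_000.0
    cohesive_density_bp: float = 45_000.0
    p_bypass_cohesive: float = 0.01
    p_bypass_polymerase: float = 0.01
    load_rate_scale: float = 0.06
    alternating_legs: bool = False
    loading_excludes_cohesive: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vp", "vL", "dt", "lifetime_bp", "average_loop_size",
                     "cohesive_density_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_bypass_cohesive", "p_bypass_polymerase"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dt * self.vL / TU_BEAD_BP >= 1.0:
            raise ValueError(
                "dt too large: vL*dt must stay below one 45-bp bead per step")


@dataclass
class BeadArray1D:
    """Heterogeneous 1D lattice derived from unit annotations."""

    bead_bp: np.ndarray          # int64[n], bp per bead
    bead_start: np.ndarray       # int64[n], cumulative bp offset
    bead_tu: np.ndarray          # int32[n], TU index or -1
    exon_frac: np.ndarray        # float64[n], exonic fraction of bead bp
    tu_ids: list[str]
    tu_strand: np.ndarray        # int8[ntu], +1 / -1
    tu_first_bead: np.ndarray    # int32[ntu], loading bead (strand-aware)
    tu_fpkm: np.ndarray          # float64[ntu]
    region_start: int
    region_end: int

    @property
    def n_beads(self) -> int:
        return len(self.bead_bp)

    @property
    def length_bp(self) -> int:
        return self.region_end - self.region_start

    def bead_mid_bp(self) -> np.ndarray:
        """Genomic midpoint (bp, region coordinates) of every bead."""
        return self.bead_start + self.bead_bp / 2.0


def _chop(total: int, unit: int) -> list[int]:
    """Split ``total`` bp into full ``unit``-bp beads plus one residual."""
    sizes = [unit] * (total // unit)
    if total % unit:
        sizes.append(total % unit)
    return sizes


def build_bead_array(tus: Sequence[TranscriptionUnit],
                     region: tuple[int, int]) -> BeadArray1D:
    """Lay out the lattice: 45-bp beads over units, 225-bp beads elsewhere.

    Residual bp at segment junctions go into one final short bead so the bead
    sizes always sum to the region length exactly.  Units must be sorted and
    non-overlapping (the lattice is single-occupancy, so opposite-strand
    overlap cannot be represented either).
    """
    r0, r1 = region
    if r1 <= r0:
        raise ValueError("empty region")
    tus = sorted(tus, key=lambda t: t.start)
    pos = r0
    sizes: list[int] = []
    tu_of: list[int] = []
    for k, tu in enumerate(tus):
        if tu.start < r0 or tu.end > r1:
            raise ValueError(f"{tu.tu_id} outside the region")
        if tu.start < pos:
            raise ValueError(f"{tu.tu_id} overlaps the previous unit")
        for s in _chop(tu.start - pos, NUC_BEAD_BP):
            sizes.append(s)
            tu_of.append(-1)
        for s in _chop(tu.length, TU_BEAD_BP):
            sizes.append(s)
            tu_of.append(k)
        pos = tu.end
    for s in _chop(r1 - pos, NUC_BEAD_BP):
        sizes.append(s)
        tu_of.append(-1)

    bead_bp = np.array(sizes, dtype=np.int64)
    bead_start = np.concatenate([[0], np.cumsum(bead_bp)[:-1]]) + r0
    bead_tu = np.array(tu_of, dtype=np.int32)
    assert bead_bp.sum() == r1 - r0

    exon_frac = np.zeros(len(bead_bp))
    for k, tu in enumerate(tus):
        idx = np.where(bead_tu == k)[0]
        for i in idx:
            b0, b1 = bead_start[i], bead_start[i] + bead_bp[i]
            ov = sum(max(0, min(b1, e) - max(b0, s)) for s, e in tu.exons)
            exon_frac[i] = ov / bead_bp[i]

    ntu = len(tus)
    strand = np.array([1 if t.strand == "+" else -1 for t in tus], dtype=np.int8)
    first = np.zeros(ntu, dtype=np.int32)
    for k in range(ntu):
        idx = np.where(bead_tu == k)[0]
        first[k] = idx[0] if strand[k] > 0 else idx[-1]
    fpkm = np.array([t.fpkm for t in tus], dtype=float)
    return BeadArray1D(bead_bp, bead_start.astype(np.int64), bead_tu,
                       exon_frac, [t.tu_id for t in tus], strand, first,
                       fpkm, r0, r1)


@dataclass
class Snapshot:
    """Agent positions at one time point (bead indices)."""

    t: float
    pol_bead: np.ndarray
    pol_tu: np.ndarray
    pol_rna: np.ndarray
    lef_left: np.ndarray
    lef_right: np.ndarray
    coh_bead: np.ndarray


# --- numba kernel ------------------------------------------------------------

@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _try_load_lef(l, lef_left, lef_right, occ_type, occ_id, bead_start,
                  lef_birth_l, lef_birth_r, exclude_coh):
    """Attempt to place LEF l on a random free adjacent pair; True on success.

    Exclusive bead occupancy means a pair is loadable only when both beads are
    empty, regardless of ``exclude_coh`` (kept for interface stability)."""
    n = occ_type.shape[0]
    for _ in range(60):
        i = np.random.randint(0, n - 1)
        if occ_type[i] == OCC_NONE and occ_type[i + 1] == OCC_NONE:
            lef_left[l] = i
            lef_right[l] = i + 1
            occ_type[i] = OCC_LEF
            occ_id[i] = l
            occ_type[i + 1] = OCC_LEF
            occ_id[i + 1] = l
            lef_birth_l[l] = bead_start[i]
            lef_birth_r[l] = bead_start[i + 1]
            return True
    return False


@njit(cache=True)
def _shift_chain(first, last, d, occ_type, occ_id, lef_left, lef_right,
                 coh_bead):
    """Shift the contiguous SMC run occupying beads first..last by one bead in
    direction d.  The caller guarantees that last+d is free and in range."""
    k = last
    while True:
        a_type = occ_type[k]
        a_id = occ_id[k]
        occ_type[k + d] = a_type
        occ_id[k + d] = a_id
        occ_type[k] = OCC_NONE
        if a_type == OCC_LEF:
            if lef_left[a_id] == k:
                lef_left[a_id] = k + d
            else:
                lef_right[a_id] = k + d
        else:
            coh_bead[a_id] = k + d
        if k == first:
            break
        k -= d


@njit(cache=True)
def _step_lef_leg(l, d, vL_dt, p_byp_pol, p_byp_coh, bead_bp, occ_type, occ_id,
                  lef_left, lef_right, coh_bead):
    n = occ_type.shape[0]
    b = lef_left[l] if d < 0 else lef_right[l]
    nb = b + d
    if nb < 0 or nb >= n:
        return
    p = vL_dt / bead_bp[nb]
    if p < 1.0 and np.random.random() >= p:
        return
    target = -1
    t = occ_type[nb]
    if t == OCC_NONE:
        target = nb
    elif t == OCC_LEF:
        return
    elif t == OCC_POL:
        # hop over the contiguous convoy; every complex in the run must be
        # bypassed, so the single draw uses p^m for a run of m polymerases
        j = nb
        m = 0
        while 0 <= j < n and occ_type[j] == OCC_POL:
            j += d
            m += 1
        if 0 <= j < n and occ_type[j] == OCC_NONE:
            if np.random.random() < p_byp_pol ** m:
                target = j
    else:  # cohesive
        beyond = nb + d
        if 0 <= beyond < n and occ_type[beyond] == OCC_NONE:
            # push the single cohesive one bead ahead and take its place
            c = occ_id[nb]
            occ_type[beyond] = OCC_COH
            occ_id[beyond] = c
            coh_bead[c] = beyond
            occ_type[nb] = OCC_NONE
            target = nb
        else:
            j = nb
            m = 0
            while 0 <= j < n and occ_type[j] == OCC_COH:
                j += d
                m += 1
            if 0 <= j < n and occ_type[j] == OCC_NONE:
                if np.random.random() < p_byp_coh ** m:
                    target = j
    if target >= 0:
        occ_type[b] = OCC_NONE
        occ_type[target] = OCC_LEF
        occ_id[target] = l
        if d < 0:
            lef_left[l] = target
        else:
            lef_right[l] = target


@njit(cache=True)
def _step_pol(p, vp_dt, bead_bp, bead_tu, exon_frac, occ_type, occ_id,
              pol_bead, pol_tu, pol_rna, pol_alive, lef_left, lef_right,
              coh_bead, tu_strand):
    n = occ_type.shape[0]
    b = pol_bead[p]
    tu = pol_tu[p]
    d = 1 if tu_strand[tu] > 0 else -1
    nb = b + d
    leaving = nb < 0 or nb >= n or bead_tu[nb] != tu
    if leaving:
        prob = vp_dt / bead_bp[b]
        if prob >= 1.0 or np.random.random() < prob:
            # terminate; push any SMC run sitting just past the unit end
            if 0 <= nb < n and (occ_type[nb] == OCC_LEF or occ_type[nb] == OCC_COH):
                j = nb
                while 0 <= j < n and (occ_type[j] == OCC_LEF or occ_type[j] == OCC_COH):
                    j += d
                if 0 <= j < n and occ_type[j] == OCC_NONE:
                    _shift_chain(nb, j - d, d, occ_type, occ_id,
                                 lef_left, lef_right, coh_bead)
            occ_type[b] = OCC_NONE
            pol_alive[p] = False
        return
    prob = vp_dt / bead_bp[nb]
    if prob < 1.0 and np.random.random() >= prob:
        return
    t = occ_type[nb]
    if t == OCC_NONE:
        occ_type[b] = OCC_NONE
        occ_type[nb] = OCC_POL
        occ_id[nb] = p
        pol_bead[p] = nb
        pol_rna[p] += bead_bp[nb] * exon_frac[nb]
    elif t == OCC_POL:
        return
    else:
        # push the whole contiguous SMC run, unless a polymerase (or the
        # array end) sits right behind it
        j = nb
        while 0 <= j < n and (occ_type[j] == OCC_LEF or occ_type[j] == OCC_COH):
            j += d
        if 0 <= j < n and occ_type[j] == OCC_NONE:
            _shift_chain(nb, j - d, d, occ_type, occ_id,
                         lef_left, lef_right, coh_bead)
            occ_type[b] = OCC_NONE
            occ_type[nb] = OCC_POL
            occ_id[nb] = p
            pol_bead[p] = nb
            pol_rna[p] += bead_bp[nb] * exon_frac[nb]


@njit(cache=True)
def _run_steps(nsteps, step0,
               bead_bp, bead_tu, exon_frac, tu_strand, tu_first_bead,
               tu_load_prob, bead_start,
               occ_type, occ_id,
               pol_bead, pol_tu, pol_rna, pol_alive, npol_arr,
               lef_left, lef_right, lef_birth_l, lef_birth_r,
               coh_bead,
               vp_dt, vL_dt, removal_prob, p_byp_pol, p_byp_coh,
               alternating, exclude_coh,
               rec_span, rec_travel, rec_count):
    ntu = tu_first_bead.shape[0]
    nlef = lef_left.shape[0]
    cap = pol_bead.shape[0]
    rec_cap = rec_span.shape[0]
    for step in range(step0, step0 + nsteps):
        # --- polymerase loading -----------------------------------------
        npol = npol_arr[0]
        for k in range(ntu):
            if tu_load_prob[k] <= 0.0:
                continue
            fb = tu_first_bead[k]
            if occ_type[fb] == OCC_NONE and npol < cap:
                if np.random.random() < tu_load_prob[k]:
                    pol_bead[npol] = fb
                    pol_tu[npol] = k
                    pol_rna[npol] = bead_bp[fb] * exon_frac[fb]
                    pol_alive[npol] = True
                    occ_type[fb] = OCC_POL
                    occ_id[fb] = npol
                    npol += 1
        npol_arr[0] = npol

        # --- LEF turnover / pending reloads -----------------------------
        for l in range(nlef):
            if lef_left[l] < 0:
                _try_load_lef(l, lef_left, lef_right, occ_type, occ_id,
                              bead_start, lef_birth_l, lef_birth_r,
                              exclude_coh)
                continue
            if np.random.random() < removal_prob:
                if rec_count[0] < rec_cap:
                    r = rec_count[0]
                    rec_span[r] = bead_start[lef_right[l]] - bead_start[lef_left[l]]
                    rec_travel[2 * r] = lef_birth_l[l] - bead_start[lef_left[l]]
                    rec_travel[2 * r + 1] = bead_start[lef_right[l]] - lef_birth_r[l]
                    rec_count[0] = r + 1
                occ_type[lef_left[l]] = OCC_NONE
                occ_type[lef_right[l]] = OCC_NONE
                lef_left[l] = -1
                lef_right[l] = -1
                _try_load_lef(l, lef_left, lef_right, occ_type, occ_id,
                              bead_start, lef_birth_l, lef_birth_r,
                              exclude_coh)

        # --- agent moves in shuffled order ------------------------------
        order = np.random.permutation(npol + nlef)
        for o in order:
            if o < npol:
                if pol_alive[o]:
                    _step_pol(o, vp_dt, bead_bp, bead_tu, exon_frac,
                              occ_type, occ_id, pol_bead, pol_tu, pol_rna,
                              pol_alive, lef_left, lef_right, coh_bead,
                              tu_strand)
            else:
                l = o - npol
                if lef_left[l] < 0:
                    continue
                if alternating:
                    d = -1 if (step % 2 == 0) else 1
                    _step_lef_leg(l, d, vL_dt, p_byp_pol, p_byp_coh, bead_bp,
                                  occ_type, occ_id, lef_left, lef_right,
                                  coh_bead)
                else:
                    _step_lef_leg(l, -1, vL_dt, p_byp_pol, p_byp_coh, bead_bp,
                                  occ_type, occ_id, lef_left, lef_right,
                                  coh_bead)
                    _step_lef_leg(l, 1, vL_dt, p_byp_pol, p_byp_coh, bead_bp,
                                  occ_type, occ_id, lef_left, lef_right,
                                  coh_bead)

        # --- compact dead polymerases -----------------------------------
        npol = npol_arr[0]
        w = 0
        for r in range(npol):
            if pol_alive[r]:
                if w != r:
                    pol_bead[w] = pol_bead[r]
                    pol_tu[w] = pol_tu[r]
                    pol_rna[w] = pol_rna[r]
                    pol_alive[w] = True
                    occ_id[pol_bead[w]] = w
                w += 1
        for r in range(w, npol):
            pol_alive[r] = False
        npol_arr[0] = npol = w
    return step0 + nsteps


# --- driver ------------------------------------------------------------------

class Sim1D:
    """Stateful 1D simulation; supports snapshotting and stage switching."""

    def __init__(self, beads: BeadArray1D, config: Sim1DConfig,
                 cohesive_positions: np.ndarray | None = None,
                 rec_capacity: int = 0):
        self.beads = beads
        self.config = config
        n = beads.n_beads
        rng = np.random.default_rng(config.seed)
        _seed(int(rng.integers(0, 2**31 - 1)))

        self.occ_type = np.zeros(n, dtype=np.int8)
        self.occ_id = np.zeros(n, dtype=np.int32)

        # cohesives: constant count, uniform random placement by default
        if cohesive_positions is None:
            ncoh = int(beads.length_bp // config.cohesive_density_bp)
            free = np.arange(n)
            pick = rng.choice(free, size=ncoh, replace=False)
            self.coh_bead = np.sort(pick).astype(np.int32)
        else:
            self.coh_bead = np.asarray(cohesive_positions, dtype=np.int32).copy()
        for b in self.coh_bead:
            if self.occ_type[b] != OCC_NONE:
                raise ValueError("cohesive placement collision")
        self.occ_type[self.coh_bead] = OCC_COH
        self.occ_id[self.coh_bead] = np.arange(len(self.coh_bead))

        # LEFs: constant count floor(L / average_loop_size)
        nlef = int(beads.length_bp // config.average_loop_size)
        self.lef_left = np.full(nlef, -1, dtype=np.int32)
        self.lef_right = np.full(nlef, -1, dtype=np.int32)
        self.lef_birth_l = np.zeros(nlef)
        self.lef_birth_r = np.zeros(nlef)
        for l in range(nlef):
            _try_load_lef(l, self.lef_left, self.lef_right, self.occ_type,
                          self.occ_id, beads.bead_start, self.lef_birth_l,
                          self.lef_birth_r, config.loading_excludes_cohesive)

        cap = int((beads.bead_tu >= 0).sum()) + 16
        self.pol_bead = np.zeros(cap, dtype=np.int32)
        self.pol_tu = np.zeros(cap, dtype=np.int32)
        self.pol_rna = np.zeros(cap)
        self.pol_alive = np.zeros(cap, dtype=np.bool_)
        self.npol = np.zeros(1, dtype=np.int64)

        self.tu_load_prob = np.minimum(
            1.0, config.load_rate_scale * beads.tu_fpkm * config.dt)

        rec_capacity = max(rec_capacity, 1)
        self.rec_span = np.zeros(rec_capacity)
        self.rec_travel = np.zeros(2 * rec_capacity)
        self.rec_count = np.zeros(1, dtype=np.int64)
        self.step = 0

    @property
    def t(self) -> float:
        return self.step * self.config.dt

    def advance(self, duration_s: float) -> None:
        """Run the kernel for ``duration_s`` seconds of simulated time."""
        cfg = self.config
        nsteps = int(round(duration_s / cfg.dt))
        removal_prob = cfg.vL * cfg.dt / cfg.lifetime_bp
        self.step = _run_steps(
            nsteps, self.step,
            self.beads.bead_bp, self.beads.bead_tu, self.beads.exon_frac,
            self.beads.tu_strand, self.beads.tu_first_bead,
            self.tu_load_prob, self.beads.bead_start,
            self.occ_type, self.occ_id,
            self.pol_bead, self.pol_tu, self.pol_rna, self.pol_alive,
            self.npol,
            self.lef_left, self.lef_right, self.lef_birth_l, self.lef_birth_r,
            self.coh_bead,
            cfg.vp * cfg.dt, cfg.vL * cfg.dt, removal_prob,
            cfg.p_bypass_polymerase, cfg.p_bypass_cohesive,
            cfg.alternating_legs, cfg.loading_excludes_cohesive,
            self.rec_span, self.rec_travel, self.rec_count)

    def snapshot(self) -> Snapshot:
        np_ = int(self.npol[0])
        return Snapshot(
            t=self.t,
            pol_bead=self.pol_bead[:np_].copy(),
            pol_tu=self.pol_tu[:np_].copy(),
            pol_rna=self.pol_rna[:np_].copy(),
            lef_left=self.lef_left.copy(),
            lef_right=self.lef_right.copy(),
            coh_bead=self.coh_bead.copy(),
        )

    def run(self, duration_s: float, snapshot_every_s: float) -> list[Snapshot]:
        snaps = [self.snapshot()]
        remaining = duration_s
        while remaining > 1e-9:
            chunk = min(snapshot_every_s, remaining)
            self.advance(chunk)
            snaps.append(self.snapshot())
            remaining -= chunk
        return snaps

    def validate(self) -> None:
        """Assert occupancy exclusivity and agent/occupancy consistency."""
        n = self.beads.n_beads
        seen = np.zeros(n, dtype=np.int8)
        np_ = int(self.npol[0])
        for b in self.pol_bead[:np_]:
            assert self.occ_type[b] == OCC_POL
            seen[b] += 1
        for l in range(len(self.lef_left)):
            if self.lef_left[l] < 0:
                continue
            assert self.lef_left[l] < self.lef_right[l]
            for b in (self.lef_left[l], self.lef_right[l]):
                assert self.occ_type[b] == OCC_LEF
                seen[b] += 1
        for b in self.coh_bead:
            assert self.occ_type[b] == OCC_COH
            seen[b] += 1
        assert seen.max() <= 1, "occupancy exclusivity violated"
        assert (seen > 0).sum() == (self.occ_type != OCC_NONE).sum()


def run_sim1d(beads: BeadArray1D, config: Sim1DConfig, duration_s: float,
              snapshot_every_s: float) -> list[Snapshot]:
    """Convenience wrapper: initialize, run, return the snapshot series."""
    sim = Sim1D(beads, config)
    return sim.run(duration_s, snapshot_every_s)


def post_lbc_mode(sim: Sim1D, loading_scale: float = 0.1,
                  seed: int | None = None) -> Sim1D:
    """Stage switch: inherit cohesive positions, damp polymerase loading.

    Returns a fresh simulation whose cohesives start where the donor run left
    them and whose per-unit loading rates are multiplied by
    ``loading_scale``; LEFs reinitialize and all other dynamics are unchanged.
    """
    cfg = replace(sim.config,
                  load_rate_scale=sim.config.load_rate_scale * loading_scale,
                  seed=sim.config.seed + 1 if seed is None else seed)
    return Sim1D(sim.beads, cfg, cohesive_positions=sim.coh_bead)


def lef_cycle_stats(region_bp: int = 1_000_000_000,
                    config: Sim1DConfig | None = None,
                    n_cycles: int = 2000,
                    lef_spacing_bp: float = 100_000_000.0,
                    max_duration_s: float = 1e7) -> dict:
    """Measure LEF load-unload cycles on a naked (TU-free) array.

    Runs the full kernel with polymerase loading disabled and no cohesives,
    recording for every completed cycle the final loop span and the per-leg
    travel (bp).  LEFs are kept sparse (default one per 100 Mb) so that
    cycles probe single-extruder processivity rather than density-limited
    blocking.  Returns the raw arrays plus the fraction of loops reaching
    1 Mb; ``leg_travel_bp`` holds both legs of every cycle (entries [::2]
    are one leg per cycle, i.e. independent samples).
    """
    config = config or Sim1DConfig()
    beads = build_bead_array([], (0, region_bp))
    cfg = replace(config, cohesive_density_bp=float(region_bp * 10),
                  average_loop_size=lef_spacing_bp)
    sim = Sim1D(beads, cfg, rec_capacity=n_cycles)
    chunk = 5000.0
    t = 0.0
    while sim.rec_count[0] < n_cycles and t < max_duration_s:
        sim.advance(chunk)
        t += chunk
    m = int(sim.rec_count[0])
    span = sim.rec_span[:m]
    travel = sim.rec_travel[:2 * m]
    return {
        "span_bp": span,
        "leg_travel_bp": travel,
        "frac_span_ge_1mb": float((span >= 1_000_000).mean()) if m else np.nan,
        "n_cycles": m,
    }


# --- snapshot store ----------------------------------------------------------

def write_snapshots(path: str, beads: BeadArray1D,
                    snapshots: list[Snapshot]) -> None:
    """Store the bead table once plus one HDF5 group per snapshot."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("beads")
        g.create_dataset("bead_bp", data=beads.bead_bp)
        g.create_dataset("bead_start", data=beads.bead_start)
        g.create_dataset("bead_tu", data=beads.bead_tu)
        g.create_dataset("exon_frac", data=beads.exon_frac)
        g.attrs["region_start"] = beads.region_start
        g.attrs["region_end"] = beads.region_end
        g.attrs["tu_ids"] = ",".join(beads.tu_ids)
        g.create_dataset("tu_strand", data=beads.tu_strand)
        g.create_dataset("tu_first_bead", data=beads.tu_first_bead)
        g.create_dataset("tu_fpkm", data=beads.tu_fpkm)
        for k, s in enumerate(snapshots):
            g = f.create_group(f"snapshots/{k:06d}")
            g.attrs["t"] = s.t
            g.create_dataset("pol_bead", data=s.pol_bead)
            g.create_dataset("pol_tu", data=s.pol_tu)
            g.create_dataset("pol_rna", data=s.pol_rna)
            g.create_dataset("lef_left", data=s.lef_left)
            g.create_dataset("lef_right", data=s.lef_right)
            g.create_dataset("coh_bead", data=s.coh_bead)


def read_snapshots(path: str) -> tuple[BeadArray1D, list[Snapshot]]:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["beads"]
        beads = BeadArray1D(
            g["bead_bp"][:], g["bead_start"][:], g["bead_tu"][:],
            g["exon_frac"][:], g.attrs["tu_ids"].split(",") if g.attrs["tu_ids"] else [],
            g["tu_strand"][:], g["tu_first_bead"][:], g["tu_fpkm"][:],
            int(g.attrs["region_start"]), int(g.attrs["region_end"]))
        snaps = []
        for k in sorted(f["snapshots"]):
            g = f[f"snapshots/{k}"]
            snaps.append(Snapshot(float(g.attrs["t"]), g["pol_bead"][:],
                                  g["pol_tu"][:], g["pol_rna"][:],
                                  g["lef_left"][:], g["lef_right"][:],
                                  g["coh_bead"][:]))
    return beads, snaps
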