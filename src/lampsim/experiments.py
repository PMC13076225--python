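"""End-to-end experiment drivers: bypass-probability regimes, stage
transitions, and the synthetic convergent-tandem insulation measurements.

A "regime" fixes the two bypass probabilities of the lattice model:

====== ======================= =========================
name   extruder vs cohesive    extruder vs polymerase
====== ======================= =========================
D      low (0.01)              near-certain (1.0)
E      low (0.01)              low (0.01)
F      near-certain (1.0)      low (0.01)
G      near-certain (1.0)      near-certain (1.0)
====== ======================= =========================

A "stage" is either the hypertranscribing state (``lbc``) or the
transcriptionally damped state (``post``), which inherits cohesive positions
from the end of an ``lbc`` run and scales polymerase loading down (default
x0.1).

The default segment sizes and durations here are deliberately small (about a
1-Mb segment, minutes of simulated time) so that replicated experiments run
on one CPU in minutes; all knobs are exposed.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field

import numpy as np

from .annotations import TranscriptionUnit, build_tandems, adjacent_pairs
from .contactmap import ContactMap
from .hicstats import cps_track, quadrant_insulation_score
from .sim1d import Sim1D, Sim1DConfig, build_bead_array, post_lbc_mode
from .sim3d import Sim3DConfig, run_sim3d
from .simhic import bin_contacts, contacts_from_conformation, normalize_per_site

__all__ = [
    "REGIMES", "MechanismConfig", "build_convergent_segment", "run_pipeline",
    "run_regime_experiment", "run_insulation_by_class",
]

REGIMES: dict[str, tuple[float, float]] = {
    # (p_bypass_cohesive, p_bypass_polymerase)
    "D": (0.01, 1.0),
    "E": (0.01, 0.01),
    "F": (1.0, 0.01),
    "G": (1.0, 1.0),
}


@dataclass
class MechanismConfig:
    """Sizing of the synthetic convergent-tandem experiment."""

    n_units: int = 1                 # convergent tandem pairs
    silent_bp: int = 160_000
    gene_long_bp: int = 80_000
    gene_short_bp: int = 40_000
    tandem_spacer_bp: int = 2_000
    gap_bp: int = 40_000
    fpkm: float = 10.0
    load_rate_scale: float = 0.05
    dt: float = 0.07
    warmup_s: float = 1_200.0
    n_snapshots: int = 6
    snapshot_every_s: float = 150.0
    post_loading_scale: float = 0.1
    post_warmup_s: float = 1_200.0
    resolution: int = 10_000
    capture_radius_nm: float = 30.0
    flank_bp: float = 230_000.0
    cps_s_bp: float = 20_000.0
    cps_w_bp: float = 150_000.0
    equil_steps: int = 1200
    steps_per_snapshot: int = 250
    site_cap: int = 8
    frames_per_snapshot: int = 2
    sim3d: Sim3DConfig = field(default_factory=lambda: Sim3DConfig(
        rna_prefactor_nm=0.2, rna_bp_cap=60_000.0))


def build_convergent_segment(cfg: MechanismConfig):
    """Deterministic layout of convergent two-gene tandem pairs.

    Each unit is ``silent | F-long F-short | gap | R-short R-long | ``; the
    convergent gap midpoints are the candidate boundary positions.  Returns
    (tus, region, info) where info carries gap midpoints, the bp of the two
    gene ends flanking each gap, and unit body intervals.
    """
    tus: list[TranscriptionUnit] = []
    pos = 0
    mids, corners, bodies = [], [], []
    k = 0
    for _ in range(cfg.n_units):
        pos += cfg.silent_bp
        for ln, st in ((cfg.gene_long_bp, "+"), (cfg.gene_short_bp, "+")):
            tus.append(TranscriptionUnit(f"TU{k:03d}", "chrS", pos, pos + ln,
                                         st, fpkm_exon=cfg.fpkm,
                                         fpkm_intron=cfg.fpkm))
            bodies.append((pos, pos + ln))
            pos += ln + cfg.tandem_spacer_bp
            k += 1
        pos -= cfg.tandem_spacer_bp
        end_f = pos
        pos += cfg.gap_bp
        mids.append(end_f + cfg.gap_bp / 2.0)
        corners.append((end_f, pos))
        for ln, st in ((cfg.gene_short_bp, "-"), (cfg.gene_long_bp, "-")):
            tus.append(TranscriptionUnit(f"TU{k:03d}", "chrS", pos, pos + ln,
                                         st, fpkm_exon=cfg.fpkm,
                                         fpkm_intron=cfg.fpkm))
            bodies.append((pos, pos + ln))
            pos += ln + cfg.tandem_spacer_bp
            k += 1
        pos -= cfg.tandem_spacer_bp
    pos += cfg.silent_bp
    region = (0, pos)
    info = {"gap_mid_bp": np.array(mids),
            "gap_corners_bp": corners,
            "tu_bodies_bp": bodies}
    return tus, region, info


def initial_cohesive_beads(beads, tus, rng: np.random.Generator) -> np.ndarray:
    """Cohesive starting beads with transcribed blocks already swept clean.

    Draws the default number of uniformly placed cohesives, then relocates
    any that fall inside a co-directional transcribed block to a stack just
    past the block's downstream end -- the steady state that sustained
    transcription produces (and the initial condition of the regime runs).
    """
    ncoh = int(beads.length_bp // Sim1DConfig().cohesive_density_bp)
    pos_bp = np.sort(rng.uniform(0, beads.length_bp, size=ncoh))
    blocks = [(t.start, t.end, t.strand) for t in build_tandems(tus)]
    taken = np.zeros(beads.n_beads, dtype=bool)
    out = []

    def place_from(b0: int, step: int) -> int:
        b = b0
        while 0 <= b < beads.n_beads and taken[b]:
            b += step
        if not 0 <= b < beads.n_beads:
            raise ValueError("no room to stack cohesives")
        taken[b] = True
        return b

    for p in pos_bp:
        home = None
        for (s, e, strand) in blocks:
            if s <= p < e:
                home = (s, e, strand)
                break
        if home is None:
            b = int(np.searchsorted(beads.bead_start, p, side="right") - 1)
            out.append(place_from(b, 1))
        elif home[2] == "+":
            b = int(np.searchsorted(beads.bead_start, home[1], side="left"))
            out.append(place_from(min(b, beads.n_beads - 1), 1))
        else:
            b = int(np.searchsorted(beads.bead_start, home[0], side="right") - 1)
            out.append(place_from(max(b, 0), -1))
    return np.array(sorted(out), dtype=np.int32)


def _map_from_run(beads, snapshots, cfg: MechanismConfig, seed: int,
                  region_bp: int) -> ContactMap:
    """3D relaxation over the snapshot series -> pooled, per-conformation
    normalized, binned contact map."""
    conf, frames, chains = run_sim3d(
        beads, snapshots, cfg.sim3d, equil_steps=cfg.equil_steps,
        steps_per_snapshot=cfg.steps_per_snapshot,
        frames_per_snapshot=cfg.frames_per_snapshot, seed=seed)
    rng = np.random.default_rng(seed + 777)
    pooled = None
    for frame, chain in zip(frames, chains):
        # capture uses the bare chromatin radii: the nascent-RNA cloud keeps
        # other loci away (repulsion) but is not itself a contact surface
        radii = np.concatenate([chain.base_radius] * 2)
        chromatid = np.concatenate([
            np.ones(chain.n_clusters, dtype=np.int8),
            np.full(chain.n_clusters, 2, dtype=np.int8)])
        cl = contacts_from_conformation(frame, radii, chromatid,
                                        chain.cluster_mid_bp(),
                                        cfg.capture_radius_nm)
        cl = normalize_per_site(cl, cap=cfg.site_cap, rng=rng)
        pooled = cl if pooled is None else pooled.concat(cl)
    return bin_contacts(pooled, cfg.resolution, region_bp)


def run_pipeline(regime: str, stage: str, seed: int,
                 cfg: MechanismConfig | None = None,
                 tus=None, region=None, info=None) -> dict:
    """One replicate: 1D sim -> 3D relax -> simulated map -> scores.

    Returns the map, its O/E, the per-gap quadrant insulation scores, the
    per-gap corner O/E vs same-distance flank, and the mean cross-pattern
    score over gene bodies.
    """
    cfg = cfg or MechanismConfig()
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    p_coh, p_pol = REGIMES[regime]
    if tus is None:
        tus, region, info = build_convergent_segment(cfg)
    beads = build_bead_array(tus, region)
    scfg = Sim1DConfig(dt=cfg.dt, p_bypass_cohesive=p_coh,
                       p_bypass_polymerase=p_pol,
                       load_rate_scale=cfg.load_rate_scale, seed=seed)
    coh0 = initial_cohesive_beads(beads, tus, np.random.default_rng(seed + 99))
    sim = Sim1D(beads, scfg, cohesive_positions=coh0)
    sim.advance(cfg.warmup_s)
    if stage == "post":
        sim = post_lbc_mode(sim, loading_scale=cfg.post_loading_scale,
                            seed=seed + 50_000)
        sim.advance(cfg.post_warmup_s)
    elif stage != "lbc":
        raise ValueError("stage must be 'lbc' or 'post'")
    snapshots = sim.run(cfg.n_snapshots * cfg.snapshot_every_s,
                        cfg.snapshot_every_s)[1:]
    cmap = _map_from_run(beads, snapshots, cfg, seed, region[1] - region[0])
    oe = cmap.observed_over_expected()

    quad = [quadrant_score_at(oe, mid, cfg.flank_bp)
            for mid in info["gap_mid_bp"]]
    quad_raw = [quadrant_score_at(cmap, mid, cfg.flank_bp)
                for mid in info["gap_mid_bp"]]
    gap_ins = [gap_insulation(cmap, mid, cfg.flank_bp)
               for mid in info["gap_mid_bp"]]
    corner = [corner_vs_flank(oe, a, b) for (a, b) in info["gap_corners_bp"]]
    cps = cps_track(cmap, cfg.cps_s_bp, cfg.cps_w_bp)
    in_tu = np.zeros(cmap.n_bins, dtype=bool)
    for (a, b) in info["tu_bodies_bp"]:
        in_tu[cmap.bin_of(a):cmap.bin_of(b) + 1] = True
    in_gap = np.zeros(cmap.n_bins, dtype=bool)
    for (a, b) in info["gap_corners_bp"]:
        in_gap[cmap.bin_of(a):cmap.bin_of(b) + 1] = True
    cps_tu = float(np.nanmean(cps[in_tu])) if np.isfinite(cps[in_tu]).any() \
        else float("nan")
    cps_silent = float(np.nanmean(cps[~in_tu & ~in_gap]))
    band = tu_band_oe(oe, info["tu_bodies_bp"])
    return {"map": cmap, "oe": oe,
            "quadrant": np.array(quad), "quadrant_raw": np.array(quad_raw),
            "gap_insulation": np.array(gap_ins),
            "corner": np.array(corner),
            "cps_tu_mean": cps_tu, "cps_silent_mean": cps_silent,
            "tu_band_oe": band,
            # cross prominence: depletion of unit-anchored mid-range contacts
            # relative to the distance expectation (1 = fully isolated loop,
            # ~0 or below = no cross)
            "cross_prominence": 1.0 - band,
            "info": info}


def quadrant_score_at(oe: ContactMap, center_bp: float,
                      flank_bp: float) -> float:
    """Quadrant insulation of the O/E submatrix centered on a position."""
    f = int(round(flank_bp / oe.resolution))
    c = oe.bin_of(center_bp)
    n = oe.n_bins
    if c - f < 0 or c + f >= n:
        return float("nan")
    sub = oe.matrix[c - f:c + f + 1, c - f:c + f + 1]
    return quadrant_insulation_score(sub)


def gap_insulation(cmap: ContactMap, center_bp: float, flank_bp: float,
                   min_sep_bins: int = 3) -> float:
    """Within-side over cross-boundary raw contact ratio around a position.

    Considers pairs within ``flank_bp`` of the center separated by at least
    ``min_sep_bins`` bins; pairs straddling the center bin count as cross.
    Higher means stronger insulation at the candidate boundary.
    """
    res = cmap.resolution
    c = cmap.bin_of(center_bp)
    f = int(round(flank_bp / res))
    n = cmap.n_bins
    lo, hi = max(0, c - f), min(n, c + f + 1)
    sub = cmap.matrix[lo:hi, lo:hi]
    cc = c - lo
    iu, ju = np.triu_indices(sub.shape[0], k=min_sep_bins)
    vals = np.nan_to_num(sub[iu, ju])
    cross_mask = (iu < cc) & (ju > cc)
    cross = vals[cross_mask].sum()
    within = vals[~cross_mask].sum()
    if cross <= 0:
        return float("inf") if within > 0 else float("nan")
    return float(within / cross)


def tu_band_oe(oe: ContactMap, tu_bodies_bp, min_sep_bins: int = 3,
               max_sep_bins: int = 15) -> float:
    """Mean O/E of unit-anchored pixels at mid-range separations.

    Low values mean the transcribed bodies are contact-depleted relative to
    distance expectation -- the map signature of an externalized loop.
    Zero-coverage pixels anchored in a unit count as 0 (fully depleted).
    """
    n = oe.n_bins
    in_tu = np.zeros(n, dtype=bool)
    for (a, b) in tu_bodies_bp:
        in_tu[oe.bin_of(a):oe.bin_of(b) + 1] = True
    vals = []
    for t in np.where(in_tu)[0]:
        for off in range(min_sep_bins, max_sep_bins + 1):
            for j in (t - off, t + off):
                if 0 <= j < n:
                    v = oe.matrix[t, j]
                    vals.append(v if np.isfinite(v) else 0.0)
    return float(np.mean(vals)) if vals else float("nan")


def corner_vs_flank(oe: ContactMap, end_left_bp: float, end_right_bp: float,
                    box_bins: int = 1, flank_bins: int = 10) -> float:
    """O/E around the (left gene end, right gene start) pixel relative to
    pixels at the same diagonal distance nearby (>1 = corner enrichment).

    The corner is the mean over a (2*box+1)^2 box so that bridges pinned a
    bead or two inside the gap still register.
    """
    i = oe.bin_of(end_left_bp)
    j = oe.bin_of(end_right_bp)
    n = oe.n_bins
    box = oe.matrix[max(0, i - box_bins):i + box_bins + 1,
                    max(0, j - box_bins):j + box_bins + 1]
    corner = np.nanmean(box) if np.isfinite(box).any() else np.nan
    ref = []
    for off in range(-flank_bins, flank_bins + 1):
        if abs(off) <= box_bins:
            continue
        ii, jj = i + off, j + off
        if 0 <= ii < n and 0 <= jj < n:
            ref.append(oe.matrix[ii, jj])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref_mean = np.nanmean(ref) if ref else np.nan
    if not np.isfinite(ref_mean) or ref_mean == 0 or not np.isfinite(corner):
        return float("nan")
    return float(corner / ref_mean)


def run_regime_experiment(regimes: list[str], stages: list[str],
                          n_replicates: int, base_seed: int = 0,
                          cfg: MechanismConfig | None = None) -> dict:
    """Replicated pipeline runs; returns per-(regime, stage) score arrays.

    Replicates are seed-paired across regimes/stages so paired sign tests
    are meaningful.
    """
    cfg = cfg or MechanismConfig()
    tus, region, info = build_convergent_segment(cfg)
    out: dict[tuple[str, str], dict] = {}
    for regime in regimes:
        for stage in stages:
            acc: dict[str, list] = {k: [] for k in
                                    ("quadrant", "gap_insulation", "corner",
                                     "cross_prominence", "cps_tu_mean")}
            for r in range(n_replicates):
                res = run_pipeline(regime, stage, base_seed + 1000 * r, cfg,
                                   tus=tus, region=region, info=info)
                acc["quadrant"].append(np.nanmean(res["quadrant"]))
                acc["gap_insulation"].append(np.nanmean(res["gap_insulation"]))
                acc["corner"].append(np.nanmean(res["corner"]))
                acc["cross_prominence"].append(res["cross_prominence"])
                acc["cps_tu_mean"].append(res["cps_tu_mean"])
            out[(regime, stage)] = {k: np.array(v) for k, v in acc.items()}
    return out


def run_insulation_by_class(regime: str, stages: list[str],
                            n_replicates: int, base_seed: int = 0,
                            cfg: MechanismConfig | None = None,
                            min_pairs: int = 5) -> dict:
    """Gap insulation for convergent tandem-pair classes at each stage.

    Tandems are labeled by median splits on length and weighted activity; a
    convergent pair inherits the class of its weaker/shorter member (the
    feature that limits boundary formation).  Per class and stage, the
    per-gap scores are pooled across replicates; classes with fewer than
    ``min_pairs`` scored gaps are reported with ``skipped=True``.
    """
    from .annotations import classify_tandems

    cfg = cfg or MechanismConfig()
    tus, region, info = build_convergent_segment(cfg)
    tandems = classify_tandems(build_tandems(tus))
    pairs = [p for p in adjacent_pairs(tandems) if p.orientation == "FR"]

    def pair_class(p) -> str:
        weaker = min((p.left, p.right),
                     key=lambda t: (t.length, t.fpkm_weighted))
        return weaker.strength_class

    # gap g corresponds to convergent pair g in layout order
    gap_class = [pair_class(p) for p in pairs]
    out: dict[str, dict] = {}
    for stage in stages:
        scores: dict[str, list[float]] = {}
        for r in range(n_replicates):
            res = run_pipeline(regime, stage, base_seed + 1000 * r, cfg,
                               tus=tus, region=region, info=info)
            for g, v in enumerate(res["gap_insulation"]):
                scores.setdefault(gap_class[g], []).append(float(v))
        out[stage] = {
            cls: {"scores": np.array(v), "n_scored": len(v),
                  "skipped": len(v) < min_pairs}
            for cls, v in scores.items()}
        out[stage]["pairs"] = pairs
    return out
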