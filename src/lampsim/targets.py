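"""Headline quantities recomputed from scratch by running the simulator.

Each function runs the relevant part of the pipeline at desk scale and
returns the quantity on the scale conventionally reported (percent where a
percentage is quoted, kb where kb are quoted).
"""

from __future__ import annotations

import numpy as np

from .annotations import TranscriptionUnit
from .sim1d import Sim1D, Sim1DConfig, build_bead_array, lef_cycle_stats
from .sim3d import Sim3DConfig, coarse_grain, init_conformation, relax
from .simhic import contacts_from_conformation, normalize_per_site, site_incidence
from .synthetic import SyntheticGenomeSpec, gen_tus

__all__ = [
    "max_site_contacts_after_normalization", "lef_passage_percentage",
    "cohesive_spacing_kb", "overstep_probability_per_second",
    "chromatin_per_lef_kb",
]


def max_site_contacts_after_normalization(seed: int,
                                          region_bp: int = 5_000_000,
                                          cap: int = 8) -> dict:
    """1D + 3D pipeline on a synthetic segment; one conformation's contacts
    are capped per site; returns the maximum incident sum over sites."""
    spec = SyntheticGenomeSpec(
        region_bp=region_bp,
        grammar="F F R gap F R gap R F gap F R gap R R F",
        naked_fraction=0.55, seed=seed)
    tus = gen_tus(spec)
    beads = build_bead_array(tus, (0, region_bp))
    sim = Sim1D(beads, Sim1DConfig(seed=seed, dt=0.07, load_rate_scale=0.02))
    sim.advance(400.0)
    snap = sim.snapshot()
    cfg3 = Sim3DConfig(rna_prefactor_nm=0.2, rna_bp_cap=60_000.0)
    chain = coarse_grain(beads, snap, cfg3)
    conf = init_conformation(chain, cfg3)
    relax(conf, 600, cfg3, seed=seed)
    radii = np.concatenate([chain.base_radius] * 2)
    contacts = contacts_from_conformation(conf.coords, radii, conf.chromatid,
                                          chain.cluster_mid_bp(), 30.0)
    before = int(site_incidence(contacts).max()) if len(contacts) else 0
    capped = normalize_per_site(contacts, cap=cap,
                                rng=np.random.default_rng(seed))
    after = int(site_incidence(capped).max()) if len(capped) else 0
    return {"value": after, "before_cap": before, "n": len(capped)}


def lef_passage_percentage(seed: int, n_cycles: int = 2000) -> dict:
    """Percent of extruder load-unload cycles whose loop spans >= 1 Mb before
    removal, on a naked array at default speed and lifetime."""
    stats = lef_cycle_stats(n_cycles=n_cycles,
                            config=Sim1DConfig(seed=seed, dt=0.07))
    return {"value": 100.0 * stats["frac_span_ge_1mb"], "n": stats["n_cycles"]}


def cohesive_spacing_kb(seed: int, region_bp: int = 10_000_000,
                        n_seeds: int = 100) -> dict:
    """Mean adjacent-cohesive spacing (kb) at initialization, averaged over
    seeds, on a naked array with the default loading density."""
    beads = build_bead_array([], (0, region_bp))
    means = []
    for k in range(n_seeds):
        sim = Sim1D(beads, Sim1DConfig(seed=seed + k))
        pos = np.sort(beads.bead_start[sim.coh_bead])
        means.append(np.diff(pos).mean())
    return {"value": float(np.mean(means)) / 1000.0, "n": n_seeds}


def overstep_probability_per_second(vp: float = 100.0,
                                    v_extruder: float = 675.0) -> dict:
    """Velocity-ratio estimate of the per-second bypass probability an
    extruder needs to traverse a dense polymerase convoy."""
    return {"value": round(vp / v_extruder, 2), "n": 1}


def chromatin_per_lef_kb(seed: int, region_bp: int = 9_000_000) -> dict:
    """Region length divided by the constant loaded-extruder count (kb)."""
    beads = build_bead_array([], (0, region_bp))
    sim = Sim1D(beads, Sim1DConfig(seed=seed))
    n0 = len(sim.lef_left)
    sim.advance(50.0)
    assert len(sim.lef_left) == n0
    return {"value": region_bp / n0 / 1000.0, "n": n0}
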