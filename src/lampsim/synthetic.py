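"""Synthetic fixtures: transcription-unit landscapes with controllable
orientation grammars, and toy contact maps with planted domains, cross loci
and compartment plaids.

Everything is reproducible from a seed and emits objects that pass the
consuming modules' validators, so the whole pipeline is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import TranscriptionUnit
from .contactmap import ContactMap
from .domains import DomainSet

__all__ = ["SyntheticGenomeSpec", "gen_tus", "gen_block_map"]


@dataclass
class SyntheticGenomeSpec:
    """Parameters of a synthetic transcribed landscape.

    ``grammar`` is a whitespace-separated sequence over {F, R, gap}; units are
    placed left to right following it (a trailing implicit gap pads the
    region).  Lengths and activities are log-normal.
    """

    region_bp: int = 5_000_000
    grammar: str = "F F R gap F R gap R F"
    tu_length_median_bp: float = 40_000.0
    tu_length_sigma_log: float = 1.0
    fpkm_median: float = 1.0
    fpkm_sigma_log: float = 1.5
    naked_fraction: float = 0.4
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("region_bp", "tu_length_median_bp", "tu_length_sigma_log",
                     "fpkm_median", "fpkm_sigma_log"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.naked_fraction < 1:
            raise ValueError("naked_fraction must be in (0, 1)")


def gen_tus(spec: SyntheticGenomeSpec) -> list[TranscriptionUnit]:
    """Generate a unit list following the orientation grammar.

    Unit lengths are drawn log-normal and rescaled so that transcribed bp
    sum to ``(1 - naked_fraction) * region_bp``; gap tokens and inter-unit
    spacers share the naked remainder.  Activities (exon = intron FPKM) are
    log-normal.  Raises when the grammar cannot be packed.
    """
    rng = np.random.default_rng(spec.seed)
    tokens = spec.grammar.split()
    strands = [t for t in tokens if t in ("F", "R")]
    if not strands:
        raise ValueError("grammar contains no units")
    n = len(strands)
    n_gap_tokens = sum(1 for t in tokens if t == "gap")

    raw = rng.lognormal(np.log(spec.tu_length_median_bp),
                        spec.tu_length_sigma_log, size=n)
    tu_total = (1.0 - spec.naked_fraction) * spec.region_bp
    lengths = np.maximum(900, (raw / raw.sum() * tu_total)).astype(int)

    # naked bp: small spacers between all units, larger blocks at gap tokens
    naked_total = spec.region_bp - int(lengths.sum())
    if naked_total < (n + 1 + n_gap_tokens) * 100:
        raise ValueError("infeasible packing: units leave no room for gaps")
    n_slots = n + 1 + n_gap_tokens
    weights = rng.dirichlet(np.ones(n_slots) * 4.0)
    naked = np.maximum(100, (weights * naked_total)).astype(int)
    # re-balance rounding into the final slot
    naked[-1] += naked_total - int(naked.sum())
    if naked[-1] < 0:
        naked[:-1] += naked[-1] // (n_slots - 1)
        naked[-1] = 100

    fpkm = rng.lognormal(np.log(spec.fpkm_median), spec.fpkm_sigma_log, size=n)

    tus = []
    pos = 0
    slot = 0
    unit_idx = 0
    pos += int(naked[slot]); slot += 1
    for tok in tokens:
        if tok == "gap":
            pos += int(naked[slot]); slot += 1
            continue
        ln = int(lengths[unit_idx])
        if pos + ln > spec.region_bp:
            raise ValueError("infeasible packing: grammar overflows region")
        strand = "+" if tok == "F" else "-"
        tus.append(TranscriptionUnit(
            f"TU{unit_idx:04d}", spec.chrom, pos, pos + ln, strand,
            fpkm_exon=float(fpkm[unit_idx]), fpkm_intron=float(fpkm[unit_idx])))
        pos += ln
        unit_idx += 1
        if slot < n_slots:
            pos += int(naked[slot]); slot += 1
    return tus


def gen_block_map(n_bins: int, resolution: int,
                  domains: list[tuple[int, int]] | None = None,
                  enrichment: float = 3.0,
                  decay_exponent: float = 1.0,
                  depth: int = 100_000,
                  cross_bins: list[int] | None = None,
                  cross_halfwidth_bins: int = 3,
                  compartment_vector: np.ndarray | None = None,
                  compartment_strength: float = 0.0,
                  rng: np.random.Generator | None = None,
                  chrom: str = "chrS") -> ContactMap:
    """Sample a toy contact map with planted structure.

    The base intensity decays as ``(|i-j| + 1) ** -decay_exponent``; pairs
    within a planted domain (bin intervals) are multiplied by ``enrichment``;
    a planted cross locus ``c`` suppresses its contacts beyond
    ``cross_halfwidth_bins`` and boosts those within; an optional two-level
    compartment vector adds a plaid modulation.  Counts are Poisson with the
    requested total depth (upper triangle), symmetrized.
    """
    rng = rng or np.random.default_rng()
    i, j = np.triu_indices(n_bins)
    lam = (np.abs(i - j) + 1.0) ** (-decay_exponent)
    if domains:
        for (a, b) in domains:
            inside = (i >= a) & (i < b) & (j >= a) & (j < b)
            lam[inside] *= enrichment
    if cross_bins:
        for c in cross_bins:
            touches = (i == c) | (j == c)
            near = np.abs(i - j) <= cross_halfwidth_bins
            lam[touches & ~near] *= 0.02
            lam[touches & near] *= 4.0
    if compartment_vector is not None and compartment_strength > 0:
        ev = np.asarray(compartment_vector, dtype=float)
        lam *= 1.0 + compartment_strength * np.sign(ev[i]) * np.sign(ev[j])
    lam *= depth / lam.sum()
    counts = rng.poisson(lam).astype(float)
    mat = np.zeros((n_bins, n_bins))
    mat[i, j] = counts
    mat[j, i] = counts
    return ContactMap(mat, resolution, chrom=chrom)


def domains_to_domainset(domains: list[tuple[int, int]], resolution: int,
                         chrom: str = "chrS") -> DomainSet:
    """Bin-interval domain layout -> bp DomainSet."""
    iv = np.array([(a * resolution, b * resolution) for a, b in domains],
                  dtype=np.int64)
    return DomainSet(iv, chrom=chrom, resolution=resolution)
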