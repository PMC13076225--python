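"""Transcription-unit annotations, activity metrics, tandems and pair classes.

Coordinates are 0-based half-open throughout; conversion to/from 1-based GTF
happens only at file boundaries.  Units overlapping on opposite strands are
legal (strand-separated de novo assemblies produce them); same-strand overlap
is an input error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptionUnit", "Tandem", "TUPair",
    "compute_fpkm", "tu_activity", "build_tandems", "classify_tandems",
    "pair_orientation", "adjacent_pairs",
    "read_gtf", "read_bed12", "read_activity_table", "write_tandems_bed6",
    "write_gtf",
]

STRANDS = ("+", "-")


@dataclass
class TranscriptionUnit:
    """A stranded transcribed interval with exon structure and activity."""

    tu_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    fpkm_exon: float | None = None
    fpkm_intron: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.tu_id}: start must be < end")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.tu_id}: strand must be + or -")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)
        prev_end = self.start
        for (s, e) in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValueError(f"{self.tu_id}: exons must be sorted, "
                                 "non-overlapping and inside the unit")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def fpkm(self) -> float:
        """Activity: min of exon and intron FPKM over the available values."""
        vals = [v for v in (self.fpkm_exon, self.fpkm_intron) if v is not None]
        if not vals:
            return 0.0
        return tu_activity(*vals) if len(vals) == 2 else float(vals[0])


@dataclass
class Tandem:
    """Maximal run of consecutive co-directional units."""

    members: list[TranscriptionUnit]
    strength_class: str | None = None

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end

    @property
    def strand(self) -> str:
        return self.members[0].strand

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def fpkm_weighted(self) -> float:
        """Length-weighted mean activity over member units."""
        lengths = np.array([tu.length for tu in self.members], dtype=float)
        fpkms = np.array([tu.fpkm for tu in self.members], dtype=float)
        return float((fpkms * lengths).sum() / lengths.sum())


@dataclass
class TUPair:
    left: TranscriptionUnit | Tandem
    right: TranscriptionUnit | Tandem
    is_boundary: bool | None = None

    @property
    def orientation(self) -> str:
        return pair_orientation(self.left, self.right)

    @property
    def gap(self) -> int:
        return self.right.start - self.left.end


def compute_fpkm(read_count: float, total_mapped: float, length: float) -> float:
    """Reads per kb per billion mapped: ``N_i * 1e9 / (N_0 * L_i)``."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if length <= 0:
        raise ValueError("length must be positive")
    return read_count * 1e9 / (total_mapped * length)


def tu_activity(fpkm_exon: float, fpkm_intron: float) -> float:
    """Unit activity: the minimum of exon and intron FPKM."""
    if fpkm_exon < 0 or fpkm_intron < 0:
        raise ValueError("FPKM values must be non-negative")
    return float(min(fpkm_exon, fpkm_intron))


def _check_sorted(tus: Sequence[TranscriptionUnit]) -> None:
    for a, b in zip(tus, tus[1:]):
        if (b.chrom, b.start) < (a.chrom, a.start):
            raise ValueError("units must be sorted by (chrom, start)")
        if a.chrom == b.chrom and a.strand == b.strand and b.start < a.end:
            raise ValueError(
                f"same-strand overlap between {a.tu_id} and {b.tu_id}")


def build_tandems(tus: Sequence[TranscriptionUnit]) -> list[Tandem]:
    """Merge maximal runs of consecutive same-strand units into tandems.

    A run breaks whenever the strand changes or the chromosome changes, so
    every unit belongs to exactly one tandem.
    """
    _check_sorted(tus)
    tandems: list[Tandem] = []
    run: list[TranscriptionUnit] = []
    for tu in tus:
        if run and (tu.strand != run[-1].strand or tu.chrom != run[-1].chrom):
            tandems.append(Tandem(run))
            run = []
        run.append(tu)
    if run:
        tandems.append(Tandem(run))
    return tandems


def classify_tandems(tandems: Sequence[Tandem]) -> list[Tandem]:
    """Label tandems by median splits on length and weighted activity.

    Ties go to the lower class ("short"/"weak"): a tandem is "long" only when
    strictly above the median length, "strong" only when strictly above the
    median activity.
    """
    if len(tandems) == 0:
        raise ValueError("need at least one tandem to classify")
    lengths = np.array([t.length for t in tandems], dtype=float)
    acts = np.array([t.fpkm_weighted for t in tandems], dtype=float)
    med_len = float(np.median(lengths))
    med_act = float(np.median(acts))
    for t, ln, ac in zip(tandems, lengths, acts):
        size = "long" if ln > med_len else "short"
        strength = "strong" if ac > med_act else "weak"
        t.strength_class = f"{size}-{strength}"
    return list(tandems)


def pair_orientation(left, right) -> str:
    """Orientation class of an ordered pair: FF, RR, FR (convergent) or RF
    (divergent)."""
    if left.end > right.start:
        raise ValueError("units overlap; pair cannot be classified")
    key = (left.strand, right.strand)
    return {("+", "+"): "FF", ("-", "-"): "RR",
            ("+", "-"): "FR", ("-", "+"): "RF"}[key]


def adjacent_pairs(units: Sequence) -> list[TUPair]:
    """All adjacent (unit_i, unit_{i+1}) pairs on the same chromosome."""
    pairs = []
    for a, b in zip(units, units[1:]):
        if a.chrom != b.chrom or a.end > b.start:
            continue
        pairs.append(TUPair(a, b))
    return pairs


# --- file boundaries ---------------------------------------------------------

def read_gtf(path: str) -> list[TranscriptionUnit]:
    """Read transcripts + exons from a GTF file (1-based closed -> 0-based
    half-open)."""
    tx: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, feat, start, end, _, strand, _, attrs = f[:9]
            if feat not in ("transcript", "exon"):
                continue
            tid = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("transcript_id"):
                    tid = item.split(None, 1)[1].strip('"')
                    break
            if tid is None:
                continue
            rec = tx.setdefault(tid, {"chrom": chrom, "strand": strand,
                                      "start": None, "end": None, "exons": []})
            s0, e0 = int(start) - 1, int(end)
            if feat == "transcript":
                rec["start"], rec["end"] = s0, e0
            else:
                rec["exons"].append((s0, e0))
    tus = []
    for tid, rec in tx.items():
        exons = sorted(rec["exons"])
        start = rec["start"] if rec["start"] is not None else exons[0][0]
        end = rec["end"] if rec["end"] is not None else exons[-1][1]
        tus.append(TranscriptionUnit(tid, rec["chrom"], start, end,
                                     rec["strand"], exons=exons))
    tus.sort(key=lambda t: (t.chrom, t.start, t.end))
    return tus


def write_gtf(path: str, tus: Iterable[TranscriptionUnit]) -> None:
    """Write transcripts + exons as GTF (0-based half-open -> 1-based closed)."""
    with open(path, "w") as fh:
        for tu in tus:
            attrs = f'gene_id "{tu.tu_id}"; transcript_id "{tu.tu_id}";'
            fh.write("\t".join([tu.chrom, "lampsim", "transcript",
                                str(tu.start + 1), str(tu.end), ".",
                                tu.strand, ".", attrs]) + "\n")
            for s, e in tu.exons:
                fh.write("\t".join([tu.chrom, "lampsim", "exon",
                                    str(s + 1), str(e), ".",
                                    tu.strand, ".", attrs]) + "\n")


def read_bed12(path: str) -> list[TranscriptionUnit]:
    """Read transcript models from BED12 (block fields give the exons)."""
    tus = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _, strand = f[:6]
            start, end = int(start), int(end)
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            else:
                exons = [(start, end)]
            tus.append(TranscriptionUnit(name, chrom, start, end, strand,
                                         exons=exons))
    tus.sort(key=lambda t: (t.chrom, t.start, t.end))
    return tus


def read_activity_table(path: str) -> pd.DataFrame:
    """Read a tab-separated (tu_id, exon_fpkm, intron_fpkm) table."""
    df = pd.read_csv(path, sep="\t")
    required = {"tu_id", "exon_fpkm", "intron_fpkm"}
    if not required.issubset(df.columns):
        raise ValueError(f"activity table must have columns {sorted(required)}")
    return df


def attach_activity(tus: Sequence[TranscriptionUnit],
                    table: pd.DataFrame) -> list[TranscriptionUnit]:
    """Attach exon/intron FPKM values from an activity table (by tu_id)."""
    idx = table.set_index("tu_id")
    for tu in tus:
        if tu.tu_id in idx.index:
            row = idx.loc[tu.tu_id]
            tu.fpkm_exon = float(row["exon_fpkm"])
            iv = row["intron_fpkm"]
            tu.fpkm_intron = None if pd.isna(iv) else float(iv)
    return list(tus)


def write_tandems_bed6(path: str, tandems: Iterable[Tandem]) -> None:
    """BED6 of tandems: class in the name field, weighted FPKM in score."""
    with open(path, "w") as fh:
        for t in tandems:
            name = t.strength_class or "unclassified"
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{name}\t"
                     f"{t.fpkm_weighted:.6g}\t{t.strand}\n")
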