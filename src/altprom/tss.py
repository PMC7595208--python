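"""Transcription-start-site geometry: promoter shape and repeat placement.

Promoters are classified as *dispersed* when initiation is spread over a
region of roughly 100 nucleotides or more across at least three distinct
start sites, and *focused* otherwise.  A second question the TSS geometry
answers is whether any transcript would carry a repeat tract in its 5' UTR:
that happens exactly when some TSS lies transcript-upstream of the repeat's
far edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genemodel import GenomicInterval

__all__ = [
    "TssSet",
    "tss_spread",
    "classify_promoter",
    "repeat_in_any_utr",
    "read_tss_bed",
]


@dataclass(frozen=True)
class TssSet:
    """Observed transcription start positions on one chromosome/strand.

    Positions are 0-based and stored sorted ascending (the constructor
    sorts); optional per-position support counts (CAGE reads, RACE clones)
    follow the sorted order.
    """

    chrom: str
    positions: tuple[int, ...]
    strand: str
    counts: Optional[tuple[int, ...]] = None

    def __init__(
        self,
        chrom: str,
        positions: Sequence[int],
        strand: str,
        counts: Optional[Sequence[int]] = None,
    ):
        if not chrom:
            raise ValueError("chrom must be nonempty")
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        positions = list(positions)
        if not positions:
            raise ValueError("a TSS set must contain at least one position")
        if counts is not None:
            counts = list(counts)
            if len(counts) != len(positions):
                raise ValueError("counts must parallel positions")
            order = sorted(range(len(positions)), key=positions.__getitem__)
            counts = tuple(counts[i] for i in order)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "positions", tuple(sorted(positions)))
        object.__setattr__(self, "strand", strand)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.positions)


def tss_spread(t: TssSet) -> int:
    """Width in bp of the initiation region: max(positions) - min(positions)."""
    return t.positions[-1] - t.positions[0]


def classify_promoter(t: TssSet, dispersed_threshold_bp: int = 100) -> str:
    """``"dispersed"`` or ``"focused"``.

    Dispersed requires the TSS spread to reach ``dispersed_threshold_bp``
    (default ~100 nt, the conventional dispersed-promoter scale) *and* at
    least three distinct start positions — two isolated starts do not
    constitute a spread initiation region.
    """
    distinct = len(set(t.positions))
    if tss_spread(t) >= dispersed_threshold_bp and distinct >= 3:
        return "dispersed"
    return "focused"


def repeat_in_any_utr(t: TssSet, repeat: GenomicInterval) -> bool:
    """Would any transcript from these TSSs carry the repeat in its 5' UTR?

    True iff some TSS lies strictly transcript-upstream of the repeat's far
    edge, so that transcription initiated there reads through the whole
    repeat before reaching the first exon.  A TSS exactly at the repeat
    boundary does not qualify (strict-inequality convention).
    """
    if t.chrom != repeat.chrom:
        raise ValueError(
            f"TSS set on {t.chrom} but repeat on {repeat.chrom}"
        )
    if t.strand == "-":
        # transcript-upstream = genomically greater; far edge = repeat.end - 1
        return any(p >= repeat.end for p in t.positions)
    return any(p < repeat.start for p in t.positions)


def read_tss_bed(path, strand: Optional[str] = None) -> TssSet:
    """Read TSS positions from a BED6 file.

    The TSS of each record is the interval start on '+' and ``end - 1`` on
    '-'; the BED score column is kept as the support count.  All records
    must share one chromosome and (unless ``strand`` overrides the column)
    one strand.
    """
    chroms: set[str] = set()
    strands: set[str] = set()
    positions: list[int] = []
    counts: list[int] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}, line {lineno}: BED6 requires 6 columns"
                )
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            rec_strand = strand if strand is not None else parts[5]
            chroms.add(chrom)
            strands.add(rec_strand)
            positions.append(end - 1 if rec_strand == "-" else start)
            try:
                counts.append(int(float(parts[4])))
            except ValueError:
                counts.append(0)
    if len(chroms) != 1:
        raise ValueError(f"{path}: TSS records span chromosomes {sorted(chroms)}")
    if len(strands) != 1:
        raise ValueError(f"{path}: TSS records span strands {sorted(strands)}")
    return TssSet(chroms.pop(), positions, strands.pop(), counts)
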