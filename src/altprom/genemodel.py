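"""Gene-locus model for a multi-promoter gene and its junction annotation.

The locus abstraction mirrors genes such as human *TCF4*: a long
reverse-strand gene whose many alternative 5' exons, each driven by its own
promoter, splice onto a shared ladder of internal exons.  Which 5' exon a
transcript starts from decides the N-terminus of the encoded protein, so
transcripts are grouped into "events" (a 5'-exon/acceptor pair such as
``"3b-4"``) and events into protein-isoform groups (``TCF4-A`` ... ``TCF4-I``).

Splice junctions are identified by exact genomic coordinates; a curated
annotation table maps each junction to its event and isoform labels.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based, half-open.  On-disk annotation tables
use 1-based inclusive intron coordinates (the STAR convention); readers and
writers convert at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "MOTIF_CLASSES",
    "ISOFORM_LABELS",
    "AnnotationError",
    "GenomicInterval",
    "SpliceJunction",
    "AnnotationRow",
    "Annotation",
    "GeneModel",
    "load_annotation",
    "write_annotation",
    "match_junction",
    "build_demo_gene",
    "build_demo_annotation",
    "DEMO_WINDOW_EVENTS",
]

#: Intron motif classes in the order STAR encodes them (code 0..6).
MOTIF_CLASSES = (
    "non-canonical",
    "GT/AG",
    "CT/AC",
    "GC/AG",
    "CT/GC",
    "AT/AC",
    "GT/AT",
)

#: Recognised protein-isoform group labels.  ``"none"`` marks junctions that
#: are quantified (e.g. internal-exon junctions) but excluded from
#: isoform-level aggregation; ``"other"`` groups minor isoforms.
ISOFORM_LABELS = (
    "TCF4-A",
    "TCF4-B",
    "TCF4-C",
    "TCF4-D",
    "TCF4-E",
    "TCF4-H",
    "TCF4-I",
    "other",
    "none",
)


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent junction annotation tables."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval on a fixed strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class SpliceJunction:
    """One intron, identified by its genomic footprint.

    ``start`` is the first intronic base, ``end`` the exclusive last intronic
    base, both in genomic (left-to-right) order irrespective of strand.
    Strand ``"."`` marks junctions whose strand the aligner could not assign;
    they are kept at I/O time and resolved (or dropped) downstream.
    """

    chrom: str
    start: int
    end: int
    strand: str
    motif: str = "GT/AG"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.motif not in MOTIF_CLASSES:
            raise ValueError(f"invalid motif {self.motif!r}")

    @property
    def key(self) -> str:
        """Identity string: chrom, intron coordinates and strand."""
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    def interval(self) -> GenomicInterval:
        strand = "+" if self.strand == "." else self.strand
        return GenomicInterval(self.chrom, self.start, self.end, strand)


@dataclass(frozen=True)
class AnnotationRow:
    """Maps one curated junction to its event and isoform-group labels."""

    junction: SpliceJunction
    event_label: str
    isoform_label: str

    def __post_init__(self) -> None:
        if not self.event_label:
            raise AnnotationError("event_label must be nonempty")
        if self.isoform_label not in ISOFORM_LABELS:
            raise AnnotationError(
                f"unknown isoform label {self.isoform_label!r}; "
                f"expected one of {ISOFORM_LABELS}"
            )


class Annotation:
    """A validated, order-preserving collection of :class:`AnnotationRow`.

    Junction identity is the full (chrom, start, end, strand) tuple; two rows
    sharing a junction are rejected.
    """

    def __init__(self, rows: Iterable[AnnotationRow]):
        self.rows: list[AnnotationRow] = list(rows)
        self._by_key: dict[str, AnnotationRow] = {}
        for row in self.rows:
            key = row.junction.key
            if key in self._by_key:
                raise AnnotationError(f"duplicate junction in annotation: {key}")
            self._by_key[key] = row

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[AnnotationRow]:
        return iter(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return self.rows == other.rows

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    def get(self, key: str) -> Optional[AnnotationRow]:
        return self._by_key.get(key)

    @property
    def events(self) -> list[str]:
        """Distinct event labels in first-seen order."""
        seen: dict[str, None] = {}
        for row in self.rows:
            seen.setdefault(row.event_label, None)
        return list(seen)

    def event_to_isoform(self) -> dict[str, str]:
        """Event label -> isoform-group label.

        Raises :class:`AnnotationError` if two junctions of one event carry
        different isoform labels.
        """
        mapping: dict[str, str] = {}
        for row in self.rows:
            prev = mapping.setdefault(row.event_label, row.isoform_label)
            if prev != row.isoform_label:
                raise AnnotationError(
                    f"event {row.event_label!r} maps to both isoform "
                    f"{prev!r} and {row.isoform_label!r}"
                )
        return mapping


_ANNOTATION_COLUMNS = (
    "chrom",
    "intron_start",
    "intron_end",
    "strand",
    "exon_event",
    "isoform",
)


def load_annotation(path) -> Annotation:
    """Read a junction annotation TSV.

    The on-disk table has a header and columns ``chrom  intron_start
    intron_end  strand  exon_event  isoform`` with 1-based inclusive intron
    coordinates; they are converted to the internal 0-based half-open
    convention.  An optional ``motif`` column is honoured (default GT/AG on
    '+', CT/AC on '-').
    """
    with open(path, "rt", encoding="utf-8") as fh:
        return _parse_annotation(fh, str(path))


def _parse_annotation(fh: io.TextIOBase, name: str) -> Annotation:
    header = fh.readline()
    if not header:
        raise AnnotationError(f"{name}: empty annotation file")
    cols = header.rstrip("\n").split("\t")
    try:
        idx = {c: cols.index(c) for c in _ANNOTATION_COLUMNS}
    except ValueError as exc:
        raise AnnotationError(f"{name}: missing required column ({exc})") from None
    motif_idx = cols.index("motif") if "motif" in cols else None

    rows = []
    for lineno, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < len(cols):
            raise AnnotationError(
                f"{name}, line {lineno}: expected {len(cols)} columns, "
                f"got {len(parts)}"
            )
        try:
            chrom = parts[idx["chrom"]]
            start1 = int(parts[idx["intron_start"]])
            end1 = int(parts[idx["intron_end"]])
            strand = parts[idx["strand"]]
            if motif_idx is not None:
                motif = parts[motif_idx]
            else:
                motif = "CT/AC" if strand == "-" else "GT/AG"
            junction = SpliceJunction(chrom, start1 - 1, end1, strand, motif)
            row = AnnotationRow(
                junction=junction,
                event_label=parts[idx["exon_event"]],
                isoform_label=parts[idx["isoform"]],
            )
        except (ValueError, AnnotationError) as exc:
            if isinstance(exc, AnnotationError) and "duplicate" in str(exc):
                raise
            raise AnnotationError(f"{name}, line {lineno}: {exc}") from None
        rows.append(row)
    return Annotation(rows)


def write_annotation(annotation: Annotation, path) -> None:
    """Write an annotation TSV (1-based inclusive intron coordinates)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(_ANNOTATION_COLUMNS + ("motif",)) + "\n")
        for row in annotation:
            j = row.junction
            fh.write(
                f"{j.chrom}\t{j.start + 1}\t{j.end}\t{j.strand}\t"
                f"{row.event_label}\t{row.isoform_label}\t{j.motif}\n"
            )


def match_junction(junction: SpliceJunction, annotation: Annotation) -> Optional[str]:
    """Return the event label of an exactly matching annotated junction.

    Matching is exact on (chrom, start, end, strand); the motif is not part
    of junction identity.  Returns ``None`` when no annotated junction
    matches.
    """
    row = annotation.get(junction.key)
    return row.event_label if row is not None else None


@dataclass
class GeneModel:
    """A multi-promoter gene locus.

    ``internal_exons`` are the shared exon ladder (named "3", "4", ... in
    transcript order); ``five_prime_exons`` the alternative first exons; the
    ``repeat_tract`` is the trinucleotide-repeat interval sitting in the
    intron between internal exons 3 and 4.
    """

    gene_region: GenomicInterval
    internal_exons: dict[str, GenomicInterval] = field(default_factory=dict)
    five_prime_exons: dict[str, GenomicInterval] = field(default_factory=dict)
    repeat_tract: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        strand = self.gene_region.strand
        for name, exon in {**self.internal_exons, **self.five_prime_exons}.items():
            if not self.gene_region.contains(exon):
                raise ValueError(f"exon {name!r} outside the gene region")
            if exon.strand != strand:
                raise ValueError(f"exon {name!r} strand differs from the gene")
        if self.repeat_tract is not None:
            if not self.gene_region.contains(self.repeat_tract):
                raise ValueError("repeat tract outside the gene region")

    @property
    def strand(self) -> str:
        return self.gene_region.strand

    def all_exons(self) -> dict[str, GenomicInterval]:
        return {**self.internal_exons, **self.five_prime_exons}


def _iv(chrom: str, start: int, end: int, strand: str) -> GenomicInterval:
    return GenomicInterval(chrom, start, end, strand)


def build_demo_gene() -> GeneModel:
    """A reverse-strand demonstration locus with the TCF4 exon architecture.

    The locus sits on chr18 within the hg19 TCF4 footprint
    (chr18:52,889,562-53,332,018): internal exons 3..21 descend genomically
    (the gene is minus-strand, so transcript order runs right to left), the
    CTG repeat tract lies in the intron between internal exons 3 and 4
    inside the chr18:53,252,500-53,254,500 window, and alternative 5' exons
    (3b/3c/3d, 4aI/4aIII/4b/4c, 8a/8bII/8cII, 10a) sit immediately
    transcript-upstream of their acceptor internal exons.  Coordinates are
    synthetic: the exon sizes and spacings are round numbers chosen for
    readability, not the real curated positions.
    """
    chrom, strand = "chr18", "-"
    region = _iv(chrom, 52_889_562, 53_332_018, strand)

    internal: dict[str, GenomicInterval] = {
        "3": _iv(chrom, 53_256_000, 53_256_150, strand),
        "4": _iv(chrom, 53_251_000, 53_251_150, strand),
    }
    for k in range(5, 22):
        start = 53_240_000 - (k - 5) * 20_000
        internal[str(k)] = _iv(chrom, start, start + 150, strand)

    five_prime = {
        "3b": _iv(chrom, 53_290_000, 53_290_150, strand),
        "3c": _iv(chrom, 53_285_000, 53_285_100, strand),
        "3d": _iv(chrom, 53_280_000, 53_280_100, strand),
        "4aI": _iv(chrom, 53_253_200, 53_253_300, strand),
        "4aIII": _iv(chrom, 53_253_100, 53_253_190, strand),
        "4b": _iv(chrom, 53_253_000, 53_253_080, strand),
        "4c": _iv(chrom, 53_252_700, 53_252_800, strand),
        "8a": _iv(chrom, 53_183_000, 53_183_100, strand),
        "8bII": _iv(chrom, 53_182_000, 53_182_080, strand),
        "8cII": _iv(chrom, 53_181_000, 53_181_070, strand),
        "10a": _iv(chrom, 53_143_000, 53_143_100, strand),
    }

    repeat = _iv(chrom, 53_253_400, 53_253_460, strand)
    return GeneModel(
        gene_region=region,
        internal_exons=internal,
        five_prime_exons=five_prime,
        repeat_tract=repeat,
    )


#: Event rows of the demo annotation: event label -> (donor exon name,
#: acceptor internal exon name, isoform group).  The intron of a
#: minus-strand junction runs from the acceptor exon's genomic end to the
#: donor exon's genomic start.
_DEMO_EVENTS: tuple[tuple[str, str, str, str], ...] = (
    ("3b-3", "3b", "3", "TCF4-B"),
    ("3c-3", "3c", "3", "TCF4-B"),
    ("3d-3", "3d", "3", "TCF4-B"),
    ("3b-4", "3b", "4", "TCF4-C"),
    ("3d-4", "3d", "4", "TCF4-C"),
    ("4aI-4", "4aI", "4", "TCF4-E"),
    ("4aIII-4", "4aIII", "4", "other"),
    ("6-7", "6", "7", "none"),
    ("7-8", "7", "8", "none"),
    ("8-9", "8", "9", "none"),
    ("8a-8", "8a", "8", "TCF4-D"),
    ("8bII-8", "8bII", "8", "TCF4-D"),
    ("8cII-8", "8cII", "8", "TCF4-D"),
    ("10a-10", "10a", "10", "TCF4-A"),
    ("10-16", "10", "16", "none"),
)

#: Extended-exon events quantified from 2-bp window coverage rather than
#: junction reads, with their isoform group.  "4c" is transcription reading
#: directly into internal exon 4.
DEMO_WINDOW_EVENTS: dict[str, str] = {"4c": "other"}


def build_demo_annotation(gene: Optional[GeneModel] = None) -> Annotation:
    """Junction annotation matching :func:`build_demo_gene`."""
    if gene is None:
        gene = build_demo_gene()
    exons = gene.all_exons()
    rows = []
    for event, donor_name, acceptor_name, isoform in _DEMO_EVENTS:
        donor = exons[donor_name]
        acceptor = exons[acceptor_name]
        # minus strand: donor exon lies at larger genomic coordinates
        junction = SpliceJunction(
            gene.gene_region.chrom,
            acceptor.end,
            donor.start,
            gene.strand,
            motif="CT/AC",
        )
        rows.append(AnnotationRow(junction, event, isoform))
    return Annotation(rows)
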