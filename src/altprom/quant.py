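"""Junction filtering, per-million normalization, window counting, aggregation.

The quantification follows a junction-centric recipe: drop mitochondrial and
non-canonical-motif junctions and those with fewer than 6 supporting reads
across the whole dataset, apply a milder >= 4-read dataset-wide floor inside
the gene of interest, normalize each junction's count by the sample's total
spliced-read count times 1e6 ("junctions per million", JPM), and sum
normalized values by event or by protein-isoform group.

Extended 5' exons (transcription reading straight into an internal exon)
leave no diagnostic junction; they are quantified by counting reads whose
aligned blocks fully cover a 2-bp window immediately transcript-upstream of
the internal exon.  A spliced read whose intron gap spans the window is
evidence of splicing, not of exon extension, and is not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genemodel import Annotation, GeneModel, GenomicInterval

__all__ = [
    "FilterConfig",
    "WindowSpec",
    "filter_dataset",
    "filter_gene",
    "normalize_jpm",
    "extended_exon_window",
    "count_window",
    "read_blocks_tsv",
    "aggregate",
]


@dataclass(frozen=True)
class FilterConfig:
    """Junction filtering thresholds.

    ``min_dataset_reads_genomewide`` is the dataset-wide support floor
    applied genome-wide (keep when sum >= threshold); ``min_dataset_reads_gene``
    the floor applied only inside the gene region.  ``exclude_chroms`` are
    dropped outright (mitochondrial contigs by default) and, with
    ``canonical_only``, so are junctions with non-canonical intron motifs.
    """

    min_dataset_reads_genomewide: int = 6
    min_dataset_reads_gene: int = 4
    exclude_chroms: frozenset[str] = frozenset({"chrM", "MT"})
    canonical_only: bool = True

    def __post_init__(self) -> None:
        if self.min_dataset_reads_genomewide < 0 or self.min_dataset_reads_gene < 0:
            raise ValueError("filter thresholds must be >= 0")


def filter_dataset(matrix, cfg: FilterConfig = FilterConfig()):
    """Genome-wide dataset-level filter.

    Removes junctions on excluded chromosomes, junctions with a
    non-canonical motif (when ``canonical_only``), and junctions whose
    dataset-wide read sum is below ``min_dataset_reads_genomewide``.
    Threshold ties are kept (>= semantics).  The sample set is unchanged.
    """
    keep = ~matrix.junctions["chrom"].isin(cfg.exclude_chroms)
    if cfg.canonical_only:
        keep &= matrix.junctions["motif"] != "non-canonical"
    keep &= matrix.row_sums() >= cfg.min_dataset_reads_genomewide
    return matrix.subset(matrix.counts.index[keep])


def filter_gene(matrix, gene_region: GenomicInterval, min_reads: int = 4):
    """Within-gene dataset-level floor.

    Among junctions overlapping ``gene_region``, removes those whose
    dataset-wide sum is below ``min_reads``; junctions outside the region
    are untouched.
    """
    meta = matrix.junctions
    in_gene = (
        (meta["chrom"] == gene_region.chrom)
        & (meta["start"] < gene_region.end)
        & (meta["end"] > gene_region.start)
    )
    keep = ~in_gene | (matrix.row_sums() >= min_reads)
    return matrix.subset(matrix.counts.index[keep])


def normalize_jpm(matrix, totals: Optional[pd.Series] = None) -> pd.DataFrame:
    """Junctions-per-million normalization.

    ``value(j, s) = count(j, s) / total(s) * 1e6`` where ``total(s)`` is the
    sample's spliced-read total.  By default the total is the column sum of
    ``matrix`` itself; pass ``totals`` to normalize a further-filtered matrix
    against denominators computed on a wider junction population.
    """
    if totals is None:
        totals = matrix.sample_totals()
    else:
        totals = totals.reindex(matrix.counts.columns)
        if totals.isna().any():
            missing = list(totals.index[totals.isna()])
            raise ValueError(f"missing totals for samples {missing}")
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero spliced-read total: {list(zero)}"
        )
    return matrix.counts / totals * 1e6


@dataclass(frozen=True)
class WindowSpec:
    """The 2-bp extended-exon counting window of one internal exon."""

    window: GenomicInterval
    exon_name: str

    def __post_init__(self) -> None:
        if self.window.length != 2:
            raise ValueError("extended-exon window must be exactly 2 bp wide")


def extended_exon_window(gene: GeneModel, internal_exon: str) -> WindowSpec:
    """The 2-bp window immediately transcript-5' of an internal exon.

    "5' of the exon" is resolved in transcript orientation: on a minus-strand
    gene the window is the two bases at genomically larger coordinates
    abutting the exon's genomic end; on a plus-strand gene the two bases
    before the exon's genomic start.
    """
    exon = gene.internal_exons[internal_exon]
    if gene.strand == "-":
        window = GenomicInterval(exon.chrom, exon.end, exon.end + 2, exon.strand)
    else:
        window = GenomicInterval(exon.chrom, exon.start - 2, exon.start, exon.strand)
    return WindowSpec(window, internal_exon)


def count_window(read_blocks: Iterable[Sequence], spec: WindowSpec) -> int:
    """Count reads crossing an extended-exon window.

    Each read is given as its aligned blocks (gaps between blocks are
    introns), either ``(start, end)`` pairs on the window's chromosome or
    ``(chrom, start, end)`` triples.  A read counts iff at least one block
    covers every position of the 2-bp window; a read whose intron gap spans
    the window does not.
    """
    w = spec.window
    n = 0
    for blocks in read_blocks:
        for block in blocks:
            if len(block) == 3:
                chrom, start, end = block
                if chrom != w.chrom:
                    continue
            else:
                start, end = block
            if start <= w.start and end >= w.end:
                n += 1
                break
    return n


def read_blocks_tsv(path) -> list[list[tuple[str, int, int]]]:
    """Read aligned blocks from a TSV ``read_id chrom block_start block_end``
    (0-based half-open, header line, one line per block), grouped by read."""
    reads: dict[str, list[tuple[str, int, int]]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            return []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}, line {lineno}: expected 4 columns, got {len(parts)}"
                )
            reads.setdefault(parts[0], []).append(
                (parts[1], int(parts[2]), int(parts[3]))
            )
    return list(reads.values())


def aggregate(
    matrix: pd.DataFrame,
    annotation: Annotation,
    by: str = "event",
    window_events: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Sum a junction-level expression matrix by event or isoform label.

    Rows of ``matrix`` are junction keys (matched exactly against the
    annotation) or extended-exon event labels listed in ``window_events``
    (event label -> isoform label), which join the aggregation as
    single-member events.  Unannotated junctions are dropped; for
    ``by="isoform"`` rows labelled ``"none"`` are excluded.  Output rows are
    in first-seen label order.
    """
    if by not in ("event", "isoform"):
        raise ValueError(f"by must be 'event' or 'isoform', got {by!r}")
    window_events = dict(window_events or {})

    labels: list[str] = []
    rows: list[str] = []
    for row_id in matrix.index:
        ann = annotation.get(row_id)
        if ann is not None:
            label = ann.event_label if by == "event" else ann.isoform_label
        elif row_id in window_events:
            label = row_id if by == "event" else window_events[row_id]
        else:
            continue
        if by == "isoform" and label == "none":
            continue
        rows.append(row_id)
        labels.append(label)

    if not rows:
        return pd.DataFrame(columns=matrix.columns, dtype=float)

    sub = matrix.loc[rows]
    order: list[str] = list(dict.fromkeys(labels))
    out = sub.groupby(pd.Index(labels, name=by), sort=False).sum()
    return out.loc[order]
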