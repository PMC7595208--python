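"""Per-sample splice-junction count I/O and dataset-level merging.

Supports the STAR ``SJ.out.tab`` 9-column dialect (plain or gzipped), a
generic per-sample junction TSV, and a sample-metadata TSV.  Per-sample
record lists are merged into a junctions x samples count matrix; only
uniquely mapped junction reads are counted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genemodel import MOTIF_CLASSES, SpliceJunction

__all__ = [
    "JunctionRecord",
    "JunctionCountMatrix",
    "read_star_sj",
    "write_star_sj",
    "read_junction_tsv",
    "read_sample_meta",
    "merge_samples",
]

_STRAND_FROM_CODE = {0: ".", 1: "+", 2: "-"}
_CODE_FROM_STRAND = {v: k for k, v in _STRAND_FROM_CODE.items()}


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction in one sample, with its read support."""

    junction: SpliceJunction
    unique_reads: int
    multimapping_reads: int = 0
    max_overhang: int = 0
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.unique_reads < 0 or self.multimapping_reads < 0:
            raise ValueError("read counts must be non-negative")


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_star_sj(path) -> list[JunctionRecord]:
    """Read a STAR ``SJ.out.tab`` file.

    Columns: chrom, intron start (1-based), intron end (1-based inclusive),
    strand code {0,1,2}, motif code {0..6}, annotated {0,1}, unique reads,
    multimapping reads, max overhang.  Coordinates are converted to 0-based
    half-open; motif and strand codes to their classes.
    """
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{path}, line {lineno}: expected 9 columns, got {len(parts)}"
                )
            try:
                chrom = parts[0]
                start1, end1 = int(parts[1]), int(parts[2])
                strand_code, motif_code = int(parts[3]), int(parts[4])
                annotated = bool(int(parts[5]))
                unique, multi, overhang = (
                    int(parts[6]),
                    int(parts[7]),
                    int(parts[8]),
                )
                junction = SpliceJunction(
                    chrom,
                    start1 - 1,
                    end1,
                    _STRAND_FROM_CODE[strand_code],
                    MOTIF_CLASSES[motif_code],
                )
                record = JunctionRecord(
                    junction, unique, multi, overhang, annotated
                )
            except (ValueError, KeyError, IndexError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
            records.append(record)
    return records


def write_star_sj(records: Sequence[JunctionRecord], path) -> None:
    """Write records in the 9-column STAR ``SJ.out.tab`` dialect."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        for r in records:
            j = r.junction
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        j.chrom,
                        j.start + 1,
                        j.end,
                        _CODE_FROM_STRAND[j.strand],
                        MOTIF_CLASSES.index(j.motif),
                        int(r.annotated),
                        r.unique_reads,
                        r.multimapping_reads,
                        r.max_overhang,
                    )
                )
                + "\n"
            )


def read_junction_tsv(path) -> list[JunctionRecord]:
    """Read the generic junction TSV: ``chrom start_1based end_1based strand
    motif count`` with a header line."""
    records = []
    with _open_text(path) as fh:
        header = fh.readline()
        if not header:
            return records
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}, line {lineno}: expected 6 columns, got {len(parts)}"
                )
            try:
                junction = SpliceJunction(
                    parts[0], int(parts[1]) - 1, int(parts[2]), parts[3], parts[4]
                )
                records.append(JunctionRecord(junction, int(parts[5])))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    return records


def read_sample_meta(path) -> pd.DataFrame:
    """Read the sample metadata TSV ``sample_id  experiment  disease``.

    Returns a frame indexed by sample_id with ``experiment`` and ``disease``
    columns (both strings).  Duplicate sample ids are rejected.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "experiment", "disease"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    return meta.set_index("sample_id")


@dataclass
class JunctionCountMatrix:
    """Junctions x samples unique-read counts plus per-junction metadata.

    ``junctions`` (index = junction key) carries chrom/start/end/strand/motif
    columns; ``counts`` shares the same index with one integer column per
    sample.
    """

    junctions: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.junctions.index.equals(self.counts.index):
            raise ValueError("junction metadata and counts indexes differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_junctions(self) -> int:
        return len(self.counts)

    def row_sums(self) -> pd.Series:
        """Dataset-wide read support per junction."""
        return self.counts.sum(axis=1)

    def sample_totals(self) -> pd.Series:
        """Total spliced reads per sample (over the current junction set)."""
        return self.counts.sum(axis=0)

    def subset(self, keys) -> "JunctionCountMatrix":
        return JunctionCountMatrix(
            self.junctions.loc[keys].copy(), self.counts.loc[keys].copy()
        )

    def junction_objects(self) -> list[SpliceJunction]:
        return [
            SpliceJunction(r.chrom, r.start, r.end, r.strand, r.motif)
            for r in self.junctions.itertuples()
        ]


def merge_samples(
    records,
    sample_ids: Sequence[str] | None = None,
) -> JunctionCountMatrix:
    """Merge per-sample junction record lists into one count matrix.

    ``records`` is either a mapping sample_id -> record list or a sequence of
    record lists accompanied by ``sample_ids``.  The junction set is the
    union over samples (first-seen order); a junction absent from a sample
    counts 0 there.  Only ``unique_reads`` are counted; multimappers are
    excluded.  Duplicate records of one junction within a sample are summed.
    """
    if isinstance(records, Mapping):
        items = list(records.items())
    else:
        if sample_ids is None:
            raise ValueError("sample_ids required when records is not a mapping")
        if len(sample_ids) != len(records):
            raise ValueError("one record list per sample id required")
        items = list(zip(sample_ids, records))

    ids = [sid for sid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids in {ids}")

    meta_rows: dict[str, SpliceJunction] = {}
    per_sample: list[dict[str, int]] = []
    for _, recs in items:
        col: dict[str, int] = {}
        for r in recs:
            key = r.junction.key
            meta_rows.setdefault(key, r.junction)
            col[key] = col.get(key, 0) + r.unique_reads
        per_sample.append(col)

    keys = list(meta_rows)
    counts = np.zeros((len(keys), len(ids)), dtype=np.int64)
    key_pos = {k: i for i, k in enumerate(keys)}
    for s, col in enumerate(per_sample):
        for k, v in col.items():
            counts[key_pos[k], s] = v

    junctions = pd.DataFrame(
        {
            "chrom": [j.chrom for j in meta_rows.values()],
            "start": [j.start for j in meta_rows.values()],
            "end": [j.end for j in meta_rows.values()],
            "strand": [j.strand for j in meta_rows.values()],
            "motif": [j.motif for j in meta_rows.values()],
        },
        index=pd.Index(keys, name="junction"),
    )
    count_df = pd.DataFrame(counts, index=junctions.index, columns=ids)
    return JunctionCountMatrix(junctions, count_df)
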