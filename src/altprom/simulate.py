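"""Synthetic study generator.

Emulates the two corneal-endothelium RNA-seq cohorts used to study
repeat-expansion effects on alternative promoter usage: two independent
experiments (6 control / 8 disease and 9 control / 6 disease samples),
negative-binomial junction counts over a TCF4-like multi-promoter gene
model, per-sample library-size variation, and a disease effect profile in
which events immediately downstream of the repeat go down, distal 5' exons
go up and some events stay flat.  Alongside the gene junctions each sample
carries background junctions that (a) provide the genome-wide spliced-read
denominator and (b) deliberately exercise every filtering branch
(mitochondrial, non-canonical motif, low support).

The generator also produces aligned-read blocks for extended-exon window
counting, dual-luciferase measurement tables and TSS position sets, so the
whole pipeline is testable without any external data.  Everything is
deterministic given the master seed: per-sample streams are derived by
stable hashing of (seed, sample id), independent of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genemodel import (
    Annotation,
    DEMO_WINDOW_EVENTS,
    GeneModel,
    SpliceJunction,
    build_demo_annotation,
    build_demo_gene,
    write_annotation,
)
from .junctions import JunctionRecord, write_star_sj
from .quant import WindowSpec, extended_exon_window

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedDataset",
    "default_fecd_profile",
    "DEFAULT_BASELINES",
    "simulate_dataset",
    "simulate_reporter",
    "simulate_tss",
]

#: Events reduced / increased / unchanged in disease, as reported for the
#: repeat-expanded cornea: events starting just downstream of the repeat
#: (4aI, 4aIII) and 5' exons spliced directly to internal exon 4 go down,
#: distal 5' exons and the downstream internal-exon chain go up.
DOWN_EVENTS = ("4aI-4", "4aIII-4", "3b-4", "3d-4", "6-7", "7-8")
UP_EVENTS = ("4c", "3b-3", "8a-8", "8bII-8", "8cII-8", "10a-10", "10-16")
FLAT_EVENTS = ("3c-3", "3d-3", "8-9")

#: Mean junction reads per event at a 1e6-spliced-read library.  Order of
#: magnitude placeholders for a moderately expressed locus; relative sizes
#: follow the usual pattern that internal-exon junctions (shared by all
#: transcripts) outnumber any single 5'-exon junction.
DEFAULT_BASELINES: dict[str, float] = {
    "4aI-4": 150.0,
    "4aIII-4": 60.0,
    "3b-4": 80.0,
    "3d-4": 50.0,
    "6-7": 300.0,
    "7-8": 280.0,
    "4c": 60.0,
    "3b-3": 200.0,
    "8a-8": 90.0,
    "8bII-8": 40.0,
    "8cII-8": 30.0,
    "10a-10": 70.0,
    "10-16": 400.0,
    "3c-3": 120.0,
    "3d-3": 60.0,
    "8-9": 250.0,
}


def default_fecd_profile(down: float = 0.3, up: float = 3.0) -> dict[str, float]:
    """Disease fold-change per event: < 1 down, > 1 up, = 1 flat."""
    profile: dict[str, float] = {}
    profile.update({e: down for e in DOWN_EVENTS})
    profile.update({e: up for e in UP_EVENTS})
    profile.update({e: 1.0 for e in FLAT_EVENTS})
    return profile


@dataclass
class SimConfig:
    """Study-design and noise parameters of the junction-count simulator."""

    seed: int = 0
    experiments: tuple[tuple[str, int, int], ...] = (
        ("2019", 6, 8),
        ("2020", 9, 6),
    )
    baseline_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    dispersion: float = 10.0
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    effect_profile: dict[str, float] = field(default_factory=default_fecd_profile)
    background_junctions: int = 50

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.baseline_mean.values()):
            raise ValueError("baseline means must be positive")
        if any(f <= 0 for f in self.effect_profile.values()):
            raise ValueError("fold-changes must be positive")
        for name, n_ctrl, n_case in self.experiments:
            if n_ctrl < 2 or n_case < 2:
                raise ValueError(f"experiment {name!r}: group sizes must be >= 2")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid library size range")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    fold: dict[str, float]
    direction: dict[str, str]
    library_size: dict[str, int]


@dataclass
class SimulatedDataset:
    """In-memory simulated study, optionally also written to disk."""

    records: dict[str, list[JunctionRecord]]
    window_counts: dict[str, dict[str, int]]
    window_blocks: dict[str, list[list[tuple[str, int, int]]]]
    window_specs: dict[str, WindowSpec]
    window_events: dict[str, str]
    meta: pd.DataFrame
    truth: SimTruth
    annotation: Annotation
    gene: GeneModel


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # order-independent per-sample stream: seed + CRC32 of the sample id
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(sample_id.encode("utf-8"))]
    )


def _nb_draw(rng: np.random.Generator, mean: float, size_param: float) -> int:
    if mean <= 0:
        return 0
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def _background_junctions(cfg: SimConfig, gene: GeneModel):
    """Deterministic background junction set with per-junction mean reads
    (at a 1e6 library).  Returns (junction, mean, kind) triples."""
    n = cfg.background_junctions
    n_canon = max(n * 2 // 5, 1)
    n_chrm = max(n // 5, 1)
    n_noncanon = max(n // 5, 1)
    n_low = max(n - n_canon - n_chrm - n_noncanon - 1, 1)

    rows: list[tuple[SpliceJunction, float, str]] = []
    for i in range(n_canon):
        j = SpliceJunction("chr2", 1_000 + i * 5_000, 1_500 + i * 5_000, "+", "GT/AG")
        rows.append((j, 2_000.0, "background"))
    for i in range(n_chrm):
        j = SpliceJunction("chrM", 100 + i * 300, 250 + i * 300, "+", "GT/AG")
        rows.append((j, 100.0, "chrM"))
    for i in range(n_noncanon):
        j = SpliceJunction(
            "chr18", 60_000_000 + i * 1_000, 60_000_400 + i * 1_000, "+",
            "non-canonical",
        )
        rows.append((j, 50.0, "non-canonical"))
    for i in range(n_low):
        j = SpliceJunction("chr3", 5_000 + i * 2_000, 5_800 + i * 2_000, "+", "GT/AG")
        rows.append((j, 0.05, "low-support"))
    # one unannotated in-gene junction with negligible support, to exercise
    # the within-gene floor when the genome-wide threshold is relaxed
    rows.append(
        (
            SpliceJunction("chr18", 53_100_000, 53_101_000, "-", "CT/AC"),
            0.05,
            "in-gene-low",
        )
    )
    return rows


def simulate_dataset(
    cfg: SimConfig, out_dir: Optional[str | Path] = None
) -> SimulatedDataset:
    """Generate per-sample junction records, window read blocks and metadata.

    Per sample: a target library size is drawn uniformly from
    ``library_size_range``; each annotated gene junction gets a
    negative-binomial count with mean ``baseline x fold(disease) x library
    factor`` (size parameter ``dispersion``); background junctions get NB
    counts around their own means; and a single filler junction tops the
    sample's written spliced-read total up to the target exactly.
    Extended-exon events get NB window-read counts realised as aligned
    blocks covering the 2-bp window, plus a few decoy reads that gap or only
    half-cover it.

    With ``out_dir`` the dataset is also written to disk: STAR-dialect SJ
    files under ``sj/``, block TSVs under ``blocks/``, ``meta.tsv``,
    ``annotation.tsv`` and ``truth.tsv``.
    """
    gene = build_demo_gene()
    annotation = build_demo_annotation(gene)
    window_events = dict(DEMO_WINDOW_EVENTS)
    junction_events = [
        (row.event_label, row.junction) for row in annotation
    ]
    window_specs = {"4c": extended_exon_window(gene, "4")}

    missing = [
        e for e, _ in junction_events if e not in cfg.baseline_mean
    ] + [e for e in window_events if e not in cfg.baseline_mean]
    if missing:
        raise ValueError(f"baseline_mean missing events: {sorted(set(missing))}")

    background = _background_junctions(cfg, gene)
    filler = SpliceJunction("chr1", 10_000, 12_000, "+", "GT/AG")

    meta_rows = []
    for exp_name, n_ctrl, n_case in cfg.experiments:
        for i in range(n_ctrl):
            meta_rows.append((f"{exp_name}_CTRL{i + 1:02d}", exp_name, "CTRL"))
        for i in range(n_case):
            meta_rows.append((f"{exp_name}_FECD{i + 1:02d}", exp_name, "FECD"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "experiment", "disease"]
    ).set_index("sample_id")

    lo, hi = cfg.library_size_range
    records: dict[str, list[JunctionRecord]] = {}
    window_counts: dict[str, dict[str, int]] = {e: {} for e in window_events}
    window_blocks: dict[str, list[list[tuple[str, int, int]]]] = {}
    library_size: dict[str, int] = {}

    for sample_id, row in meta.iterrows():
        rng = _sample_rng(cfg.seed, sample_id)
        target = int(rng.integers(lo, hi + 1))
        library_size[sample_id] = target
        lf = target / 1e6
        diseased = row["disease"] == "FECD"

        recs: list[JunctionRecord] = []
        total = 0
        for event, junction in junction_events:
            mean = cfg.baseline_mean[event] * lf
            if diseased:
                mean *= cfg.effect_profile.get(event, 1.0)
            count = _nb_draw(rng, mean, cfg.dispersion)
            total += count
            recs.append(
                JunctionRecord(junction, count, 0, 30, annotated=True)
            )
        for junction, mean, _kind in background:
            count = _nb_draw(rng, mean * lf, cfg.dispersion)
            total += count
            recs.append(
                JunctionRecord(junction, count, count // 10, 25)
            )
        fill = max(target - total, 0)
        recs.append(JunctionRecord(filler, fill, 0, 40))
        records[sample_id] = recs

        blocks: list[list[tuple[str, int, int]]] = []
        for event, iso in window_events.items():
            spec = window_specs[event]
            mean = cfg.baseline_mean[event] * lf
            if diseased:
                mean *= cfg.effect_profile.get(event, 1.0)
            count = _nb_draw(rng, mean, cfg.dispersion)
            window_counts[event][sample_id] = count
            w = spec.window
            for _ in range(count):
                blocks.append([(w.chrom, w.start - 50, w.end + 30)])
            # decoys: spliced reads gapping the window and half-coverers
            for _ in range(3):
                blocks.append(
                    [
                        (w.chrom, w.start - 80, w.start),
                        (w.chrom, w.end, w.end + 40),
                    ]
                )
            for _ in range(2):
                blocks.append([(w.chrom, w.start - 20, w.start + 1)])
        window_blocks[sample_id] = blocks

    truth = SimTruth(
        fold={
            e: cfg.effect_profile.get(e, 1.0)
            for e in list(dict.fromkeys(e for e, _ in junction_events))
            + list(window_events)
        },
        direction={},
        library_size=library_size,
    )
    truth.direction = {
        e: ("up" if f > 1 else "down" if f < 1 else "flat")
        for e, f in truth.fold.items()
    }

    dataset = SimulatedDataset(
        records=records,
        window_counts=window_counts,
        window_blocks=window_blocks,
        window_specs=window_specs,
        window_events=window_events,
        meta=meta,
        truth=truth,
        annotation=annotation,
        gene=gene,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(dataset: SimulatedDataset, out_dir: Path) -> None:
    sj_dir = out_dir / "sj"
    blocks_dir = out_dir / "blocks"
    sj_dir.mkdir(parents=True, exist_ok=True)
    blocks_dir.mkdir(parents=True, exist_ok=True)
    for sample_id, recs in dataset.records.items():
        write_star_sj(recs, sj_dir / f"{sample_id}.SJ.out.tab")
        with open(
            blocks_dir / f"{sample_id}.blocks.tsv", "wt", encoding="utf-8"
        ) as fh:
            fh.write("read_id\tchrom\tblock_start\tblock_end\n")
            for i, blocks in enumerate(dataset.window_blocks[sample_id]):
                for chrom, start, end in blocks:
                    fh.write(f"read{i:06d}\t{chrom}\t{start}\t{end}\n")
    dataset.meta.reset_index().to_csv(out_dir / "meta.tsv", sep="\t", index=False)
    write_annotation(dataset.annotation, out_dir / "annotation.tsv")
    truth = pd.DataFrame(
        {
            "event": list(dataset.truth.fold),
            "fold": list(dataset.truth.fold.values()),
            "direction": [dataset.truth.direction[e] for e in dataset.truth.fold],
        }
    )
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)


#: Relative promoter activity by repeat length (fraction of the 11-repeat
#: activity): expansion progressively silences the promoter, with the
#: longest construct reduced to the per-promoter ``effect_144`` level.
_DEFAULT_LENGTH_PROFILE = {11: 1.0, 25: 1.0, 31: 0.95, 54: 0.75, 70: 0.6}


def simulate_reporter(
    seed: int = 0,
    effect_144: Mapping[str, float] = None,
    noise_cv: float = 0.10,
    n_experiments: int = 3,
    repeat_lengths: Sequence[int] = (11, 25, 31, 54, 70, 144),
    length_profile: Optional[Mapping[int, float]] = None,
) -> pd.DataFrame:
    """Dual-luciferase measurements for the two promoter constructs.

    Per promoter, experiment and repeat length one firefly/Renilla pair is
    generated: the firefly/Renilla ratio is ``base ratio(experiment) x
    relative activity(length)`` under multiplicative log-normal noise with
    coefficient of variation ``noise_cv`` (Renilla noise cancels in the
    ratio, so ``noise_cv = 0`` recovers the configured activities exactly).
    ``effect_144`` sets the 144-repeat relative activity per promoter
    (default 0.30 for p4a, 0.25 for p4abc, i.e. 70%/75% reductions).
    """
    if effect_144 is None:
        effect_144 = {"p4a": 0.30, "p4abc": 0.25}
    if any(v <= 0 for v in effect_144.values()):
        raise ValueError("effects must be positive")
    profile = dict(_DEFAULT_LENGTH_PROFILE)
    if length_profile is not None:
        profile.update(length_profile)

    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    rows = []
    for promoter, eff in effect_144.items():
        rng = _sample_rng(seed, f"reporter:{promoter}")
        for experiment in range(1, n_experiments + 1):
            base_ratio = 2.0 * float(rng.lognormal(0.0, 0.3))
            renilla_base = 1_000.0 * float(rng.lognormal(0.0, 0.2))
            for length in repeat_lengths:
                activity = eff if length == 144 else profile.get(length, 1.0)
                noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
                renilla = renilla_base * float(rng.lognormal(0.0, 0.1))
                ratio = base_ratio * activity * noise
                rows.append(
                    {
                        "promoter": promoter,
                        "repeat_length": length,
                        "experiment": experiment,
                        "firefly": ratio * renilla,
                        "renilla": renilla,
                    }
                )
    return pd.DataFrame(rows)


def simulate_tss(
    n: int,
    center: int,
    spread: int,
    strand: str = "-",
    seed: int = 0,
    chrom: str = "chr18",
):
    """``n`` TSS positions uniform over ``[center - spread/2, center +
    spread/2]``, sorted, deterministic by seed."""
    from .tss import TssSet

    if n < 1:
        raise ValueError("need at least one TSS")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    rng = _sample_rng(seed, f"tss:{chrom}:{center}:{spread}:{n}")
    lo = center - spread // 2
    hi = center + (spread - spread // 2)
    positions = rng.integers(lo, hi + 1, size=n)
    return TssSet(chrom, positions.tolist(), strand)
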