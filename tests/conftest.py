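import numpy as np
import pandas as pd
import pytest

from altprom.genemodel import (
    Annotation,
    AnnotationRow,
    SpliceJunction,
    build_demo_annotation,
    build_demo_gene,
)
from altprom.junctions import JunctionCountMatrix


@pytest.fixture(scope="session")
def demo_gene():
    return build_demo_gene()


@pytest.fixture(scope="session")
def demo_annotation(demo_gene):
    return build_demo_annotation(demo_gene)


def make_matrix(rows, samples):
    """Build a JunctionCountMatrix from (chrom, start, end, strand, motif,
    counts) tuples."""
    junctions = [
        SpliceJunction(chrom, start, end, strand, motif)
        for chrom, start, end, strand, motif, _ in rows
    ]
    keys = [j.key for j in junctions]
    meta = pd.DataFrame(
        {
            "chrom": [j.chrom for j in junctions],
            "start": [j.start for j in junctions],
            "end": [j.end for j in junctions],
            "strand": [j.strand for j in junctions],
            "motif": [j.motif for j in junctions],
        },
        index=pd.Index(keys, name="junction"),
    )
    counts = pd.DataFrame(
        np.asarray([r[5] for r in rows], dtype=np.int64),
        index=meta.index,
        columns=samples,
    )
    return JunctionCountMatrix(meta, counts)


def random_small_matrix(rng, max_junctions=20, max_samples=6):
    """A random small count matrix mixing chromosomes, motifs and support
    levels so every filter branch can fire."""
    n_j = int(rng.integers(1, max_junctions + 1))
    n_s = int(rng.integers(1, max_samples + 1))
    samples = [f"s{i}" for i in range(n_s)]
    rows = []
    for i in range(n_j):
        chrom = rng.choice(["chr18", "chr2", "chrM"], p=[0.6, 0.3, 0.1])
        start = int(rng.integers(0, 60_000_000))
        motif = rng.choice(["CT/AC", "GT/AG", "non-canonical"], p=[0.5, 0.3, 0.2])
        counts = rng.integers(0, 12, size=n_s)
        rows.append(
            (str(chrom), start, start + 100 + i, "-", str(motif), counts)
        )
    return make_matrix(rows, samples)
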