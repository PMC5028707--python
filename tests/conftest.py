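"""Shared builders and independent brute-force oracles.

The oracles here deliberately avoid the package's interval algebra: overlap
is computed on explicit per-base sets, and transcript windows by walking the
transcript base-by-base in 5'->3' order. Tests compare the fast sweep
implementations against these.
"""

from __future__ import annotations

import numpy as np
import pytest

from sineup_scan.models import GenomicInterval, TranscriptModel


def tx(
    tid: str,
    strand: str,
    exons: list[tuple[int, int]],
    cds: tuple[int, int] | None = None,
    chrom: str = "chr1",
    source: str = "assembly",
) -> TranscriptModel:
    """Terse transcript builder for tests."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=f"g_{tid}",
        chrom=chrom,
        strand=strand,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds=cds,
        source_set=source,
    )


def exon_bases(t: TranscriptModel) -> set[int]:
    out: set[int] = set()
    for iv in t.exons:
        out.update(range(iv.start, iv.end))
    return out


def per_base_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Brute-force exonic overlap: size of the intersection of base sets."""
    if a.chrom != b.chrom:
        return 0
    return len(exon_bases(a) & exon_bases(b))


def base_walk(t: TranscriptModel) -> list[int]:
    """Genomic positions of every transcript base in 5'->3' order."""
    positions: list[int] = []
    if t.strand == "+":
        for iv in t.exons:
            positions.extend(range(iv.start, iv.end))
    else:
        for iv in reversed(t.exons):
            positions.extend(range(iv.end - 1, iv.start - 1, -1))
    return positions


def interval_bases(intervals) -> set[int]:
    out: set[int] = set()
    for iv in intervals:
        out.update(range(iv.start, iv.end))
    return out


def random_transcript(
    rng: np.random.Generator,
    tid: str,
    chrom: str = "chr1",
    region: tuple[int, int] = (0, 10_000),
    with_cds: bool = False,
    min_utr: int = 0,
) -> TranscriptModel:
    """A random 1-3 exon transcript, optionally with a CDS leaving >=min_utr
    nt of 5' UTR."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 4))
    pos = int(rng.integers(region[0], region[1] - 1200))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 201))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(20, 101))
    cds = None
    if with_cds:
        t_tmp = tx(tid, strand, exons, chrom=chrom)
        total = t_tmp.exonic_length
        utr = int(rng.integers(min_utr, total - 3))
        clen = int(rng.integers(3, total - utr + 1))
        walk = base_walk(t_tmp)
        cds_positions = walk[utr : utr + clen]
        cds = (min(cds_positions), max(cds_positions) + 1)
    return tx(tid, strand, exons, cds=cds, chrom=chrom)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
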