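"""Core genomic domain types.

All coordinates in this package follow a single convention: 0-based,
half-open ``[start, end)`` intervals, with strand ``"+"``, ``"-"`` or
``"."`` (unstranded). The 1-based closed conventions of GTF and
RepeatMasker ``.out`` files are converted at the I/O boundary and never
appear internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from sineup_scan.errors import ValidationError

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

#: Valid strand symbols.
Strand = {PLUS, MINUS, UNSTRANDED}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome / sequence name.
    start : int
        0-based inclusive start.
    end : int
        Exclusive end; must satisfy ``start < end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."``.
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in Strand:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """Distance in nt from ``pos`` to this interval; 0 if inside."""
        return max(self.start - pos, pos - (self.end - 1), 0)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended (start, end) tuples into a sorted chain."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class TranscriptModel:
    """An exon-structured, stranded transcript with optional CDS.

    The unit of both reference mRNAs and assembled antisense transcripts.
    Exons are stored sorted by genomic start and must be non-overlapping;
    ``cds`` is the genomic span (start, end) of the coding region, which
    must lie within the exon chain.

    Transcript coordinates run 5'->3' in transcript orientation: position 0
    is the first transcribed base (the leftmost genomic exonic base on the
    plus strand, the rightmost on the minus strand).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: tuple[int, int] | None = None
    source_set: str = "assembly"

    def __post_init__(self):
        if self.strand not in (PLUS, MINUS):
            raise ValidationError(
                f"{self.transcript_id}: transcript strand must be + or -, got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons {a} and {b}"
                )
        for iv in exons:
            if iv.chrom != self.chrom:
                raise ValidationError(
                    f"{self.transcript_id}: exon chrom {iv.chrom} != {self.chrom}"
                )
        self.exons = [replace(iv, strand=self.strand) for iv in exons]
        if self.cds is not None:
            cs, ce = self.cds
            if not (cs < ce):
                raise ValidationError(f"{self.transcript_id}: empty CDS span")
            if cs < self.span_start or ce > self.span_end:
                raise ValidationError(
                    f"{self.transcript_id}: CDS [{cs}, {ce}) outside exon span"
                )
            # both CDS endpoints must fall in exonic sequence
            if not self._is_exonic(cs) or not self._is_exonic(ce - 1):
                raise ValidationError(
                    f"{self.transcript_id}: CDS [{cs}, {ce}) not contained in exons"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def span_start(self) -> int:
        return self.exons[0].start

    @property
    def span_end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.span_start, self.span_end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(len(iv) for iv in self.exons)

    @property
    def five_prime_pos(self) -> int:
        """Genomic coordinate of the first transcribed base (the TSS)."""
        return self.span_start if self.strand == PLUS else self.span_end - 1

    @property
    def three_prime_pos(self) -> int:
        return self.span_end - 1 if self.strand == PLUS else self.span_start

    def _is_exonic(self, gpos: int) -> bool:
        return any(iv.start <= gpos < iv.end for iv in self.exons)

    # -- transcript-coordinate machinery --------------------------------

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map an exonic genomic position to its transcript coordinate.

        Raises ValueError for intronic or out-of-span positions.
        """
        offset = 0
        exons = self.exons if self.strand == PLUS else reversed(self.exons)
        for iv in exons:
            if iv.start <= gpos < iv.end:
                within = gpos - iv.start if self.strand == PLUS else iv.end - 1 - gpos
                return offset + within
            offset += len(iv)
        raise ValueError(
            f"{self.transcript_id}: position {gpos} is not exonic"
        )

    def transcript_to_genomic(self, tpos: int) -> int:
        """Map a transcript coordinate to its genomic position."""
        if not (0 <= tpos < self.exonic_length):
            raise ValueError(
                f"{self.transcript_id}: transcript position {tpos} out of range"
            )
        offset = tpos
        exons = self.exons if self.strand == PLUS else reversed(self.exons)
        for iv in exons:
            if offset < len(iv):
                return iv.start + offset if self.strand == PLUS else iv.end - 1 - offset
            offset -= len(iv)
        raise AssertionError("unreachable")

    def project(self, tstart: int, tend: int) -> list[GenomicInterval]:
        """Project a transcript-coordinate window [tstart, tend) to genomic intervals.

        Returns intervals sorted by genomic start; a window spanning an exon
        junction yields one interval per exon touched.
        """
        if tstart >= tend:
            return []
        if tstart < 0 or tend > self.exonic_length:
            raise ValueError(
                f"{self.transcript_id}: window [{tstart}, {tend}) outside transcript"
            )
        pieces: list[tuple[int, int]] = []
        offset = 0
        exons = list(self.exons) if self.strand == PLUS else list(reversed(self.exons))
        for iv in exons:
            lo = max(tstart, offset)
            hi = min(tend, offset + len(iv))
            if lo < hi:
                if self.strand == PLUS:
                    pieces.append((iv.start + (lo - offset), iv.start + (hi - offset)))
                else:
                    pieces.append((iv.end - (hi - offset), iv.end - (lo - offset)))
            offset += len(iv)
        pieces.sort()
        return [GenomicInterval(self.chrom, s, e, self.strand) for s, e in pieces]

    # -- CDS / UTR ------------------------------------------------------

    @property
    def has_cds(self) -> bool:
        return self.cds is not None

    @property
    def start_codon_pos(self) -> int:
        """Genomic position of the first base of the start codon (the A of AUG)."""
        if self.cds is None:
            raise ValueError(f"{self.transcript_id}: no CDS")
        return self.cds[0] if self.strand == PLUS else self.cds[1] - 1

    @property
    def cds_start_tpos(self) -> int:
        """Transcript coordinate of the first CDS base."""
        return self.genomic_to_transcript(self.start_codon_pos)

    @property
    def utr5_length(self) -> int:
        """Exonic length of the 5' UTR (0 when the CDS begins at the 5' end)."""
        return self.cds_start_tpos

    @property
    def cds_exonic_length(self) -> int:
        if self.cds is None:
            raise ValueError(f"{self.transcript_id}: no CDS")
        cs, ce = self.cds
        return sum(max(0, min(iv.end, ce) - max(iv.start, cs)) for iv in self.exons)

    def utr5_intervals(self) -> list[GenomicInterval]:
        """Genomic projection of the 5' UTR exonic sequence."""
        return self.project(0, self.utr5_length)


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker annotation: a named, classified, stranded repeat copy."""

    chrom: str
    interval: GenomicInterval
    strand: str
    repeat_name: str
    repeat_class: str
    repeat_family: str = ""

    def __post_init__(self):
        if not self.repeat_class:
            raise ValidationError(f"repeat {self.repeat_name!r} has empty class")


@dataclass(frozen=True)
class CageCluster:
    """A CAGE tag cluster marking a transcription start site, scored in tags per million."""

    chrom: str
    interval: GenomicInterval
    strand: str
    tpm: float
    name: str = "."

    def __post_init__(self):
        if self.tpm < 0:
            raise ValidationError(f"CAGE cluster with negative tpm {self.tpm}")


def group_by_chrom(features: Sequence, key=lambda f: f.chrom) -> dict[str, list]:
    """Bucket features by chromosome (helper for sweep-style intersections)."""
    out: dict[str, list] = {}
    for f in features:
        out.setdefault(key(f), []).append(f)
    return out
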