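"""Strand-aware interval algebra over transcript models.

Implements the geometric primitives of the screen: exonic overlap between
two transcripts, sense/antisense pair configuration (divergent / convergent /
full-length / internal), the TIS-proximal window (the last nucleotides of
5' UTR immediately upstream of the start codon) and the binding-domain
window (-up/+down around the AUG).
"""

from __future__ import annotations

from dataclasses import dataclass

from sineup_scan.errors import ContractError, NoTisError
from sineup_scan.models import GenomicInterval, TranscriptModel

DIVERGENT = "divergent"
CONVERGENT = "convergent"
FULL_LENGTH = "full-length"
INTERNAL = "internal"

#: TIS-window modes: "adjacent" takes the window immediately upstream of the
#: start codon in transcript coordinates (projected across junctions);
#: "per_exon_end" takes the last k nt of every 5'-UTR exon.
TIS_WINDOW_MODES = ("adjacent", "per_exon_end")


@dataclass(frozen=True)
class OverlapConfiguration:
    """How a sense/antisense pair overlaps.

    category : one of divergent (head-to-head, both 5' ends in the overlap),
        convergent (tail-to-tail), full-length (one span contains the other),
        internal (anything else).
    overlap_bp : total exonic overlap in nt (strand-agnostic).
    covers_tis : whether the antisense exons cover the first base of the
        sense start codon.
    """

    category: str
    overlap_bp: int
    covers_tis: bool


@dataclass(frozen=True)
class TisWindow:
    """Genomic projection of the TIS-proximal 5'-UTR window of a transcript."""

    transcript_id: str
    intervals: tuple[GenomicInterval, ...]
    width: int


def intersect_chains(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersect two sorted, non-overlapping interval chains (linear sweep)."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def exonic_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total overlap in nt between the exon chains of two transcripts.

    Strand-agnostic; intron-only overlap counts 0; different chromosomes
    return 0 rather than raising.
    """
    if a.chrom != b.chrom:
        return 0
    pieces = intersect_chains(
        [(iv.start, iv.end) for iv in a.exons],
        [(iv.start, iv.end) for iv in b.exons],
    )
    return sum(e - s for s, e in pieces)


def exonic_overlap_with_intervals(
    t: TranscriptModel, intervals: list[GenomicInterval]
) -> int:
    """Overlap in nt between a transcript's exons and a set of genomic intervals."""
    same = [(iv.start, iv.end) for iv in intervals if iv.chrom == t.chrom]
    if not same:
        return 0
    from sineup_scan.models import merge_intervals

    pieces = intersect_chains(
        [(iv.start, iv.end) for iv in t.exons], merge_intervals(same)
    )
    return sum(e - s for s, e in pieces)


def _covers_point(t: TranscriptModel, chrom: str, gpos: int) -> bool:
    return t.chrom == chrom and any(iv.start <= gpos < iv.end for iv in t.exons)


def classify_pair(
    sense: TranscriptModel, antisense: TranscriptModel, span_mode: bool = False
) -> OverlapConfiguration:
    """Classify the overlap configuration of an opposite-strand pair.

    Containment of either genomic span in the other is full-length (identical
    spans included). Otherwise the pair is divergent when both 5' ends fall
    inside the span overlap (head-to-head), convergent when both 3' ends do
    (tail-to-tail), internal otherwise. ``covers_tis`` tests whether the
    antisense exons contain the first base of the sense start codon.

    With ``span_mode`` the reported overlap_bp is the span intersection
    rather than the exon-chain intersection.
    """
    if sense.strand == antisense.strand:
        raise ContractError(
            f"classify_pair requires opposite strands "
            f"({sense.transcript_id} and {antisense.transcript_id} are both {sense.strand})"
        )
    if span_mode:
        ov = max(
            0,
            min(sense.span_end, antisense.span_end)
            - max(sense.span_start, antisense.span_start),
        ) if sense.chrom == antisense.chrom else 0
    else:
        ov = exonic_overlap_bp(sense, antisense)
    if ov < 1:
        raise ContractError(
            f"classify_pair requires overlapping transcripts "
            f"({sense.transcript_id} / {antisense.transcript_id} do not overlap)"
        )

    covers_tis = sense.has_cds and _covers_point(
        antisense, sense.chrom, sense.start_codon_pos
    )

    s_lo, s_hi = sense.span_start, sense.span_end
    a_lo, a_hi = antisense.span_start, antisense.span_end
    if (s_lo <= a_lo and a_hi <= s_hi) or (a_lo <= s_lo and s_hi <= a_hi):
        return OverlapConfiguration(FULL_LENGTH, ov, covers_tis)

    olo, ohi = max(s_lo, a_lo), min(s_hi, a_hi)

    def inside(pos: int) -> bool:
        return olo <= pos < ohi

    both_5p = inside(sense.five_prime_pos) and inside(antisense.five_prime_pos)
    both_3p = inside(sense.three_prime_pos) and inside(antisense.three_prime_pos)
    if both_5p:
        return OverlapConfiguration(DIVERGENT, ov, covers_tis)
    if both_3p:
        return OverlapConfiguration(CONVERGENT, ov, covers_tis)
    return OverlapConfiguration(INTERNAL, ov, covers_tis)


def tis_window(t: TranscriptModel, k: int = 5, mode: str = "adjacent") -> TisWindow:
    """The TIS-proximal window of a coding transcript, projected to the genome.

    In the default "adjacent" mode this is the ``min(k, 5'-UTR length)``
    transcript-orientation nucleotides immediately upstream of the start
    codon, which may split across an exon junction. The "per_exon_end" mode
    instead takes the last ``k`` nt of every 5'-UTR exon.

    Raises NoTisError when the transcript has no CDS; a zero-length UTR
    yields an empty window of width 0.
    """
    if mode not in TIS_WINDOW_MODES:
        raise ValueError(f"unknown tis_window mode {mode!r}")
    if not t.has_cds:
        raise NoTisError(f"{t.transcript_id}: no CDS, cannot derive a TIS window")
    utr = t.utr5_length
    if mode == "adjacent":
        w = min(k, utr)
        ivs = t.project(utr - w, utr)
        return TisWindow(t.transcript_id, tuple(ivs), w)
    # per_exon_end: last k nt (transcript orientation) of each UTR exon
    pieces: list[GenomicInterval] = []
    offset = 0
    exons = list(t.exons) if t.strand == "+" else list(reversed(t.exons))
    for iv in exons:
        lo = offset
        hi = min(offset + len(iv), utr)
        if lo < hi:  # this exon contributes UTR sequence [lo, hi)
            pieces.extend(t.project(max(lo, hi - k), hi))
        offset += len(iv)
        if offset >= utr:
            break
    pieces.sort(key=lambda iv: iv.start)
    return TisWindow(t.transcript_id, tuple(pieces), sum(len(p) for p in pieces))


def bd_window(
    t: TranscriptModel, up: int = 35, down: int = 4
) -> tuple[list[GenomicInterval], bool]:
    """Genomic projection of the binding-domain target window around the AUG.

    The window covers ``up`` UTR nucleotides plus the first ``down`` CDS
    nucleotides in transcript orientation (+1 is the A of AUG; there is no
    position 0, so -35/+4 spans 39 nt). Returns (intervals, truncated):
    when the UTR is shorter than ``up`` the window is truncated at the
    transcript 5' end and the flag is set.
    """
    if not t.has_cds:
        raise NoTisError(f"{t.transcript_id}: no CDS, cannot derive a BD window")
    cds_t = t.cds_start_tpos
    if t.cds_exonic_length < down:
        raise ContractError(
            f"{t.transcript_id}: CDS shorter than down={down}"
        )
    truncated = cds_t < up
    lo = max(0, cds_t - up)
    return t.project(lo, cds_t + down), truncated
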