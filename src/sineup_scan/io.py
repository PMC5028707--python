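"""Readers and writers for the annotation formats the screen touches.

Every parser converts to the internal 0-based half-open convention at the
boundary: GTF and RepeatMasker ``.out`` are 1-based closed on disk (with
``C`` meaning minus strand in RepeatMasker), BED is already 0-based
half-open. Emitted BED is 0-based half-open; genomic columns in emitted
TSV tables are 1-based closed and labelled as such.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from sineup_scan.errors import ParseError, ValidationError
from sineup_scan.models import (
    CageCluster,
    GenomicInterval,
    RepeatFeature,
    TranscriptModel,
    merge_intervals,
)

# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path, source_set: str = "assembly") -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    Accepts both the Ensembl/Cufflinks ``key "value";`` attribute dialect and
    ``key=value``. Exon features are required per transcript; a CDS feature is
    optional and its genomic span must be contained in the exon chain.
    Transcripts are grouped by transcript_id, not by line adjacency;
    gene_id is synthesized from transcript_id when absent.
    """
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (chrom, strand, gene_id)
    order: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}",
                    str(path),
                    line_no,
                )
            ftype = fields[2]
            if ftype not in ("exon", "CDS"):
                continue
            try:
                feat = feature_from_line(line)
                tid = feat.attributes["transcript_id"][0]
            except Exception as exc:
                raise ParseError(f"malformed GTF line ({exc})", str(path), line_no)
            gid = (feat.attributes.get("gene_id") or [tid])[0]
            start0, end = feat.start - 1, feat.end  # 1-based closed -> half-open
            if start0 < 0 or start0 >= end:
                raise ParseError(
                    f"invalid coordinates {feat.start}-{feat.end}", str(path), line_no
                )
            if feat.strand not in ("+", "-"):
                raise ParseError(f"invalid strand {feat.strand!r}", str(path), line_no)
            if tid not in meta:
                meta[tid] = (feat.seqid, feat.strand, gid)
                order.append(tid)
            elif meta[tid][0] != feat.seqid or meta[tid][1] != feat.strand:
                raise ParseError(
                    f"transcript {tid} spans multiple chromosomes or strands",
                    str(path),
                    line_no,
                )
            (exons if ftype == "exon" else cds).setdefault(tid, []).append(
                (start0, end)
            )

    out: list[TranscriptModel] = []
    for tid in order:
        chrom, strand, gid = meta[tid]
        if tid not in exons:
            # records with no exon feature are rejected
            continue
        exon_ivs = [
            GenomicInterval(chrom, s, e, strand)
            for s, e in merge_intervals(exons[tid])
        ]
        cds_span = None
        if tid in cds:
            cds_span = (min(s for s, _ in cds[tid]), max(e for _, e in cds[tid]))
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=exon_ivs,
                cds=cds_span,
                source_set=source_set,
            )
        )
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (1-based closed) with exon and CDS lines."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for iv in t.exons:
                fh.write(
                    f"{t.chrom}\tsineup_scan\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
            if t.cds is not None:
                cs, ce = t.cds
                for iv in t.exons:
                    lo, hi = max(iv.start, cs), min(iv.end, ce)
                    if lo < hi:
                        fh.write(
                            f"{t.chrom}\tsineup_scan\tCDS\t{lo + 1}\t{hi}\t.\t"
                            f"{t.strand}\t.\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_STRANDS = {"+": "+", "C": "-"}


def read_repeatmasker_out(path: str | Path) -> list[RepeatFeature]:
    """Parse a RepeatMasker ``.out`` annotation file.

    The dialect: header lines, then whitespace-delimited data lines with
    1-based inclusive begin/end, strand ``+`` or ``C`` (complement), and a
    ``class/family`` column (family may be absent, e.g. ``Simple_repeat``).
    Lines flagged with a trailing asterisk (lower-scoring overlap) are kept.
    """
    path = Path(path)
    out: list[RepeatFeature] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            first = line.split(None, 1)[0]
            # header lines start with "SW"/"score"/"bit" rather than a score
            if not first.isdigit():
                if line_no <= 3 or first in ("SW", "score", "bit"):
                    continue
                raise ParseError(
                    f"unparseable line (leading token {first!r})", str(path), line_no
                )
            cols = line.split()
            if len(cols) < 15:
                raise ParseError(
                    f"expected >=15 whitespace-delimited columns, got {len(cols)}",
                    str(path),
                    line_no,
                )
            chrom, begin, end, strand_sym = cols[4], cols[5], cols[6], cols[8]
            name, classfam = cols[9], cols[10]
            if strand_sym not in _RM_STRANDS:
                raise ParseError(
                    f"unknown strand symbol {strand_sym!r}", str(path), line_no
                )
            try:
                start0, end1 = int(begin) - 1, int(end)
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {begin!r}/{end!r}", str(path), line_no
                )
            rclass, _, rfamily = classfam.partition("/")
            strand = _RM_STRANDS[strand_sym]
            out.append(
                RepeatFeature(
                    chrom=chrom,
                    interval=GenomicInterval(chrom, start0, end1, strand),
                    strand=strand,
                    repeat_name=name,
                    repeat_class=rclass,
                    repeat_family=rfamily,
                )
            )
    return out


_RM_HEADER = (
    "   SW  perc perc perc  query     position in query    matching "
    "repeat      position in repeat\n"
    "score  div. del. ins.  sequence  begin end (left)  strand repeat "
    "class/family  begin end (left) ID\n"
    "\n"
)


def write_repeatmasker_out(repeats: Sequence[RepeatFeature], path: str | Path) -> None:
    """Write repeats in the RepeatMasker ``.out`` dialect (for simulation output)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, r in enumerate(repeats, start=1):
            classfam = (
                f"{r.repeat_class}/{r.repeat_family}"
                if r.repeat_family
                else r.repeat_class
            )
            strand = "+" if r.strand == "+" else "C"
            length = len(r.interval)
            fh.write(
                f"  500  10.0  0.0  0.0  {r.chrom}  {r.interval.start + 1}  "
                f"{r.interval.end}  (0)  {strand}  {r.repeat_name}  {classfam}  "
                f"1  {length}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_cage_bed(path: str | Path) -> list[CageCluster]:
    """Parse CAGE clusters from BED6; the score column is tags-per-million."""
    path = Path(path)
    out: list[CageCluster] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 6:
                raise ParseError(
                    f"BED6 requires >=6 columns, got {len(cols)}", str(path), line_no
                )
            chrom, start, end, name, score, strand = cols[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
                tpm = float(score)
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"bad BED record ({exc})", str(path), line_no)
            out.append(
                CageCluster(chrom=chrom, interval=iv, strand=strand, tpm=tpm, name=name)
            )
    return out


def write_cage_bed(clusters: Sequence[CageCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.interval.start}\t{c.interval.end}\t{c.name}\t"
                f"{c.tpm:g}\t{c.strand}\n"
            )


# ---------------------------------------------------------------------------
# Candidate table / funnel report

#: Column order of the candidate TSV. Genomic coordinates in this table are
#: 1-based closed (suffix ``_1based``); the companion BED stays 0-based.
CANDIDATE_COLUMNS = [
    "antisense_id",
    "sense_id",
    "chrom",
    "antisense_start_1based",
    "antisense_end_1based",
    "antisense_strand",
    "sense_start_1based",
    "sense_end_1based",
    "sense_strand",
    "category",
    "overlap_bp",
    "covers_tis",
    "n_repeats",
    "repeat_names",
    "repeat_classes",
    "tis_overlap_bp",
    "cage_supported",
    "cage_best_tpm",
    "cage_distance",
]


def candidates_to_frame(candidates: Iterable) -> pd.DataFrame:
    """Flatten CandidateSineup objects into the documented TSV layout."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "antisense_id": c.antisense_id,
                "sense_id": c.sense_id,
                "chrom": c.antisense.chrom,
                "antisense_start_1based": c.antisense.span_start + 1,
                "antisense_end_1based": c.antisense.span_end,
                "antisense_strand": c.antisense.strand,
                "sense_start_1based": c.sense.span_start + 1,
                "sense_end_1based": c.sense.span_end,
                "sense_strand": c.sense.strand,
                "category": c.configuration.category,
                "overlap_bp": c.configuration.overlap_bp,
                "covers_tis": c.configuration.covers_tis,
                "n_repeats": len(c.embedded_repeats),
                "repeat_names": ",".join(r.repeat_name for r in c.embedded_repeats),
                "repeat_classes": ",".join(
                    sorted({r.repeat_class for r in c.embedded_repeats})
                ),
                "tis_overlap_bp": c.tis_overlap_bp,
                "cage_supported": c.cage_supported,
                "cage_best_tpm": float("nan") if c.cage_best_tpm is None else float(c.cage_best_tpm),
                "cage_distance": float("nan") if c.cage_distance is None else float(c.cage_distance),
            }
        )
    frame = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    frame["cage_best_tpm"] = frame["cage_best_tpm"].astype(float)
    frame["cage_distance"] = frame["cage_distance"].astype(float)
    return frame


def write_candidates(
    candidates: Sequence, tsv_path: str | Path, bed_path: str | Path | None = None
) -> None:
    """Write the candidate table (TSV, 1-based closed coordinates) and,
    optionally, a BED6 of antisense spans scored by tis_overlap_bp."""
    frame = candidates_to_frame(candidates)
    frame.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in candidates:
                fh.write(
                    f"{c.antisense.chrom}\t{c.antisense.span_start}\t"
                    f"{c.antisense.span_end}\t{c.antisense_id}|{c.sense_id}\t"
                    f"{c.tis_overlap_bp}\t{c.antisense.strand}\n"
                )


def read_candidates(tsv_path: str | Path) -> pd.DataFrame:
    """Read a candidate TSV back into the flat frame written by write_candidates."""
    frame = pd.read_csv(
        tsv_path,
        sep="\t",
        dtype={"repeat_names": "string", "repeat_classes": "string"},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in CANDIDATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"candidate table missing columns {missing}", str(tsv_path))
    for col in ("repeat_names", "repeat_classes"):
        frame[col] = frame[col].fillna("").astype(object)
    return frame


def write_funnel(report, path: str | Path) -> None:
    """Serialize a funnel report as deterministic JSON."""
    payload = {
        "n_assembly": report.n_assembly,
        "n_antisense": report.n_antisense,
        "n_sine": report.n_sine,
        "n_tis": report.n_tis,
        "n_cage": report.n_cage,
    }
    if report.per_stage_ids is not None:
        payload["per_stage_ids"] = {
            stage: sorted(ids) for stage, ids in report.per_stage_ids.items()
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as an id -> uppercase sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
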