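"""The candidate-SINEUP filter cascade.

Stages, in order:

1. antisense pairing — assembled transcripts whose exon chains overlap a
   reference transcript on the opposite strand (the Cufflinks class-code-"x"
   relation);
2. SINE containment — the antisense exons overlap at least one repeat of an
   allowed class (default SINE), anywhere in the transcript;
3. TIS-window overlap — the antisense exons overlap the last nucleotides of
   the sense 5' UTR immediately upstream of the start codon (default 5 nt);
4. CAGE support — a CAGE cluster lies within a half-width (default 200 nt)
   of the antisense 5' end; an annotation by default, a filter on request.

The funnel counts distinct antisense transcripts at each stage; the
candidate table keeps one row per (antisense, sense) pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from sineup_scan import io as sio
from sineup_scan.errors import ConfigError, SineupError
from sineup_scan.intervals import (
    OverlapConfiguration,
    classify_pair,
    exonic_overlap_bp,
    exonic_overlap_with_intervals,
    tis_window,
)
from sineup_scan.models import (
    CageCluster,
    RepeatFeature,
    TranscriptModel,
    group_by_chrom,
)

logger = logging.getLogger(__name__)


@dataclass
class CandidateSineup:
    """A sense/antisense pair surviving (part of) the cascade."""

    antisense: TranscriptModel
    sense: TranscriptModel
    configuration: OverlapConfiguration
    embedded_repeats: list[RepeatFeature] = field(default_factory=list)
    tis_overlap_bp: int = 0
    cage_supported: bool = False
    cage_best_tpm: float | None = None
    cage_distance: int | None = None

    @property
    def antisense_id(self) -> str:
        return self.antisense.transcript_id

    @property
    def sense_id(self) -> str:
        return self.sense.transcript_id


@dataclass
class FunnelReport:
    """Distinct-antisense survivor counts per cascade stage."""

    n_assembly: int
    n_antisense: int
    n_sine: int
    n_tis: int
    n_cage: int
    per_stage_ids: dict[str, list[str]] | None = None

    def __post_init__(self):
        counts = [self.n_assembly, self.n_antisense, self.n_sine, self.n_tis]
        if any(a < b for a, b in zip(counts, counts[1:])) or self.n_cage < 0:
            raise SineupError(f"non-monotone funnel {counts + [self.n_cage]}")


def _distinct_antisense(pairs: list[CandidateSineup]) -> set[str]:
    return {p.antisense_id for p in pairs}


# ---------------------------------------------------------------------------
# Stage 1: antisense pairing


def find_antisense_pairs(
    assembly: list[TranscriptModel],
    reference: list[TranscriptModel],
    min_overlap: int = 1,
    span_mode: bool = False,
) -> list[CandidateSineup]:
    """All (assembly, reference) pairs with opposite strands and exonic overlap.

    An assembly transcript may pair with several reference isoforms; each
    pairing becomes its own candidate row. ``span_mode`` relaxes the overlap
    test from exon chains to genomic spans.
    """
    out: list[CandidateSineup] = []
    ref_by_chrom = group_by_chrom(reference)
    for asm in assembly:
        for ref in ref_by_chrom.get(asm.chrom, []):
            if asm.strand == ref.strand:
                continue
            if span_mode:
                ov = max(
                    0,
                    min(asm.span_end, ref.span_end)
                    - max(asm.span_start, ref.span_start),
                )
            else:
                ov = exonic_overlap_bp(asm, ref)
            if ov >= max(1, min_overlap):
                cfg = classify_pair(ref, asm, span_mode=span_mode)
                out.append(CandidateSineup(antisense=asm, sense=ref, configuration=cfg))
    out.sort(key=lambda c: (c.antisense_id, c.sense_id))
    return out


# ---------------------------------------------------------------------------
# Stage 2: SINE containment


def filter_sine_containing(
    pairs: list[CandidateSineup],
    repeats: list[RepeatFeature],
    classes: set[str] = frozenset({"SINE"}),
) -> list[CandidateSineup]:
    """Keep pairs whose antisense exons overlap >=1 repeat of an allowed class.

    The repeat may sit anywhere in the antisense exon chain, not only inside
    the sense overlap (candidate SINEUPs typically carry the element at their
    3' end, away from the binding region). All overlapping repeats of allowed
    classes are attached as ``embedded_repeats``.
    """
    known = {r.repeat_class for r in repeats}
    unknown = set(classes) - known
    if unknown and repeats:
        raise ConfigError(
            f"unknown repeat class(es) {sorted(unknown)}; "
            f"classes present in the annotation: {sorted(known)}"
        )
    allowed = [r for r in repeats if r.repeat_class in classes]
    rep_by_chrom = group_by_chrom(allowed)
    out: list[CandidateSineup] = []
    for p in pairs:
        hits = [
            r
            for r in rep_by_chrom.get(p.antisense.chrom, [])
            if exonic_overlap_with_intervals(p.antisense, [r.interval]) >= 1
        ]
        if hits:
            hits.sort(key=lambda r: (r.interval.start, r.interval.end, r.repeat_name))
            out.append(replace_fields(p, embedded_repeats=hits))
    return out


def replace_fields(p: CandidateSineup, **kw) -> CandidateSineup:
    """Shallow-copy a candidate with updated fields (stages never mutate input)."""
    return replace(p, **kw)


# ---------------------------------------------------------------------------
# Stage 3: TIS-window overlap


def filter_tis_overlap(
    pairs: list[CandidateSineup], k: int = 5, mode: str = "adjacent"
) -> list[CandidateSineup]:
    """Keep pairs where the antisense exons overlap the sense TIS window.

    Sense transcripts lacking a CDS or with a zero-length 5' UTR can never
    match. Records the overlap width as ``tis_overlap_bp``.
    """
    out: list[CandidateSineup] = []
    for p in pairs:
        if not p.sense.has_cds or p.sense.utr5_length == 0:
            continue
        win = tis_window(p.sense, k=k, mode=mode)
        ov = exonic_overlap_with_intervals(p.antisense, list(win.intervals))
        if ov >= 1:
            out.append(replace_fields(p, tis_overlap_bp=ov))
    return out


# ---------------------------------------------------------------------------
# Stage 4: CAGE support


def annotate_cage_support(
    pairs: list[CandidateSineup],
    cage: list[CageCluster],
    halfwidth: int = 200,
    same_strand: bool = True,
) -> list[CandidateSineup]:
    """Annotate each pair with CAGE evidence near the antisense 5' end.

    A cluster supports the antisense transcript when its distance to the 5'-end
    base is at most ``halfwidth`` nt (0 when the base falls inside the
    cluster) and, with ``same_strand``, its strand matches the antisense
    strand. Records the best (max) tpm and the smallest distance among
    supporting clusters.
    """
    cage_by_chrom = group_by_chrom(cage)
    out: list[CandidateSineup] = []
    for p in pairs:
        tss = p.antisense.five_prime_pos
        best_tpm: float | None = None
        best_dist: int | None = None
        for c in cage_by_chrom.get(p.antisense.chrom, []):
            if same_strand and c.strand != p.antisense.strand:
                continue
            d = c.interval.distance_to_point(tss)
            if d <= halfwidth:
                best_tpm = c.tpm if best_tpm is None else max(best_tpm, c.tpm)
                best_dist = d if best_dist is None else min(best_dist, d)
        out.append(
            replace_fields(
                p,
                cage_supported=best_tpm is not None,
                cage_best_tpm=best_tpm,
                cage_distance=best_dist,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Full cascade


@dataclass
class ScreenConfig:
    """File paths and parameters for a full screen run."""

    assembly_gtf: str | Path
    reference_gtf: str | Path
    repeats_out: str | Path
    cage_bed: str | Path
    out_dir: str | Path | None = None
    tis_window: int = 5
    tis_window_mode: str = "adjacent"
    cage_halfwidth: int = 200
    cage_same_strand: bool = True
    cage_filter: bool = False
    repeat_classes: frozenset[str] = frozenset({"SINE"})
    min_overlap: int = 1
    span_mode: bool = False
    keep_stage_ids: bool = True


def screen_transcripts(
    assembly: list[TranscriptModel],
    reference: list[TranscriptModel],
    repeats: list[RepeatFeature],
    cage: list[CageCluster],
    config: ScreenConfig | None = None,
) -> tuple[list[CandidateSineup], FunnelReport]:
    """Run the cascade on in-memory inputs; see run_screen for the file API."""
    cfg = config or ScreenConfig("", "", "", "")
    if reference and not any(t.has_cds for t in reference):
        warnings.warn(
            "reference set has no CDS-bearing transcripts; TIS stage will be empty",
            stacklevel=2,
        )
    pairs = find_antisense_pairs(
        assembly, reference, min_overlap=cfg.min_overlap, span_mode=cfg.span_mode
    )
    sine = filter_sine_containing(pairs, repeats, classes=set(cfg.repeat_classes))
    tis = filter_tis_overlap(sine, k=cfg.tis_window, mode=cfg.tis_window_mode)
    annotated = annotate_cage_support(
        tis, cage, halfwidth=cfg.cage_halfwidth, same_strand=cfg.cage_same_strand
    )
    candidates = [c for c in annotated if c.cage_supported] if cfg.cage_filter else annotated
    candidates.sort(key=lambda c: (c.antisense_id, c.sense_id))

    supported = {c.antisense_id for c in annotated if c.cage_supported}
    stage_ids = None
    if cfg.keep_stage_ids:
        stage_ids = {
            "antisense": sorted(_distinct_antisense(pairs)),
            "sine": sorted(_distinct_antisense(sine)),
            "tis": sorted(_distinct_antisense(tis)),
            "cage": sorted(supported),
        }
    report = FunnelReport(
        n_assembly=len({t.transcript_id for t in assembly}),
        n_antisense=len(_distinct_antisense(pairs)),
        n_sine=len(_distinct_antisense(sine)),
        n_tis=len(_distinct_antisense(tis)),
        n_cage=len(supported),
        per_stage_ids=stage_ids,
    )
    logger.info(
        "funnel: %d assembled -> %d antisense -> %d SINE -> %d TIS -> %d CAGE",
        report.n_assembly,
        report.n_antisense,
        report.n_sine,
        report.n_tis,
        report.n_cage,
    )
    return candidates, report


def run_screen(config: ScreenConfig) -> tuple[list[CandidateSineup], FunnelReport]:
    """Run the full cascade from files and optionally write the output bundle.

    Reads the assembly and reference GTFs, the RepeatMasker ``.out`` and the
    CAGE BED named in ``config``; when ``config.out_dir`` is set, writes
    candidates.tsv, candidates.bed and funnel.json there.
    """
    for label, p in (
        ("assembly GTF", config.assembly_gtf),
        ("reference GTF", config.reference_gtf),
        ("repeat annotation", config.repeats_out),
        ("CAGE BED", config.cage_bed),
    ):
        if not Path(p).is_file():
            raise SineupError(f"missing input file ({label}): {p}")
    assembly = sio.read_gtf(config.assembly_gtf, source_set="assembly")
    reference = sio.read_gtf(config.reference_gtf, source_set="reference")
    repeats = sio.read_repeatmasker_out(config.repeats_out)
    cage = sio.read_cage_bed(config.cage_bed)
    candidates, report = screen_transcripts(
        assembly, reference, repeats, cage, config
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_candidates(
            candidates, out / "candidates.tsv", out / "candidates.bed"
        )
        sio.write_funnel(report, out / "funnel.json")
    return candidates, report
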