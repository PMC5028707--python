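"""Synthetic annotation generator with planted truth labels.

Emulates the structure of a brain-transcriptome antisense screen without any
external downloads: one synthetic chromosome carries a series of independent
loci, each with a reference mRNA (5' UTR + CDS + 3' UTR) and one assembled
transcript of a labelled class:

- ``true_candidate`` — an opposite-strand transcript whose exon covers the
  sense TIS window, carries one SINE at its 3' end and has a CAGE cluster
  near its 5' end (the geometry of a PPP1R12A-AS1-like locus);
- ``no_sine`` — same geometry but carrying a LINE/L1 instead of a SINE;
- ``no_tis_overlap`` — antisense overlapping only CDS sequence at least
  50 nt downstream of the TIS window (SINE present);
- ``same_strand`` — overlaps the mRNA on the same strand (SINE present);
- ``intergenic`` — overlaps nothing (SINE present).

Background SINE copies (for the enrichment genome background) and CAGE noise
clusters are placed in a tail region that no transcript touches. Every file
is reproducible byte-for-byte from the seed, and all planted geometric
constraints are re-verified by independent per-base checks before the truth
table is written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from sineup_scan import io as sio
from sineup_scan.errors import GenerationError, SineupError
from sineup_scan.intervals import tis_window
from sineup_scan.models import (
    CageCluster,
    GenomicInterval,
    RepeatFeature,
    TranscriptModel,
)

#: Repeat roster: name -> (class, family). The first ``n_families`` SINE
#: entries are used as the plantable family pool.
SINE_ROSTER = [
    ("FRAM", "SINE", "Alu"),
    ("AluY", "SINE", "Alu"),
    ("MIRb", "SINE", "MIR"),
    ("AluSx", "SINE", "Alu"),
    ("MIR3", "SINE", "MIR"),
    ("AluJb", "SINE", "Alu"),
    ("FLAM_C", "SINE", "Alu"),
    ("MIRc", "SINE", "MIR"),
]
_DECOY = ("L1MA4", "LINE", "L1")

TRUE_CANDIDATE = "true_candidate"
NO_SINE = "no_sine"
NO_TIS = "no_tis_overlap"
SAME_STRAND = "same_strand"
INTERGENIC = "intergenic"
KLASSES = (TRUE_CANDIDATE, NO_SINE, NO_TIS, SAME_STRAND, INTERGENIC)


@dataclass
class SyntheticDatasetSpec:
    """Parameters of one synthetic screen dataset."""

    seed: int = 7
    n_true: int = 10
    n_no_sine: int = 5
    n_no_tis: int = 5
    n_same_strand: int = 5
    n_intergenic: int = 5
    n_families: int = 4
    genome_len: int | None = None  # None: sized automatically
    utr_len_range: tuple[int, int] = (100, 300)
    cds_len_range: tuple[int, int] = (300, 900)
    sine_len_range: tuple[int, int] = (80, 300)
    cage_tpm_range: tuple[float, float] = (0.5, 50.0)
    cage_noise_clusters: int = 10
    n_background_repeats: int = 200
    cage_halfwidth: int = 200
    tis_window: int = 5
    chrom: str = "chrS"
    family_probs: tuple[float, ...] | None = None  # None: uniform

    def __post_init__(self):
        counts = (
            self.n_true,
            self.n_no_sine,
            self.n_no_tis,
            self.n_same_strand,
            self.n_intergenic,
            self.cage_noise_clusters,
            self.n_background_repeats,
        )
        if any(c < 0 for c in counts):
            raise SineupError("all counts must be >= 0")
        if self.n_families < 2 or self.n_families > len(SINE_ROSTER):
            raise SineupError(
                f"n_families must be in [2, {len(SINE_ROSTER)}]"
            )
        for name in ("utr_len_range", "cds_len_range", "sine_len_range", "cage_tpm_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise SineupError(f"invalid {name} ({lo}, {hi})")
        if self.family_probs is not None:
            p = np.asarray(self.family_probs, dtype=float)
            if len(p) != self.n_families or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise SineupError("family_probs must be n_families non-negative values summing to 1")

    @property
    def families(self) -> list[tuple[str, str, str]]:
        return SINE_ROSTER[: self.n_families]

    @property
    def probs(self) -> np.ndarray:
        """Family abundance distribution; defaults to a geometric decay
        (each family half as abundant as the previous), mimicking the
        strongly skewed subfamily spectrum of genomic SINEs."""
        if self.family_probs is not None:
            return np.asarray(self.family_probs, dtype=float)
        w = 0.5 ** np.arange(self.n_families)
        return w / w.sum()


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label of one assembled transcript."""

    transcript_id: str
    klass: str
    sense_partner: str | None = None
    planted_family: str | None = None

    def __post_init__(self):
        if self.klass not in KLASSES:
            raise SineupError(f"unknown truth class {self.klass!r}")
        if self.klass == TRUE_CANDIDATE and (
            self.sense_partner is None or self.planted_family is None
        ):
            raise SineupError("true_candidate needs sense_partner and planted_family")


@dataclass
class SyntheticDataset:
    """In-memory view of a generated dataset (plus file paths once written)."""

    spec: SyntheticDatasetSpec
    reference: list[TranscriptModel]
    assembly: list[TranscriptModel]
    repeats: list[RepeatFeature]
    cage: list[CageCluster]
    truth: list[TruthRecord]
    genome_len: int
    paths: dict[str, Path] = field(default_factory=dict)

    def truth_ids(self, klass: str) -> set[str]:
        return {t.transcript_id for t in self.truth if t.klass == klass}


# ---------------------------------------------------------------------------
# locus construction (local coordinates, sense 5'->3' left to right)

_MARGIN = 700  # room left of the sense 5' end for antisense/CAGE extension
_UTR3 = 60
_LOCUS_GAP = 400


def _mirror(iv: tuple[int, int], width: int) -> tuple[int, int]:
    return (width - iv[1], width - iv[0])


def _flip_strand(s: str) -> str:
    return "-" if s == "+" else "+"


class _Locus:
    """One sense/assembled locus laid out on a local axis, then mirrored
    for minus-strand senses and shifted onto the chromosome."""

    def __init__(self, rng: np.random.Generator, spec: SyntheticDatasetSpec, klass: str):
        self.klass = klass
        u = int(rng.integers(spec.utr_len_range[0], spec.utr_len_range[1] + 1))
        c = int(rng.integers(spec.cds_len_range[0], spec.cds_len_range[1] + 1))
        c -= c % 3
        slen = int(rng.integers(spec.sine_len_range[0], spec.sine_len_range[1] + 1))
        S = _MARGIN
        tis = S + u  # local position of the first CDS base
        self.sense_exon = (S, S + u + c + _UTR3)
        self.sense_cds = (tis, tis + c)
        self.asm_exon: tuple[int, int] | None = None
        self.asm_is_antisense = True
        self.repeat: tuple[int, int] | None = None
        self.repeat_strand_local = "+" if rng.random() < 0.5 else "-"
        self.cage: tuple[int, int] | None = None

        if klass in (TRUE_CANDIDATE, NO_SINE):
            # antisense 3' end (local left) inside the UTR, 5' end in the CDS
            down_ext = int(rng.integers(50, min(c, 200) + 1))
            alen = slen + int(rng.integers(100, 251))
            a1 = tis + down_ext
            a0 = a1 - alen
            self.asm_exon = (a0, a1)
            pad = int(rng.integers(0, 21))
            if klass == TRUE_CANDIDATE:
                self.repeat = (a0 + pad, a0 + pad + slen)
            else:
                # decoy LINE so the class filter, not mere absence, is tested
                self.repeat = (a0 + pad, a0 + pad + slen)
            self.cage = self._cage_near(rng, five_prime=a1 - 1)
        elif klass == NO_TIS:
            # CDS-only overlap, >=50 nt downstream of the TIS window
            a0 = tis + 50 + int(rng.integers(0, 51))
            alen = slen + int(rng.integers(100, 201))
            self.asm_exon = (a0, a0 + alen)
            pad = int(rng.integers(0, 21))
            self.repeat = (a0 + pad, a0 + pad + slen)
            self.cage = self._cage_near(rng, five_prime=a0 + alen - 1)
        elif klass == SAME_STRAND:
            self.asm_is_antisense = False
            a0 = S + int(rng.integers(0, u))
            alen = slen + int(rng.integers(100, 201))
            self.asm_exon = (a0, a0 + alen)
            pad = int(rng.integers(0, 21))
            self.repeat = (a0 + pad, a0 + pad + slen)
        elif klass == INTERGENIC:
            a0 = self.sense_exon[1] + 250
            alen = slen + int(rng.integers(100, 201))
            self.asm_exon = (a0, a0 + alen)
            pad = int(rng.integers(0, 21))
            self.repeat = (a0 + pad, a0 + pad + slen)
        else:  # pragma: no cover
            raise GenerationError(f"unknown class {klass}")
        self.width = max(self.sense_exon[1], self.asm_exon[1]) + 100

    @staticmethod
    def _cage_near(rng: np.random.Generator, five_prime: int) -> tuple[int, int]:
        off = int(rng.integers(-150, 151))
        w = int(rng.integers(10, 31))
        start = five_prime + off
        return (start, start + w)


def _place_locus(
    locus: _Locus,
    offset: int,
    sense_strand: str,
    idx: int,
    spec: SyntheticDatasetSpec,
    rng: np.random.Generator,
    family: tuple[str, str, str] | None,
) -> tuple[TranscriptModel, TranscriptModel, list[RepeatFeature], list[CageCluster], TruthRecord]:
    """Mirror local coordinates for minus-strand senses and shift to genome."""
    w = locus.width
    flip = sense_strand == "-"

    def g(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = _mirror(iv, w) if flip else iv
        return (s + offset, e + offset)

    chrom = spec.chrom
    sid = f"REF_{idx:04d}"
    aid = f"ASM_{idx:04d}"
    sense = TranscriptModel(
        transcript_id=sid,
        gene_id=f"G_{idx:04d}",
        chrom=chrom,
        strand=sense_strand,
        exons=[GenomicInterval(chrom, *g(locus.sense_exon), sense_strand)],
        cds=g(locus.sense_cds),
        source_set="reference",
    )
    asm_strand = (
        sense_strand if not locus.asm_is_antisense else _flip_strand(sense_strand)
    )
    asm = TranscriptModel(
        transcript_id=aid,
        gene_id=aid,
        chrom=chrom,
        strand=asm_strand,
        exons=[GenomicInterval(chrom, *g(locus.asm_exon), asm_strand)],
        cds=None,
        source_set="assembly",
    )
    repeats: list[RepeatFeature] = []
    planted_family = None
    if locus.repeat is not None:
        if locus.klass == NO_SINE:
            name, rclass, rfam = _DECOY
        else:
            assert family is not None
            name, rclass, rfam = family
            if locus.klass == TRUE_CANDIDATE:
                planted_family = name
        rstrand = locus.repeat_strand_local
        if flip:
            rstrand = _flip_strand(rstrand)
        repeats.append(
            RepeatFeature(
                chrom=chrom,
                interval=GenomicInterval(chrom, *g(locus.repeat), rstrand),
                strand=rstrand,
                repeat_name=name,
                repeat_class=rclass,
                repeat_family=rfam,
            )
        )
    cage: list[CageCluster] = []
    if locus.cage is not None:
        tpm = float(
            np.round(rng.uniform(spec.cage_tpm_range[0], spec.cage_tpm_range[1]), 2)
        )
        cage.append(
            CageCluster(
                chrom=chrom,
                interval=GenomicInterval(chrom, *g(locus.cage), asm_strand),
                strand=asm_strand,
                tpm=tpm,
                name=f"cage_{aid}",
            )
        )
    truth = TruthRecord(
        transcript_id=aid,
        klass=locus.klass,
        sense_partner=sid if locus.klass != INTERGENIC else None,
        planted_family=planted_family,
    )
    return sense, asm, repeats, cage, truth


# ---------------------------------------------------------------------------
# post-hoc verification (independent per-base checks)


def _exonic_bases(t: TranscriptModel) -> set[int]:
    out: set[int] = set()
    for iv in t.exons:
        out.update(range(iv.start, iv.end))
    return out


def _verify(ds: SyntheticDataset) -> None:
    """Re-check every planted constraint per-base before the truth table is
    trusted; raises GenerationError on any violation."""
    ref_by_id = {t.transcript_id: t for t in ds.reference}
    sine_bases: set[int] = set()
    for r in ds.repeats:
        if r.repeat_class == "SINE":
            sine_bases.update(range(r.interval.start, r.interval.end))
    for rec in ds.truth:
        asm = next(t for t in ds.assembly if t.transcript_id == rec.transcript_id)
        bases = _exonic_bases(asm)
        if rec.klass == INTERGENIC:
            for ref in ds.reference:
                if bases & _exonic_bases(ref):
                    raise GenerationError(f"{rec.transcript_id}: intergenic overlaps {ref.transcript_id}")
            continue
        sense = ref_by_id[rec.sense_partner]
        win = tis_window(sense, k=ds.spec.tis_window)
        win_bases = {b for iv in win.intervals for b in range(iv.start, iv.end)}
        if rec.klass == SAME_STRAND:
            if asm.strand != sense.strand or not (bases & _exonic_bases(sense)):
                raise GenerationError(f"{rec.transcript_id}: bad same-strand geometry")
            continue
        if asm.strand == sense.strand or not (bases & _exonic_bases(sense)):
            raise GenerationError(f"{rec.transcript_id}: not antisense-overlapping")
        if rec.klass == TRUE_CANDIDATE:
            if not win_bases <= bases:
                raise GenerationError(f"{rec.transcript_id}: TIS window not covered")
            if sense.start_codon_pos not in bases:
                raise GenerationError(f"{rec.transcript_id}: TIS base not covered")
            if not (bases & sine_bases):
                raise GenerationError(f"{rec.transcript_id}: no SINE planted")
            tss = asm.five_prime_pos
            near = [
                c
                for c in ds.cage
                if c.strand == asm.strand
                and c.interval.distance_to_point(tss) <= ds.spec.cage_halfwidth
            ]
            if not near:
                raise GenerationError(f"{rec.transcript_id}: no CAGE support planted")
        elif rec.klass == NO_SINE:
            if bases & sine_bases:
                raise GenerationError(f"{rec.transcript_id}: stray SINE overlap")
        elif rec.klass == NO_TIS:
            if bases & win_bases or sense.start_codon_pos in bases:
                raise GenerationError(f"{rec.transcript_id}: touches the TIS window")
            if not (bases & sine_bases):
                raise GenerationError(f"{rec.transcript_id}: no SINE planted")


# ---------------------------------------------------------------------------
# public API


def build_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Generate a dataset in memory (no files); deterministic in spec.seed."""
    rng = np.random.default_rng(spec.seed)
    plan = (
        [TRUE_CANDIDATE] * spec.n_true
        + [NO_SINE] * spec.n_no_sine
        + [NO_TIS] * spec.n_no_tis
        + [SAME_STRAND] * spec.n_same_strand
        + [INTERGENIC] * spec.n_intergenic
    )
    families = spec.families
    probs = spec.probs
    reference: list[TranscriptModel] = []
    assembly: list[TranscriptModel] = []
    repeats: list[RepeatFeature] = []
    cage: list[CageCluster] = []
    truth: list[TruthRecord] = []
    offset = 100
    for idx, klass in enumerate(plan):
        locus = _Locus(rng, spec, klass)
        sense_strand = "+" if rng.random() < 0.5 else "-"
        fam = None
        if klass != NO_SINE and locus.repeat is not None:
            fam = families[int(rng.choice(len(families), p=probs))]
        sense, asm, reps, cg, rec = _place_locus(
            locus, offset, sense_strand, idx, spec, rng, fam
        )
        reference.append(sense)
        assembly.append(asm)
        repeats.extend(reps)
        cage.extend(cg)
        truth.append(rec)
        offset += locus.width + _LOCUS_GAP

    # tail: genome-background repeat copies and CAGE noise, touching nothing
    tail = offset + 600
    for j in range(spec.n_background_repeats):
        name, rclass, rfam = families[int(rng.choice(len(families), p=probs))]
        slen = int(
            rng.integers(spec.sine_len_range[0], spec.sine_len_range[1] + 1)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        repeats.append(
            RepeatFeature(
                chrom=spec.chrom,
                interval=GenomicInterval(spec.chrom, tail, tail + slen, strand),
                strand=strand,
                repeat_name=name,
                repeat_class=rclass,
                repeat_family=rfam,
            )
        )
        tail += slen + 20
    for j in range(spec.cage_noise_clusters):
        w = int(rng.integers(10, 31))
        strand = "+" if rng.random() < 0.5 else "-"
        tpm = float(np.round(rng.uniform(*spec.cage_tpm_range), 2))
        cage.append(
            CageCluster(
                chrom=spec.chrom,
                interval=GenomicInterval(spec.chrom, tail, tail + w, strand),
                strand=strand,
                tpm=tpm,
                name=f"noise_{j:03d}",
            )
        )
        tail += w + 50

    needed = tail + 100
    if spec.genome_len is not None and spec.genome_len < needed:
        raise GenerationError(
            f"genome_len {spec.genome_len} too small; need >= {needed}"
        )
    genome_len = spec.genome_len or needed
    repeats.sort(key=lambda r: (r.interval.start, r.interval.end, r.repeat_name))
    cage.sort(key=lambda c: (c.interval.start, c.interval.end, c.name))

    ds = SyntheticDataset(
        spec=spec,
        reference=reference,
        assembly=assembly,
        repeats=repeats,
        cage=cage,
        truth=truth,
        genome_len=genome_len,
    )
    _verify(ds)
    return ds


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=length))


def generate_dataset(
    spec: SyntheticDatasetSpec, out_dir: str | Path
) -> SyntheticDataset:
    """Generate and write a complete dataset bundle.

    Files: genome.fasta, reference.gtf, assembly.gtf, repeats.out, cage.bed,
    truth.tsv. Byte-identical across runs with the same spec; the generator
    validates every planted constraint before writing.
    """
    ds = build_dataset(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # a genome-sequence stream independent of the geometry stream keeps
    # coordinates stable whether or not the FASTA is consumed
    seq_rng = np.random.default_rng(spec.seed + 10_000)
    genome_chars = list(_random_genome(seq_rng, ds.genome_len))
    # every reference mRNA genuinely starts with AUG on its own strand
    for t in ds.reference:
        if t.cds is None:
            continue
        if t.strand == "+":
            genome_chars[t.cds[0] : t.cds[0] + 3] = "ATG"
        else:
            genome_chars[t.cds[1] - 3 : t.cds[1]] = "CAT"
    genome = "".join(genome_chars)

    paths = {
        "genome": out / "genome.fasta",
        "reference": out / "reference.gtf",
        "assembly": out / "assembly.gtf",
        "repeats": out / "repeats.out",
        "cage": out / "cage.bed",
        "truth": out / "truth.tsv",
    }
    sio.write_fasta({spec.chrom: genome}, paths["genome"])
    sio.write_gtf(ds.reference, paths["reference"])
    sio.write_gtf(ds.assembly, paths["assembly"])
    sio.write_repeatmasker_out(ds.repeats, paths["repeats"])
    sio.write_cage_bed(ds.cage, paths["cage"])
    with open(paths["truth"], "w") as fh:
        fh.write("transcript_id\tklass\tsense_partner\tplanted_family\n")
        for t in ds.truth:
            fh.write(
                f"{t.transcript_id}\t{t.klass}\t{t.sense_partner or '.'}\t"
                f"{t.planted_family or '.'}\n"
            )
    ds.paths = paths
    return ds


# ---------------------------------------------------------------------------
# enrichment scenarios


@dataclass
class EnrichmentScenario:
    """Candidate-embedded and genome-background repeat draws for the
    family-composition statistic."""

    cand_repeats: list[RepeatFeature]
    genome_repeats: list[RepeatFeature]
    family_probs: dict[str, float]
    cand_probs: dict[str, float]


def generate_enrichment_scenario(
    spec: SyntheticDatasetSpec,
    family_probs: Sequence[float] | None = None,
    enrich: tuple[str, float] | None = None,
) -> EnrichmentScenario:
    """Draw candidate and background repeat families for an enrichment test.

    In the null scenario both the ``spec.n_true`` candidate-embedded copies
    and the ``spec.n_background_repeats`` genomic copies are drawn i.i.d.
    from ``family_probs`` (uniform when omitted). ``enrich=(family, fold)``
    multiplies that family's probability by ``fold`` for the candidate draws
    only, renormalizing; a fold that produces an invalid distribution is an
    error.
    """
    rng = np.random.default_rng(spec.seed)
    families = spec.families
    names = [f[0] for f in families]
    if family_probs is None:
        p = spec.probs
    else:
        p = np.asarray(family_probs, dtype=float)
        if len(p) != len(families) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise SineupError(
                f"family_probs must be {len(families)} non-negative values summing to 1"
            )
    cand_p = p.copy()
    if enrich is not None:
        fam, fold = enrich
        if fam not in names:
            raise SineupError(f"unknown family {fam!r}; known: {names}")
        if fold < 0:
            raise SineupError(f"enrichment fold must be >= 0, got {fold}")
        cand_p[names.index(fam)] *= fold
        total = cand_p.sum()
        if total <= 0:
            raise SineupError("enrichment fold annihilated the distribution")
        cand_p = cand_p / total

    def draw(n: int, probs: np.ndarray, start: int) -> list[RepeatFeature]:
        out = []
        pos = start
        for i in rng.choice(len(families), size=n, p=probs):
            name, rclass, rfam = families[int(i)]
            out.append(
                RepeatFeature(
                    chrom=spec.chrom,
                    interval=GenomicInterval(spec.chrom, pos, pos + 100, "+"),
                    strand="+",
                    repeat_name=name,
                    repeat_class=rclass,
                    repeat_family=rfam,
                )
            )
            pos += 120
        return out

    cand = draw(spec.n_true, cand_p, 0)
    genome = draw(spec.n_background_repeats, p, 10_000_000)
    return EnrichmentScenario(
        cand_repeats=cand,
        genome_repeats=genome,
        family_probs=dict(zip(names, p.tolist())),
        cand_probs=dict(zip(names, cand_p.tolist())),
    )
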